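# Methods notes

## Coordinate frame and body model

All modules share one right-handed lab frame: x antero-posterior
(forward +), y mediolateral (leftward +), z vertical (up +), with the
floor at the ankle plane.  The body is a sagittal-dominant chain —
ankle → knee → hip → shoulder → hand — driven by six joint angles
(ankle dorsiflexion, knee flexion, hip flexion, lumbar/spine flexion,
shoulder flexion relative to the trunk, elbow flexion), plus a single
out-of-plane degree of freedom, an arm azimuth about the vertical axis
through the shoulder, used to reach lateral targets.  Hip and lumbar
flexion both pitch the single trunk segment; they are distinct channels
whose split is resolved by the generator's excursion prior, not by
geometry.  Bilateral landmarks (ankles, hands) carry fixed lateral
offsets; legs and arms are mirror-symmetric.

Segment masses and COM locations are a standard adult dispersion table
(trunk+head+neck 0.578 of body mass with COM 0.66 along hip→shoulder;
per-side thigh 0.100, shank 0.0465, foot 0.0145, upper arm 0.028,
forearm+hand 0.022), shipped as `data/segment_parameters.yaml` and
user-overridable.  The foot is a point mass at the ankle: the feet never
move, so this choice only adds a constant to the COM and cancels in
every displacement.  Whole-body COM is the mass-fraction-weighted sum of
segment COMs and is linear in landmark positions.

Joint angles decompose segment rotations by the intrinsic sequence
flexion-extension (y) → lateral bending (x) → axial rotation (z).  At
gimbal lock (lateral bending ±90°) axial rotation is set to 0, the
residual folds into flexion, and the sample is flagged.

## Task geometry

Impact heights are individualized:
IH_k = hip_height + trunk·cos θ_k − arm·sin θ_k, the hand-centroid
height with the shoulder flexed 90°, elbow extended and lumbar flexion
θ_k.  θ₁ = 15° and θ₃ = 60° are prescribed by the task; θ₂ is never
stated and defaults to their midpoint, 37.5° (configurable).  Each
15-ball set contains one block ball for every (impact height ×
direction) cell, three more drawn uniformly from those cells, and three
head-height duck balls (the set composition given in the task
description is internally inconsistent; this is the adopted reading).
Balls fly in a straight line at a constant 30 m/s — only launch speed
and intended impact points are specified, so no gravity drop is
modelled.  Launch intervals are uniform on [3.0, 3.6] s (a reading of
"3.3 ± 0.3 s"; a normal model is selectable).  Miss penalties are not
published; a miss costs the level's block reward, and the starting
balance is derived from the all-fail-ends-at-zero constraint.
Interception counts boundary contact (center distance exactly equal to
the sum of radii) as a block.

## Synthetic cohort and trial generator

**What is emulated.**  The generator reproduces the *statistical
structure* the analysis assumes: per-(perspective × impact height × sex)
means of measured movement time, hand position at contact, AP COM
displacement and success probability; between-subject and trial-level
Gaussian noise; and bell-shaped single-peak speed profiles so the
5%-of-peak segmentation is meaningful.  Cells of the default effect
table combine the published marginals additively
(cell = perspective marginal + impact-height marginal − grand mean),
with the reported interactions (vertical hand position at IH3 by
perspective, sex offsets at IH1/IH2, male elbow by perspective)
overriding the additive fill.

**Ready stance.**  Movements start from a "ready" posture (slight
crouch, ball held up: ankle 4°, knee 8°, hip 5°, spine 10°, shoulder
70°, elbow 25°), not rigid quiet standing — onset is detected mid-game.
This is also the only reading under which far-forward contact positions
(~77 cm) coexist with centimetre-scale AP COM displacements measured
onset→contact.

**Contact posture.**  Joint excursions are not free dials: the contact
posture must actually place the hand and COM at the configured values
for a given body.  Per cell (and per launch direction), a bounded
least-squares solve finds excursions and arm azimuth such that hand
AP/ML/vertical position and AP COM displacement match their targets
exactly, while staying close to sagittally plausible reference
excursions (a soft prior; the elbow is pinned to its configured value).
The solved excursions — direction-balanced means over left/center/right
— are written back into the table as the configured truth; vertical and
mediolateral COM displacement are *emergent* from the solved postures
and recorded as derived values (only AP COM is an enforced, published
quantity).

**Time structure.**  Every joint follows the same minimum-jerk profile
s(τ) = 10τ³ − 15τ⁴ + 6τ⁵.  Its speed shape crosses 5% of peak at
τ ≈ 0.0594 and 0.9406, so a profile of duration T yields a measured
movement time of 0.8811 T; the generator inverts this and then
*self-calibrates* against its own reduction: the profile duration and
amplitudes are iterated until the detected onset sample carries exactly
the ready posture, the detected contact sample exactly the solved
contact posture, and the detected movement time matches the target to
within half a sample.  This makes the zero-noise pipeline an exact
round-trip (≤ 1 sample in time, ≲0.01° and ≲0.01 cm in practice).
Recordings are sampled at 100 Hz with 0.45 s of quiet stance on both
sides (> the 20-sample half-window of the smoother).

**Noise model.**  Each subject gets Gaussian intercepts per quantity
(shared across cells), each trial an additional Gaussian draw; both are
truncated at ±2.5 SD.  Movement time uses the SE-reconstructed cohort SD
(SE·√29 ≈ 215 ms).  The positional SDs are deliberately *smaller* than
SE·√n (2.0 cm hand, 0.5 cm COM): in a real cohort most between-subject
positional spread reflects anthropometric scale, whereas the generator
applies offsets directly to reach targets that must stay inside each
subject's workspace — at SE·√29 ≈ 11.8 cm much of the cohort would be
asked to reach beyond arm's length.  Hand and COM offsets share a latent
"reach style" factor (r = 0.8).  Targets that still fall outside the
workspace saturate at the feasible boundary, as a real reach would.
Success is Bernoulli per trial with a subject-level offset on the
probability.  Anthropometrics are truncated normals around per-sex
reference bodies (derived from standard stature proportions at 1.63 m /
1.77 m mean stature).

**What is *not* emulated** — and hence what passing tests do not show
about real data: marker-cluster noise, occlusion/gap-filling,
soft-tissue artifact, left/right asymmetries, learning or fatigue across
sets, ducking kinematics, and any dependence of kinematics on ball size
(levels 2–3 trials are generated with identical condition effects and
are excluded by the analysis filter exactly as in the study design).
Between-subject variance enters directly on the measured quantities
rather than emerging from anthropometric diversity, so covariances
between measures are simpler than in a real cohort.

## Reduction

"Velocity" for segmentation is the Euclidean norm of the 3-D
hand-centroid velocity from the Savitzky–Golay derivative (41 samples,
order 4, `scipy.signal.savgol_filter`, edges by polynomial
extrapolation); the hand centroid stands in for the index fingertip of a
marker-based setup.  A 41-sample quartic window passes a 1 Hz sinusoid's
derivative with ~0.5% peak attenuation — the filter equals the
per-window least-squares fit to 1e-9, which is the accuracy claim the
tests enforce.  Onset/contact are the first samples at-or-below the
5%-of-peak level searching backward/forward from the peak (equality
counts; boundary truncation is flagged).  Excursions are read from the
raw angle channels at the bound samples (right side only, flexion
positive); positions are processed in metres and reported in cm, time in
ms.  Aggregation pools directions *balanced* (mean of per-direction
means) so the randomized extra block balls do not re-weight cells; this
is required for zero-noise exactness to be well-posed under the
randomized set composition.

## Statistics

The mixed ANOVA is the classical univariate split-plot computed by
projecting per-subject cell means onto orthonormal within contrasts
(normalized Helmert) and regressing each stratum's scores on the
effect-coded between factor.  Effect SS are Type III (unweighted means)
— relevant for the 15/14 sex split; with balanced groups the strata sum
exactly to the total SS (a tested invariant).  Uncorrected F is the
primary report for the 3-level factor (df 2, 2(N−2)), with
Greenhouse–Geisser ε and adjusted p alongside.  (Published 3-level
effects with df (2, 26) correspond to SPSS's multivariate tests; the
univariate decomposition is used here by design.)  LSD post hocs use the
omnibus stratum error term, so for a 2-level factor the single
comparison reproduces the omnibus F exactly (t² = F).  Simple effects
use the pooled within-cell error across moderator levels by default
(per-level error optional).  Sample size for a within factor uses the
noncentral-F formulation λ = n·m·f²/(1−ρ), df = (m−1, (n−1)(m−1)),
nonsphericity correction 1 — the convention in which f does not absorb
the repeated-measures correlation.  Under f = 0.4, α = .05, power .80,
m = 2, ρ = .5 this gives power 0.7901 at n = 14 (Monte-Carlo-confirmed)
and therefore a minimum of n = 15; a published minimum of 14 under
nominally identical assumptions is consistent with, e.g., ρ ≈ 0.55.

## Numerical choices and degenerate inputs

* Solver: `scipy.optimize.least_squares` (trf, bounded), position
  residuals weighted 1/0.02 cm vs 1/10° excursion priors; tolerances
  1e-14 for calibration/noise-free runs, 1e-9 with warm starts per
  (cell, direction) for noisy trials.
* Zero-variance ANOVA strata yield flagged infinite F (NaN when the
  effect SS is also numerically zero, threshold scaled to the data
  magnitude).
* All-zero speed profiles raise a degenerate-trial error; profiles whose
  tails never reach 5% return boundary indices with truncation flags.
* Ties in the threshold search resolve to the first qualifying sample in
  the search direction.
* All randomness flows from one master seed via
  `SeedSequence([seed, subject_index, stream])`; stream 1 = subject
  intercepts, 2/3 = sessions, `[seed, 0xA0]` = cohort anthropometrics.

## Problem sizes

The default study-scale run is 29 subjects × 2 sessions × 3 levels ×
2 sets × 12 block balls = 4176 recordings (~156 samples each), of which
the 1392 level-1 trials are analyzed; it completes in a couple of
minutes on one CPU.  Unit and property tests run on 2–8-subject cohorts
and level-1-only sessions; the type-I calibration uses 1000 null
replicates of the full 29-subject design.

## Known limitations

* The kinematic chain is planar-plus-azimuth; lateral bending and axial
  rotation channels exist in the Euler layer but are not driven by the
  generator.
* Hip vs lumbar flexion are geometrically degenerate (single trunk
  segment); their split is prior-driven.
* Vertical COM displacement of the solved postures is several times the
  published centimetre-scale values for low targets — enforcing it
  jointly with hand position and AP COM is over-constrained in this
  chain, and it is deliberately left emergent.
* Success is statistically generated (Bernoulli), not derived from the
  interception geometry; the gameplay module's interception check is
  available but not coupled to the kinematic generator.
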