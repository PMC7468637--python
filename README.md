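# vdodge — virtual-dodgeball interception kinematics

`vdodge` is a reusable, fully tested pipeline for studying how **avatar
perspective** (first- vs third-person rendering of one's virtual body)
shapes whole-body movement in a VR interception task.  In the task a
player blocks dodgeballs launched at 30 m/s toward one of three
individualized **impact heights** (IH1 highest … IH3 lowest, derived from
the player's hip height, trunk length and arm length at prescribed lumbar
flexion angles) and three directions (midline, ±20 cm).  The questions of
interest are biomechanical: how far does the hand reach at ball contact,
how much does each joint flex between movement onset and contact, and how
far does the whole-body center of mass (COM) travel?

Because motion-capture recordings of such studies are rarely shared, the
package ships a **synthetic motion-capture generator** whose default
condition effects transcribe a published cohort's condition means, so the
full analysis chain is exercisable end-to-end with no downloads:

1. **`vdodge.synth`** — seeded cohorts (n subjects, alternating sexes,
   anthropometric variation) performing minimum-jerk whole-body reaches
   from a ready stance to a contact posture solved by inverse kinematics
   so that hand position, AP COM displacement and movement time hit the
   configured per-condition means plus subject/trial noise.  Output:
   100 Hz joint-angle + landmark time series (TSV + JSON sidecar).
2. **`vdodge.reduction`** — the kinematic reduction: 41-point 4th-order
   Savitzky–Golay smoothing/differentiation of the hand path; movement
   onset/contact as the samples where speed falls to ≤ 5% of its peak
   (backward/forward search from the peak); movement time, per-joint
   excursions, COM displacement from segment parameters, and hand
   position relative to the ankle centroid; trial filtering (standard
   24 cm ball only) and per-(subject × perspective × impact height)
   aggregation.
3. **`vdodge.stats`** — 3-way mixed repeated-measures ANOVA (sex between;
   perspective and impact height within), Fisher-LSD post hocs sharing
   the ANOVA error strata, simple-effects decomposition, Bonferroni
   paired t-tests, and noncentral-F power/sample-size computation for
   within-subject designs.

## The statistics in brief

For subject *i* in sex group *g* with within-subject cells
(*p*, *h*) ∈ {first, third} × {IH1, IH2, IH3}, the cell means
*Y*<sub>*i,p,h*</sub> decompose as a classical univariate split-plot:
each within effect is projected onto orthonormal contrasts and tested
against its own subject-by-factor stratum,

F = MS<sub>effect</sub> / MS<sub>subject×factor</sub>,

with Type III (unweighted-means) sums of squares for the slightly
unbalanced sex split and Greenhouse–Geisser ε reported for the 3-level
factor.  Power for a one-group within factor with *m* measurements,
effect size *f* and inter-measure correlation ρ uses
λ = *n·m·f*²/(1−ρ), df = (m−1, (n−1)(m−1)).

## Worked example

```python
from vdodge.pipeline import (PipelineConfig, condition_marginals,
                             run_analyze, run_reduce, simulate_cohort, format_report)

cfg = PipelineConfig(seed=1, n_subjects=8, levels=(1,))
cohort, recs, events = simulate_cohort(cfg)        # 8 subjects, 384 recordings
_, cell_means = run_reduce(recs, config=cfg)
print(condition_marginals(cell_means))
print(format_report(run_analyze(cell_means)))
```

prints (abridged) the pooled condition marginals of this small cohort

```
   hand_ap_first: 78.1      # cm forward of the ankles at ball contact
   hand_ap_third: 70.5
          mt_IH1: 508.9     # ms onset -> contact (high balls are reached faster)
          mt_IH3: 596.3
   hand_vert_IH1: 114.8     # cm above the floor
    com_ap_first: 2.4       # cm of forward COM travel
   success_first: 91.9      # % of balls blocked
```

and the ANOVA block for antero-posterior hand position:

```
[hand_ap_cm]  (n = 8)
  perspective                          F(1,6) = 2426.548  p = 0.0000 *
  impact_height                        F(2,12) = 1260.978  p = 0.0000 *
  ...
    LSD perspective: first - third = +7.645  t(6) = 49.260, p = 0.0000
```

The first-person perspective draws the hand ~7.6 cm further forward —
the generator's configured perspective effect, recovered through the
entire smoothing/segmentation/aggregation chain.  (With only 8 subjects
and the default between-subject scatter, movement-time marginals sit a
sampling-error away from their configured 574/671 ms; the full 29-subject
cohort recovers them within two standard errors.)

The same pipeline is available as a CLI:

```bash
vdodge simulate --seed 1 --out run/
vdodge reduce   --manifest run/manifest.csv --out run/
vdodge analyze  --cell-means run/cell_means.csv --out run/effects.csv
vdodge report   --cell-means run/cell_means.csv
```

## Layout

```
src/vdodge/
  body.py       anthropometrics, forward kinematics, Euler angles, COM
  gameplay.py   impact heights, launch schedules, ballistics, scoring
  effects.py    condition-effect tables (study-derived defaults)
  synth.py      synthetic cohort + trial generator
  recording.py  TSV/JSON trial-recording container
  reduction.py  smoothing, segmentation, trial measures, aggregation
  stats.py      mixed RM-ANOVA, LSD, simple effects, paired t, power
  pipeline.py   orchestration; cli.py  command-line interface
  data/segment_parameters.yaml   segment mass/COM fractions
docs/methods.md  model and design notes
```
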