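"""Synthetic motion-capture generator.

Every trial is a whole-body interception movement from a fixed ready
stance to a contact posture, time-parameterized by a minimum-jerk profile
(quintic, zero endpoint velocity and acceleration), sampled at 100 Hz with
quiet padding on both sides.  The contact posture is solved per trial so
that the measured quantities — hand position at contact, antero-posterior
COM displacement, joint excursions — equal the effect-table cell values
plus subject- and trial-level noise, and the generator self-calibrates so
that the 5%-of-peak-velocity segmentation recovers exactly the intended
onset-to-contact changes:

* the onset sample's posture is the ready stance,
* the contact sample's posture is the solved contact posture,
* the measured movement time equals the cell's movement time to within
  one sample.

All randomness flows from one master seed through documented
``numpy.random.SeedSequence`` streams (``[master, subject_index, stream]``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .body import (
    Anthropometrics,
    Posture,
    SegmentParameterTable,
    ankle_centroid,
    com_from_landmarks,
    forward_kinematics,
    forward_kinematics_arrays,
    hand_centroid,
)
from .effects import EffectCell, EffectTable, READY_STANCE
from .errors import GenerationError, ValidationError
from .gameplay import DIRECTION_OFFSETS, generate_set_schedule
from .recording import TrialRecording
from .reduction import detect_movement_bounds, savgol_derivative

__all__ = [
    "Subject",
    "sample_cohort",
    "minimum_jerk_position",
    "minimum_jerk_speed_shape",
    "threshold_crossings",
    "calibrate_duration",
    "solve_contact_posture",
    "ContactSolution",
    "draw_subject_offsets",
    "synthesize_trial",
    "synthesize_session",
]

RATE = 100.0  # Hz
PAD_S = 0.45  # quiet standing padding on each side of the movement (s)
MIN_MT_MS = 250.0  # floor for noisy movement-time draws

#: SDs of the cohort anthropometric distributions (m / kg), applied around
#: the per-sex reference body and truncated at +/-2.5 SD
ANTHRO_SD = dict(hip_height=0.035, trunk_length=0.020, arm_length=0.025, body_mass=7.0)

#: correlation between a subject's hand-reach offset and COM offset —
#: subjects who reach further also displace their COM further
HAND_COM_CORR = 0.8

_NOISY_QUANTITIES = ("mt_ms", "hand_ap_cm", "hand_ml_cm", "hand_vert_cm", "com_ap_cm", "success_p")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    sex: str
    anthro: Anthropometrics
    index: int = 0


# ---------------------------------------------------------------------------
# minimum-jerk time structure
# ---------------------------------------------------------------------------

def minimum_jerk_position(tau):
    """Normalized minimum-jerk position s(tau) on [0, 1]."""
    t = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def minimum_jerk_speed_shape(tau):
    """ds/dtau = 30 tau^2 (1 - tau)^2 (bell-shaped, single interior peak)."""
    t = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 30 * t**2 * (1 - t) ** 2


def threshold_crossings(threshold: float = 0.05) -> tuple[float, float]:
    """Fractions of total duration where the minimum-jerk speed crosses
    ``threshold`` x peak: the closed-form roots of
    ``tau (1 - tau) = sqrt(threshold)/4``."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    disc = np.sqrt(1.0 - np.sqrt(threshold))
    return (1.0 - disc) / 2.0, (1.0 + disc) / 2.0


def calibrate_duration(target_measured_mt_ms: float, threshold: float = 0.05) -> float:
    """Total profile duration T (ms) whose interval between the
    threshold-of-peak speed crossings equals the target measured movement
    time; T = target / (tau2 - tau1) ~ target / 0.8811 at 5%."""
    if target_measured_mt_ms <= 0:
        raise ValidationError("target movement time must be positive")
    t1, t2 = threshold_crossings(threshold)
    return target_measured_mt_ms / (t2 - t1)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def sample_cohort(n: int, seed: int, noise_scale: float = 1.0) -> list[Subject]:
    """Sample ``n`` subjects with near-balanced, alternating sexes and
    anthropometrics drawn from truncated normal distributions around the
    per-sex reference bodies.  With ``noise_scale`` 0 every subject gets
    exactly the reference body of their sex."""
    if n < 2:
        raise ValidationError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA0]))
    subjects = []
    for i in range(n):
        sex = "male" if i % 2 == 0 else "female"  # male-first: n=29 -> 15 male
        ref = Anthropometrics.reference(sex)
        draws = {}
        for name, sd in ANTHRO_SD.items():
            z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            draws[name] = getattr(ref, name) + noise_scale * sd * z
        subjects.append(
            Subject(
                subject_id=f"S{i + 1:02d}",
                sex=sex,
                anthro=Anthropometrics(sex=sex, **draws),
                index=i,
            )
        )
    return subjects


def draw_subject_offsets(rng: np.random.Generator, table: EffectTable) -> dict[str, float]:
    """Subject-level random intercepts for every noisy quantity.

    The hand-AP and COM-AP offsets share a latent 'reach style' factor
    (correlation ~0.8) so that subjects who reach further also shift
    their COM further — keeping noisy targets inside the workspace.
    """
    z = {q: float(rng.standard_normal()) for q in _NOISY_QUANTITIES}
    z["com_ap_cm"] = HAND_COM_CORR * z["hand_ap_cm"] + np.sqrt(1 - HAND_COM_CORR**2) * z["com_ap_cm"]
    return {q: table.between_sd.get(q, 0.0) * float(np.clip(z[q], -2.5, 2.5))
            for q in _NOISY_QUANTITIES}


# ---------------------------------------------------------------------------
# contact-posture solver
# ---------------------------------------------------------------------------

_IK_JOINTS = ("ankle", "knee", "hip", "spine", "shoulder")  # elbow is pinned
_IK_BOUNDS_LO = np.array([-15.0, -8.0, -15.0, -20.0, -50.0, -70.0])
_IK_BOUNDS_HI = np.array([35.0, 75.0, 75.0, 75.0, 85.0, 70.0])
_POS_TOL_CM = 0.02  # residual scale for position constraints
_PRIOR_TOL_DEG = 10.0  # soft anchor scale for the free excursions
_AZ_PRIOR_DEG = 45.0


def _fast_chain(x5, elbow, azimuth, ready_arr, anthro) -> np.ndarray:
    """Midline chain points [ankle_c, knee, hip, shoulder, elbow, hand_mid]
    as a (6, 3) array; float-math fast path for the solver's inner loop."""
    import math

    a = ready_arr[0] + x5[0]
    k = ready_arr[1] + x5[1]
    h = ready_arr[2] + x5[2]
    sp = ready_arr[3] + x5[3]
    sh = ready_arr[4] + x5[4]
    el = ready_arr[5] + elbow
    rad = math.radians
    b_sh, b_th = rad(a), rad(a - k)
    b_tr = rad(a - k + h + sp)
    b_ua = rad(a - k + h + sp + 180.0 - sh)
    b_fa = b_ua - rad(el)
    pts = np.empty((6, 3))
    pts[0] = 0.0
    pts[1] = (anthro.shank_length * math.sin(b_sh), 0.0, anthro.shank_length * math.cos(b_sh))
    pts[2] = pts[1] + (anthro.thigh_length * math.sin(b_th), 0.0, anthro.thigh_length * math.cos(b_th))
    pts[3] = pts[2] + (anthro.trunk_length * math.sin(b_tr), 0.0, anthro.trunk_length * math.cos(b_tr))
    ev = np.array([anthro.upper_arm_length * math.sin(b_ua), 0.0, anthro.upper_arm_length * math.cos(b_ua)])
    hv = ev + (anthro.forearm_length * math.sin(b_fa), 0.0, anthro.forearm_length * math.cos(b_fa))
    az = rad(azimuth)
    ca, sa = math.cos(az), math.sin(az)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    pts[4] = pts[3] + rot @ ev
    pts[5] = pts[3] + rot @ hv
    return pts


#: (weight, com_fraction, proximal index, distal index) into the fast-chain
#: points; hand_l/hand_r collapse onto the hand midpoint (their fixed,
#: equal-mass lateral offsets cancel in the COM sum)
_FAST_POINT_INDEX = {"ankle_c": 0, "knee": 1, "hip": 2, "shoulder": 3, "elbow": 4,
                     "hand_l": 5, "hand_r": 5}


def _fast_com_spec(params: SegmentParameterTable):
    spec = []
    for seg in params.segments.values():
        try:
            pi = _FAST_POINT_INDEX[seg["proximal"]]
            di = _FAST_POINT_INDEX[seg["distal"]]
        except KeyError:
            return None  # non-standard landmark: fall back to the generic path
        spec.append((seg["mass_fraction"] * seg.get("count", 1), seg["com_fraction"], pi, di))
    return spec


def _fast_com(pts: np.ndarray, spec) -> np.ndarray:
    com = np.zeros(3)
    for w, f, pi, di in spec:
        com += w * (pts[pi] + f * (pts[di] - pts[pi]))
    return com


@dataclass(frozen=True)
class ContactSolution:
    """Solved contact posture for one cell/trial."""

    excursions: dict  # deg, all six joints
    arm_azimuth_deg: float
    posture: Posture
    hand_cm: tuple  # achieved hand position rel. ankle centroid
    com_ml_cm: float  # emergent
    com_vert_cm: float  # emergent
    com_ap_cm: float  # achieved
    max_constraint_err_cm: float


def solve_contact_posture(
    anthro: Anthropometrics,
    ready: Posture,
    targets: dict[str, float],
    e_ref: dict[str, float],
    elbow_deg: float,
    params: SegmentParameterTable | None = None,
    cell_name: str = "",
    warm: np.ndarray | None = None,
    strict_cm: float = 0.05,
    solver_tol: float = 1e-14,
) -> ContactSolution:
    """Resolve the kinematic redundancy of the contact posture.

    Finds excursions from the ready stance (plus an arm azimuth for
    lateral targets) such that the hand centroid lands on the configured
    position (AP/ML/vertical, cm relative to the ankle centroid) and the
    whole-body COM moves by the configured antero-posterior amount, while
    staying close to the reference excursions.  The elbow excursion is
    pinned to its configured value.  Raises :class:`GenerationError` when
    the constraints cannot be met within ``strict_cm``.
    """
    if params is None:
        params = SegmentParameterTable()
    ready_arr = ready.as_array()
    lm_ready = forward_kinematics(ready, anthro)
    com_ready = com_from_landmarks(lm_ready, params)

    t = np.array(
        [targets["hand_ap_cm"], targets["hand_ml_cm"], targets["hand_vert_cm"], targets["com_ap_cm"]]
    )
    e_ref_vec = np.array([e_ref[j] for j in _IK_JOINTS])
    com_spec = _fast_com_spec(params)

    def _measures(x):
        """Hand position rel. ankle centroid and COM displacement, in cm."""
        if com_spec is not None:
            pts = _fast_chain(x[:5], elbow_deg, x[5], ready_arr, anthro)
            hand = (pts[5] - pts[0]) * 100.0
            com = (_fast_com(pts, com_spec) - com_ready) * 100.0
            return hand, com
        angles = dict(zip(_IK_JOINTS, ready_arr[:5] + x[:5]))
        angles["elbow"] = ready_arr[5] + elbow_deg
        angles["arm_azimuth"] = x[5]
        lm = forward_kinematics_arrays({k: np.asarray(v) for k, v in angles.items()}, anthro)
        hand = (hand_centroid(lm) - ankle_centroid(lm)) * 100.0
        com = (com_from_landmarks(lm, params) - com_ready) * 100.0
        return hand, com

    def residuals(x):
        hand, com = _measures(x)
        return np.concatenate(
            [
                (np.array([hand[0], hand[1], hand[2], com[0]]) - t) / _POS_TOL_CM,
                (x[:5] - e_ref_vec) / _PRIOR_TOL_DEG,
                [x[5] / _AZ_PRIOR_DEG],
            ]
        )

    x0 = warm.copy() if warm is not None else np.concatenate([e_ref_vec, [0.0]])
    x0 = np.clip(x0, _IK_BOUNDS_LO + 1e-9, _IK_BOUNDS_HI - 1e-9)
    sol = least_squares(
        residuals, x0, bounds=(_IK_BOUNDS_LO, _IK_BOUNDS_HI),
        method="trf", xtol=solver_tol, ftol=solver_tol, gtol=solver_tol, max_nfev=400,
    )
    hand, com = _measures(sol.x)
    err = np.abs(np.array([hand[0], hand[1], hand[2], com[0]]) - t)
    if np.max(err) > strict_cm:
        raise GenerationError(
            f"cell {cell_name or targets}: contact posture infeasible "
            f"(worst constraint error {np.max(err):.3f} cm)"
        )
    exc = dict(zip(_IK_JOINTS, (float(v) for v in sol.x[:5])))
    exc["elbow"] = float(elbow_deg)
    posture = ready.with_excursion(
        np.array([exc[j] for j in Posture.JOINTS]), arm_azimuth=float(sol.x[5])
    )
    return ContactSolution(
        excursions=exc,
        arm_azimuth_deg=float(sol.x[5]),
        posture=posture,
        hand_cm=tuple(float(v) for v in hand),
        com_ml_cm=float(com[1]),
        com_vert_cm=float(com[2]),
        com_ap_cm=float(com[0]),
        max_constraint_err_cm=float(np.max(err)),
    )


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------

def _build_recording(
    anthro: Anthropometrics,
    ready: Posture,
    solution: ContactSolution,
    mt_ms: float,
    threshold: float = 0.05,
    rate: float = RATE,
    max_iter: int = 12,
):
    """Time-parameterize ready -> contact and self-calibrate so that the
    *detected* onset/contact samples carry exactly the ready and contact
    postures and their separation equals the requested movement time.

    Two couplings are corrected iteratively: (a) the smoothing filter
    widens the speed profile at the 5% level, so the profile duration T is
    rescaled until the detected movement time matches ``mt_ms`` to within
    half a sample; (b) amplitudes are rescaled by the minimum-jerk position
    values at the detected bounds so measured excursions equal the solved
    ones.  Returns (time, angle dict, landmark dict, bounds)."""
    ready7 = np.concatenate([ready.as_array(), [ready.arm_azimuth]])
    e7 = np.concatenate(
        [[solution.excursions[j] for j in Posture.JOINTS], [solution.arm_azimuth_deg - ready.arm_azimuth]]
    )

    t1, t2 = threshold_crossings(threshold)
    T = calibrate_duration(mt_ms, threshold) / 1000.0  # s
    n_pad = int(round(PAD_S * rate))
    frac_on, frac_off = t1, t2
    bounds = None
    prev = None
    time = s = angles_t = None
    for _ in range(max_iter):
        n_move = max(4, int(round(T * rate)))
        n = 2 * n_pad + n_move + 1
        time = np.arange(n) / rate
        tau = np.clip((time - n_pad / rate) / T, 0.0, 1.0)
        s = minimum_jerk_position(tau)
        s_on, s_off = minimum_jerk_position(frac_on), minimum_jerk_position(frac_off)
        span = s_off - s_on
        if span <= 1e-9:
            raise GenerationError("degenerate minimum-jerk span")
        amp = e7 / span
        base = ready7 + e7 - amp * s_off
        angles_t = base[None, :] + np.outer(s, amp)
        names = Posture.JOINTS + ("arm_azimuth",)
        lm = forward_kinematics_arrays({nm: angles_t[:, k] for k, nm in enumerate(names)}, anthro)
        hand = hand_centroid(lm)
        _, vel = savgol_derivative(hand, rate=rate)
        speed = np.linalg.norm(vel, axis=1)
        bounds = detect_movement_bounds(speed, threshold=threshold)
        measured_ms = (bounds.contact_index - bounds.onset_index) / rate * 1000.0
        frac_on = np.clip(tau[bounds.onset_index], 0.0, 1.0)
        frac_off = np.clip(tau[bounds.contact_index], 0.0, 1.0)
        state = (bounds.onset_index, bounds.contact_index, n_move)
        if abs(measured_ms - mt_ms) <= 1000.0 / rate / 2.0 and state == prev:
            break
        prev = state
        if measured_ms > 0:
            T *= mt_ms / measured_ms
    angle_channels = {nm: angles_t[:, k] for k, nm in enumerate(Posture.JOINTS + ("arm_azimuth",))}
    return time, angle_channels, lm, bounds


def synthesize_trial(
    subject: Subject,
    cell: EffectCell,
    direction: str,
    rng: np.random.Generator,
    table: EffectTable,
    subject_offsets: dict[str, float] | None = None,
    meta: dict | None = None,
    warm_cache: dict | None = None,
) -> TrialRecording:
    """One synthetic trial for a condition cell and launch direction.

    Trial-level Gaussian noise is added to the cell targets, the contact
    posture is re-solved for the noisy targets (warm-started from the
    previous solve of the same cell/direction), and success is drawn
    Bernoulli from the cell probability plus the subject offset.
    """
    if cell.excursions is None:
        raise ValidationError("effect table must be calibrated before synthesis")
    b = subject_offsets or {q: 0.0 for q in _NOISY_QUANTITIES}
    w = table.within_sd

    def noisy(q: str, base: float) -> float:
        # trial draws are truncated at +/-2.5 SD as a workspace guard
        z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
        return base + b.get(q, 0.0) + w.get(q, 0.0) * z

    mt = max(MIN_MT_MS, noisy("mt_ms", cell.mt_ms))
    dir_cm = DIRECTION_OFFSETS[direction] * 100.0
    targets = dict(
        hand_ap_cm=noisy("hand_ap_cm", cell.hand_ap_cm),
        hand_ml_cm=noisy("hand_ml_cm", cell.hand_ml_cm + dir_cm),
        hand_vert_cm=noisy("hand_vert_cm", cell.hand_vert_cm),
        com_ap_cm=noisy("com_ap_cm", cell.com_ap_cm),
    )
    key = (cell.perspective, cell.impact_height, cell.sex, direction)
    warm = warm_cache.get(key) if warm_cache is not None else None
    if warm is None and cell.direction_warm and direction in cell.direction_warm:
        warm = np.asarray(cell.direction_warm[direction], dtype=float)
    if warm is None:
        warm = np.concatenate(
            [[cell.excursions[j] for j in _IK_JOINTS], [cell.arm_azimuth_deg]]
        )
    sol = solve_contact_posture(
        subject.anthro,
        table.ready_stance,
        targets,
        e_ref=cell.e_ref,
        elbow_deg=cell.elbow_deg,
        cell_name=str(key),
        warm=np.asarray(warm, dtype=float),
        # noisy targets may fall outside the subject's workspace; the reach
        # then saturates at the feasible boundary (as a real reach would)
        # and only gross failures abort
        strict_cm=0.05 if _is_noise_free(table) else 6.0,
        solver_tol=1e-14 if _is_noise_free(table) else 1e-9,
    )
    if warm_cache is not None:
        warm_cache[key] = np.concatenate([[sol.excursions[j] for j in _IK_JOINTS], [sol.arm_azimuth_deg]])

    time, angle_channels, landmarks, bnds = _build_recording(
        subject.anthro, table.ready_stance, sol, mt
    )
    p = float(np.clip(cell.success_p + b.get("success_p", 0.0), 0.0, 1.0))
    success = bool(rng.random() < p)
    md = {
        "subject_id": subject.subject_id,
        "sex": subject.sex,
        "perspective": cell.perspective,
        "impact_height": cell.impact_height,
        "direction": direction,
        "success": success,
        "target_mt_ms": mt,
    }
    if meta:
        md.update(meta)
    return TrialRecording(time=time, angles=angle_channels, landmarks=landmarks, meta=md, rate=RATE)


def _is_noise_free(table: EffectTable) -> bool:
    return all(v == 0 for v in table.between_sd.values()) and all(
        v == 0 for v in table.within_sd.values()
    )


def synthesize_session(
    subject: Subject,
    perspective: str,
    table: EffectTable,
    seed,
    subject_offsets: dict[str, float] | None = None,
    levels: tuple[int, ...] = (1, 2, 3),
    sets_per_level: int = 2,
    session_index: int = 0,
) -> tuple[list[TrialRecording], list[dict]]:
    """One gameplay session: ``sets_per_level`` 15-ball sets per level.

    Block balls yield full trial recordings; duck balls (object avoidance
    rather than interception) emit event-log entries only.  Returns
    (recordings, event rows).
    """
    rng = np.random.default_rng(seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed)))
    recordings: list[TrialRecording] = []
    events: list[dict] = []
    warm_cache: dict = {}
    t0 = 0.0
    for level in levels:
        for set_idx in range(sets_per_level):
            schedule = generate_set_schedule(subject.anthro, level, rng, set_index=set_idx, t0=t0)
            t0 = schedule[-1].launch_time
            for ball in schedule:
                event = {
                    "subject_id": subject.subject_id,
                    "perspective": perspective,
                    "session_index": session_index,
                    "level": level,
                    "set_index": set_idx,
                    "ball_index": ball.ball_index,
                    "launch_time_s": ball.launch_time,
                    "kind": ball.kind,
                    "impact_height_label": ball.ih_label,
                    "direction": ball.direction,
                    "diameter_m": ball.diameter,
                }
                events.append(event)
                if ball.kind != "block":
                    continue
                cell = table.cell(perspective, ball.ih_label, subject.sex)
                rec = synthesize_trial(
                    subject,
                    cell,
                    ball.direction,
                    rng,
                    table,
                    subject_offsets=subject_offsets,
                    warm_cache=warm_cache,
                    meta={
                        "kind": "block",
                        "diameter": ball.diameter,
                        "level": level,
                        "set_index": set_idx,
                        "ball_index": ball.ball_index,
                        "session_index": session_index,
                        "trial_id": f"{subject.subject_id}_{perspective}_L{level}S{set_idx}B{ball.ball_index:02d}",
                    },
                )
                event["success"] = rec.meta["success"]
                recordings.append(rec)
    return recordings, events
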