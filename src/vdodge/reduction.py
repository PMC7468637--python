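"""Kinematic data reduction.

The pipeline mirrors a standard whole-body reaching reduction: the hand
path is smoothed and differentiated with a 41-point fourth-order
Savitzky-Golay filter; movement onset and target contact are the nearest
samples at-or-before / at-or-after the speed peak where speed first drops
to <= 5% of its peak (backward and forward search respectively); movement
time, joint excursions, whole-body COM displacement and the hand position
relative to the ankle centroid are then read off between those bounds.

Angles are analyzed for the right side only.  "Velocity" for segmentation
is the Euclidean norm of the 3-D hand-centroid velocity; the hand centroid
stands in for the index fingertip tracked in a marker-based setup.
Positions are processed in metres and reported in centimetres; movement
time in milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .body import SegmentParameterTable, com_from_landmarks
from .errors import ConfigurationError, DegenerateTrialError, ValidationError
from .recording import TrialRecording

__all__ = [
    "MovementBounds",
    "savgol_derivative",
    "detect_movement_bounds",
    "movement_time",
    "joint_excursions",
    "com_displacement",
    "hand_position_at_contact",
    "reduce_trial",
    "reduce_many",
    "filter_trials",
    "aggregate_subject_condition",
    "SAVGOL_WINDOW",
    "SAVGOL_ORDER",
    "ONSET_THRESHOLD",
    "JOINTS",
]

log = logging.getLogger(__name__)

SAVGOL_WINDOW = 41
SAVGOL_ORDER = 4
ONSET_THRESHOLD = 0.05  # fraction of peak speed
JOINTS = ("ankle", "knee", "hip", "spine", "shoulder", "elbow")

#: standard dodgeball diameter (m); only level-1 block trials with this
#: diameter enter the statistical analysis
STANDARD_DIAMETER = 0.24


@dataclass(frozen=True)
class MovementBounds:
    """Onset / peak / contact sample indices from the 5%-of-peak criterion.

    ``truncated_start``/``truncated_end`` flag profiles whose tails never
    fall to the threshold on that side (the series boundary is returned).
    """

    onset_index: int
    peak_index: int
    contact_index: int
    peak_speed: float
    truncated_start: bool = False
    truncated_end: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_index <= self.peak_index <= self.contact_index):
            raise ValidationError("bounds must satisfy onset <= peak <= contact")
        if self.peak_speed <= 0:
            raise ValidationError("peak speed must be positive")


def savgol_derivative(
    series: np.ndarray,
    window: int = SAVGOL_WINDOW,
    order: int = SAVGOL_ORDER,
    rate: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothing and first derivative along axis 0.

    At each interior sample a degree-``order`` polynomial is fit in the
    least-squares sense to the window centred there; the returned values
    are the polynomial's value and first derivative at the centre, the
    latter scaled by the sampling rate.  Exact for global polynomials of
    degree <= ``order``.  NaNs propagate to every window they touch.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValidationError("window must be odd")
    if order >= window:
        raise ValidationError("order must be smaller than the window")
    if series.shape[0] < window:
        raise ValidationError(
            f"series of length {series.shape[0]} is shorter than the {window}-sample window"
        )
    smoothed = savgol_filter(series, window, order, deriv=0, axis=0, mode="interp")
    deriv = savgol_filter(series, window, order, deriv=1, delta=1.0 / rate, axis=0, mode="interp")
    return smoothed, deriv


def detect_movement_bounds(speed: np.ndarray, threshold: float = ONSET_THRESHOLD) -> MovementBounds:
    """Segment a speed profile by the <=5%-of-peak criterion.

    Peak = argmax; onset = first sample at-or-before the peak satisfying
    ``speed <= threshold * peak`` encountered searching backward; contact =
    the analogous forward search.  Equality counts as satisfying.  The
    result is invariant under uniform rescaling of the speed.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.ndim != 1:
        raise ValidationError("speed must be one-dimensional")
    if np.any(speed < -1e-12):
        raise ValidationError("speed must be non-negative")
    peak = int(np.argmax(speed))
    peak_speed = float(speed[peak])
    if peak_speed <= 0:
        raise DegenerateTrialError("all-zero speed profile")
    level = threshold * peak_speed
    below = speed <= level

    before = np.nonzero(below[: peak + 1])[0]
    truncated_start = before.size == 0
    onset = 0 if truncated_start else int(before[-1])

    after = np.nonzero(below[peak:])[0]
    truncated_end = after.size == 0
    contact = speed.size - 1 if truncated_end else peak + int(after[0])

    return MovementBounds(
        onset_index=onset,
        peak_index=peak,
        contact_index=contact,
        peak_speed=peak_speed,
        truncated_start=truncated_start,
        truncated_end=truncated_end,
    )


def movement_time(bounds: MovementBounds, rate: float = 100.0) -> float:
    """Onset-to-contact duration in milliseconds."""
    return (bounds.contact_index - bounds.onset_index) / rate * 1000.0


def joint_excursions(rec: TrialRecording, bounds: MovementBounds) -> dict[str, float]:
    """Per-joint change in angle (deg) from onset to contact, right side.

    Flexion increases are positive.
    """
    out = {}
    for joint in JOINTS:
        if joint not in rec.angles:
            raise ValidationError(f"recording is missing joint channel {joint!r}")
        ch = rec.angles[joint]
        out[joint] = float(ch[bounds.contact_index] - ch[bounds.onset_index])
    return out


def com_displacement(
    rec: TrialRecording, bounds: MovementBounds, params: SegmentParameterTable | None = None
) -> np.ndarray:
    """Whole-body COM displacement (cm, [AP, ML, vertical]) from onset to
    contact, from the segment-parameter combination of landmark positions."""
    if params is None:
        params = SegmentParameterTable()
    com = com_from_landmarks(rec.landmarks, params)
    return (com[bounds.contact_index] - com[bounds.onset_index]) * 100.0


def hand_position_at_contact(rec: TrialRecording, bounds: MovementBounds) -> np.ndarray:
    """Hand centroid minus ankle centroid at the contact sample (cm)."""
    for lm in ("hand_l", "hand_r", "ankle_l", "ankle_r"):
        if lm not in rec.landmarks:
            raise ValidationError(f"recording is missing landmark {lm!r}")
    delta = rec.hand_centroid()[bounds.contact_index] - rec.ankle_centroid()[bounds.contact_index]
    return delta * 100.0


def reduce_trial(
    rec: TrialRecording,
    params: SegmentParameterTable | None = None,
    window: int = SAVGOL_WINDOW,
    order: int = SAVGOL_ORDER,
    threshold: float = ONSET_THRESHOLD,
) -> dict:
    """Full per-trial reduction -> flat dict of measures plus metadata."""
    _, vel = savgol_derivative(rec.hand_centroid(), window=window, order=order, rate=rec.rate)
    speed = np.linalg.norm(vel, axis=1)
    bounds = detect_movement_bounds(speed, threshold=threshold)
    exc = joint_excursions(rec, bounds)
    com = com_displacement(rec, bounds, params)
    hand = hand_position_at_contact(rec, bounds)
    row = {
        "movement_time_ms": movement_time(bounds, rec.rate),
        "peak_speed_m_s": bounds.peak_speed,
        "onset_index": bounds.onset_index,
        "contact_index": bounds.contact_index,
        "truncated": bounds.truncated_start or bounds.truncated_end,
    }
    row.update({f"exc_{j}_deg": v for j, v in exc.items()})
    row.update({f"com_{ax}_cm": com[k] for k, ax in enumerate(("ap", "ml", "vert"))})
    row.update({f"hand_{ax}_cm": hand[k] for k, ax in enumerate(("ap", "ml", "vert"))})
    for key in ("subject_id", "sex", "perspective", "impact_height", "direction",
                "kind", "diameter", "level", "set_index", "ball_index", "success"):
        if key in rec.meta:
            row[key] = rec.meta[key]
    return row


def reduce_many(recordings, params: SegmentParameterTable | None = None, **kwargs) -> pd.DataFrame:
    """Reduce an iterable of recordings into a tidy per-trial table.

    Degenerate recordings are skipped with a logged warning.
    """
    rows, skipped = [], 0
    for rec in recordings:
        try:
            rows.append(reduce_trial(rec, params=params, **kwargs))
        except DegenerateTrialError as exc:
            skipped += 1
            log.warning("skipping degenerate trial %s: %s", rec.meta.get("trial_id", "?"), exc)
    if skipped:
        log.warning("skipped %d degenerate trial(s)", skipped)
    return pd.DataFrame(rows)


def filter_trials(measures: pd.DataFrame) -> pd.DataFrame:
    """Retain the analysis subset: block trials with the standard 24 cm
    dodgeball (level 1).  Duck trials and the smaller-ball levels are
    excluded; retention counts are logged."""
    if measures.empty:
        log.warning("filter_trials: empty input")
        return measures
    mask = pd.Series(True, index=measures.index)
    if "kind" in measures.columns:
        mask &= measures["kind"] == "block"
    if "diameter" in measures.columns:
        mask &= np.isclose(measures["diameter"].astype(float), STANDARD_DIAMETER)
    kept = measures[mask]
    log.info("filter_trials: retained %d of %d trials", len(kept), len(measures))
    if kept.empty:
        log.warning("filter_trials: no analyzable trials remain")
    return kept.reset_index(drop=True)


MEASURE_COLUMNS = (
    ["movement_time_ms"]
    + [f"exc_{j}_deg" for j in JOINTS]
    + [f"com_{ax}_cm" for ax in ("ap", "ml", "vert")]
    + [f"hand_{ax}_cm" for ax in ("ap", "ml", "vert")]
)


def aggregate_subject_condition(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, perspective, impact height) means of every measure,
    pooling launch directions; adds the per-cell trial count and, when a
    success flag is present, the cell success rate.

    Pooling is direction-balanced (mean of per-direction means) so the
    left/center/right launch locations carry equal weight even when the
    randomized set composition repeats some of them.
    """
    if measures.empty:
        raise ValidationError("cannot aggregate an empty measure table")
    keys = ["subject_id", "sex", "perspective", "impact_height"]
    cols = [c for c in MEASURE_COLUMNS if c in measures.columns]
    df = measures.copy()
    if "success" in df.columns:
        df["success_rate"] = df["success"].astype(float)
        cols = cols + ["success_rate"]
    inner_keys = keys + (["direction"] if "direction" in df.columns else [])
    per_dir = df.groupby(inner_keys, as_index=False, observed=True)[cols].mean()
    grouped = per_dir.groupby(keys, as_index=False, observed=True)[cols].mean()
    counts = df.groupby(keys, as_index=False, observed=True).size().rename(columns={"size": "n_trials"})
    return grouped.merge(counts, on=keys)
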