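"""Trial recordings: fixed-rate time series of joint angles and landmark
positions for one launched ball, with TSV + JSON-sidecar serialization.

A recording is written as one TSV (one row per sample; ``time_s``, the six
joint angles plus ``arm_azimuth`` in degrees, and x/y/z triplets for each
landmark in metres) plus ``<stem>.json`` holding the trial metadata.  The
reader reconstructs recordings losslessly (values serialized at %.10g).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .body import LANDMARK_NAMES, Posture
from .errors import ValidationError

__all__ = ["TrialRecording", "write_recording", "read_recording"]

ANGLE_CHANNELS = Posture.JOINTS + ("arm_azimuth",)


@dataclass
class TrialRecording:
    """Uniformly sampled (100 Hz default) kinematics of one trial.

    ``angles`` maps channel name -> (n,) degrees; ``landmarks`` maps
    landmark name -> (n, 3) metres in the shared lab frame.  ``meta``
    carries subject/condition bookkeeping (subject_id, sex, perspective,
    impact_height, direction, diameter, level, kind, seed, success, ...).
    """

    time: np.ndarray
    angles: dict[str, np.ndarray]
    landmarks: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    rate: float = 100.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValidationError("recording must have at least 2 samples")
        dt = np.diff(self.time)
        if not np.allclose(dt, 1.0 / self.rate, atol=1e-9):
            raise ValidationError("samples are not uniform at the stated rate")
        for name, arr in self.angles.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"angle channel {name!r} has shape {arr.shape}")
            self.angles[name] = arr
        for name, arr in self.landmarks.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise ValidationError(f"landmark {name!r} has shape {arr.shape}")
            self.landmarks[name] = arr

    @property
    def n_samples(self) -> int:
        return self.time.size

    def hand_centroid(self) -> np.ndarray:
        return 0.5 * (self.landmarks["hand_l"] + self.landmarks["hand_r"])

    def ankle_centroid(self) -> np.ndarray:
        return 0.5 * (self.landmarks["ankle_l"] + self.landmarks["ankle_r"])

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time_s": self.time}
        for name in ANGLE_CHANNELS:
            if name in self.angles:
                cols[f"angle_{name}_deg"] = self.angles[name]
        for name, arr in self.landmarks.items():
            for k, ax in enumerate("xyz"):
                cols[f"{name}_{ax}_m"] = arr[:, k]
        return pd.DataFrame(cols)


def write_recording(rec: TrialRecording, path: str | Path) -> Path:
    """Write the TSV and its JSON metadata sidecar; returns the TSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = path.with_suffix(".json")
    meta = dict(rec.meta)
    meta["rate_hz"] = rec.rate
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
    return path


def read_recording(path: str | Path) -> TrialRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    rate = float(meta.pop("rate_hz", 100.0))
    angles = {}
    for name in ANGLE_CHANNELS:
        col = f"angle_{name}_deg"
        if col in df.columns:
            angles[name] = df[col].to_numpy()
    landmarks = {}
    for name in LANDMARK_NAMES:
        cols = [f"{name}_{ax}_m" for ax in "xyz"]
        if all(c in df.columns for c in cols):
            landmarks[name] = df[cols].to_numpy()
    return TrialRecording(
        time=df["time_s"].to_numpy(), angles=angles, landmarks=landmarks, meta=meta, rate=rate
    )
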