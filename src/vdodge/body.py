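"""Anthropometric body model: segment lengths, forward kinematics, Euler
angles, and whole-body center of mass.

Axis convention (shared by every module)
----------------------------------------
Right-handed lab frame with

* ``x`` — antero-posterior, forward positive,
* ``y`` — mediolateral, leftward positive,
* ``z`` — vertical, up positive.

The floor is the plane of the ankle joints (``z = 0``).  All joint angles
are in degrees; all positions in metres unless a function says otherwise.

The kinematic chain is sagittal-dominant: ankle dorsiflexion, knee flexion,
hip flexion, lumbar (spine) flexion, shoulder flexion and elbow flexion act
in the x–z plane.  A single additional degree of freedom, ``arm_azimuth``,
yaws the arm about the vertical axis through the shoulder so that lateral
targets can be reached; it is the only out-of-plane component the generator
uses.  Shoulder flexion is measured relative to the trunk axis: 0 deg means
the arm hangs along the trunk, 90 deg means the arm is perpendicular to the
trunk pointing forward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Anthropometrics",
    "SegmentParameterTable",
    "Posture",
    "euler_decompose",
    "euler_recompose",
    "forward_kinematics",
    "whole_body_com",
    "com_from_landmarks",
    "LANDMARK_NAMES",
]

# fixed lateral offsets of bilateral landmarks from the midline (m)
ANKLE_HALF_STANCE = 0.11
SHOULDER_HALF_WIDTH = 0.18
ELBOW_HALF_WIDTH = 0.15
HAND_HALF_SEP = 0.11  # hands hold one ball between them

LANDMARK_NAMES = (
    "ankle_l",
    "ankle_r",
    "knee",
    "hip",
    "shoulder",
    "elbow",
    "hand_l",
    "hand_r",
)


@dataclass(frozen=True)
class Anthropometrics:
    """Per-subject segment lengths (m) and body mass (kg).

    Only ``hip_height``, ``trunk_length``, ``arm_length``, ``body_mass`` and
    ``sex`` are required; distal subdivisions default to fixed fractions of
    the composite lengths so that the chain is consistent by construction
    (shank + thigh = hip height, upper arm + forearm = arm length).
    ``arm_length`` is shoulder to hand centroid with the elbow extended, so
    the forearm segment here includes the hand.
    """

    hip_height: float
    trunk_length: float
    arm_length: float
    body_mass: float = 70.0
    sex: str = "female"
    shank_length: float | None = None
    thigh_length: float | None = None
    upper_arm_length: float | None = None
    forearm_length: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.shank_length is None:
            object.__setattr__(self, "shank_length", 0.53 * self.hip_height)
        if self.thigh_length is None:
            object.__setattr__(self, "thigh_length", self.hip_height - self.shank_length)
        if self.upper_arm_length is None:
            object.__setattr__(self, "upper_arm_length", 0.55 * self.arm_length)
        if self.forearm_length is None:
            object.__setattr__(self, "forearm_length", self.arm_length - self.upper_arm_length)
        for name in (
            "hip_height",
            "trunk_length",
            "arm_length",
            "body_mass",
            "shank_length",
            "thigh_length",
            "upper_arm_length",
            "forearm_length",
        ):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be a positive finite number, got {value}")
        if self.arm_length > self.upper_arm_length + self.forearm_length + 0.3:
            raise ValidationError("arm_length inconsistent with upper arm + forearm")
        if self.hip_height >= 1.5 * (self.shank_length + self.thigh_length):
            raise ValidationError("hip_height inconsistent with shank + thigh lengths")

    @classmethod
    def reference(cls, sex: str = "female") -> "Anthropometrics":
        """Typical young-adult anthropometrics by sex.

        Derived from standard stature proportions (hip height ~0.53 H,
        hip-to-shoulder trunk ~0.29 H, shoulder-to-hand-centroid ~0.39 H)
        applied to mean statures of 1.63 m (female) and 1.77 m (male).
        """
        if sex == "female":
            return cls(hip_height=0.86, trunk_length=0.47, arm_length=0.63,
                       body_mass=61.0, sex="female")
        if sex == "male":
            return cls(hip_height=0.94, trunk_length=0.51, arm_length=0.69,
                       body_mass=78.0, sex="male")
        raise ValidationError(f"unknown sex {sex!r}")


#: (mass fraction of whole body per instance, COM fraction from proximal end,
#:  proximal landmark, distal landmark, number of instances)
_DEFAULT_SEGMENTS = {
    # Winter-style dispersion of body mass; the trunk entry includes head
    # and neck, the forearm entry includes the hand (its distal landmark is
    # the hand centroid).  The foot is treated as a point mass at the ankle:
    # the feet stay planted so this only offsets the COM by a constant.
    "trunk": dict(mass_fraction=0.578, com_fraction=0.66, proximal="hip", distal="shoulder", count=1),
    "thigh": dict(mass_fraction=0.100, com_fraction=0.433, proximal="hip", distal="knee", count=2),
    "shank": dict(mass_fraction=0.0465, com_fraction=0.433, proximal="knee", distal="ankle_c", count=2),
    "foot": dict(mass_fraction=0.0145, com_fraction=0.5, proximal="ankle_c", distal="ankle_c", count=2),
    "upper_arm": dict(mass_fraction=0.028, com_fraction=0.436, proximal="shoulder", distal="elbow", count=2),
    "forearm_hand_l": dict(mass_fraction=0.022, com_fraction=0.682, proximal="elbow", distal="hand_l", count=1),
    "forearm_hand_r": dict(mass_fraction=0.022, com_fraction=0.682, proximal="elbow", distal="hand_r", count=1),
}


@dataclass(frozen=True)
class SegmentParameterTable:
    """Segment mass fractions and COM locations used for the whole-body COM.

    ``segments`` maps a segment name to a dict with ``mass_fraction`` (of
    whole-body mass, per instance), ``com_fraction`` (COM position along the
    segment from the proximal end, in [0, 1]), ``proximal``/``distal``
    landmark names and ``count`` (1 for midline, 2 for bilateral segments
    represented once by midline landmarks).
    """

    segments: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SEGMENTS.items()})

    def __post_init__(self) -> None:
        total = sum(s["mass_fraction"] * s.get("count", 1) for s in self.segments.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"segment mass fractions sum to {total}, expected 1")
        for name, seg in self.segments.items():
            if not 0.0 <= seg["com_fraction"] <= 1.0:
                raise ValidationError(f"segment {name}: com_fraction outside [0, 1]")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SegmentParameterTable":
        return cls(segments={k: dict(v) for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, path=None) -> "SegmentParameterTable":
        """Load from a YAML table; defaults to the packaged standard values."""
        import yaml

        if path is None:
            from importlib.resources import files

            text = (files("vdodge") / "data" / "segment_parameters.yaml").read_text()
        else:
            from pathlib import Path

            text = Path(path).read_text()
        return cls.from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class Posture:
    """Joint configuration (degrees) of the right-side sagittal chain.

    A designated neutral standing posture (all angles zero) maps to all-zero
    excursions.  ``arm_azimuth`` yaws the arm leftward-positive about the
    vertical axis through the shoulder.
    """

    ankle: float = 0.0
    knee: float = 0.0
    hip: float = 0.0
    spine: float = 0.0
    shoulder: float = 0.0
    elbow: float = 0.0
    arm_azimuth: float = 0.0

    JOINTS = ("ankle", "knee", "hip", "spine", "shoulder", "elbow")

    def __post_init__(self) -> None:
        for name in self.JOINTS + ("arm_azimuth",):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"joint angle {name} is not finite")
        if self.elbow < 0:
            raise ValidationError("elbow flexion must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, j) for j in self.JOINTS], dtype=float)

    def with_excursion(self, excursion: np.ndarray, arm_azimuth: float | None = None) -> "Posture":
        vals = self.as_array() + np.asarray(excursion, dtype=float)
        az = self.arm_azimuth if arm_azimuth is None else arm_azimuth
        return Posture(*vals, arm_azimuth=az)


# ---------------------------------------------------------------------------
# Euler angles
# ---------------------------------------------------------------------------

#: intrinsic rotation sequence: flexion-extension about y (mediolateral),
#: then lateral bending about x (antero-posterior), then axial rotation
#: about z (longitudinal).
_EULER_SEQ = "YXZ"
GIMBAL_LOCK_DEG = 89.999


def euler_recompose(flexion: float, lateral: float, axial: float) -> np.ndarray:
    """Rotation matrix from the three clinical angles (degrees), applied in
    the order flexion-extension -> lateral bending -> axial rotation."""
    return Rotation.from_euler(_EULER_SEQ, [flexion, lateral, axial], degrees=True).as_matrix()


def euler_decompose(rotation: np.ndarray) -> tuple[float, float, float, bool]:
    """Decompose a proper rotation into (flexion, lateral bending, axial
    rotation) degrees for the intrinsic y-x-z sequence.

    Returns a fourth element ``gimbal_flag``: True when lateral bending is
    within numerical reach of +/-90 deg, where the convention is to assign
    axial rotation 0 and fold the residual into flexion-extension.

    Raises
    ------
    ValidationError
        If the input is not orthonormal with determinant +1 (tol 1e-8).
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or abs(np.linalg.det(R) - 1.0) > 1e-8:
        raise ValidationError("rotation must be orthonormal with determinant +1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock; we flag instead
        flexion, lateral, axial = Rotation.from_matrix(R).as_euler(_EULER_SEQ, degrees=True)
    gimbal = abs(abs(lateral) - 90.0) <= (90.0 - GIMBAL_LOCK_DEG) + 1e-9
    if gimbal:
        axial = 0.0
    if flexion <= -180.0:
        flexion += 360.0
    return float(flexion), float(lateral), float(axial), bool(gimbal)


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def _dir(beta_deg: np.ndarray) -> np.ndarray:
    """Unit vector in the sagittal plane at angle beta from vertical,
    tilting toward +x (forward) for positive beta.  Shape (..., 3)."""
    b = np.deg2rad(np.asarray(beta_deg, dtype=float))
    return np.stack([np.sin(b), np.zeros_like(b), np.cos(b)], axis=-1)


def forward_kinematics_arrays(
    angles: dict[str, np.ndarray], anthro: Anthropometrics
) -> dict[str, np.ndarray]:
    """Vectorized chain: ``angles`` maps joint names (Posture.JOINTS plus
    optional ``arm_azimuth``) to arrays of a common shape; returns landmark
    positions of shape (..., 3).  Midline landmarks are on y = 0; bilateral
    landmarks carry fixed lateral offsets."""
    try:
        ankle = np.asarray(angles["ankle"], dtype=float)
        knee = np.asarray(angles["knee"], dtype=float)
        hip = np.asarray(angles["hip"], dtype=float)
        spine = np.asarray(angles["spine"], dtype=float)
        shoulder = np.asarray(angles["shoulder"], dtype=float)
        elbow = np.asarray(angles["elbow"], dtype=float)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(f"missing joint channel {exc}") from exc
    azimuth = np.asarray(angles.get("arm_azimuth", np.zeros_like(ankle)), dtype=float)

    for name in ("shank_length", "thigh_length", "trunk_length",
                 "upper_arm_length", "forearm_length"):
        if getattr(anthro, name) is None:  # pragma: no cover - dataclass fills these
            raise ConfigurationError(f"missing segment length {name}")

    beta_shank = ankle
    beta_thigh = ankle - knee
    beta_trunk = ankle - knee + hip + spine
    beta_ua = beta_trunk + 180.0 - shoulder
    beta_fa = beta_ua - elbow

    zero = np.zeros(ankle.shape + (3,))
    ankle_c = zero
    knee_p = ankle_c + anthro.shank_length * _dir(beta_shank)
    hip_p = knee_p + anthro.thigh_length * _dir(beta_thigh)
    shoulder_p = hip_p + anthro.trunk_length * _dir(beta_trunk)

    elbow_vec = anthro.upper_arm_length * _dir(beta_ua)
    hand_vec = elbow_vec + anthro.forearm_length * _dir(beta_fa)
    # yaw the whole arm about the vertical axis through the shoulder
    az = np.deg2rad(azimuth)
    ca, sa = np.cos(az), np.sin(az)

    def _yaw(v: np.ndarray) -> np.ndarray:
        x, y, z = v[..., 0], v[..., 1], v[..., 2]
        return np.stack([x * ca - y * sa, x * sa + y * ca, z], axis=-1)

    elbow_p = shoulder_p + _yaw(elbow_vec)
    hand_p = shoulder_p + _yaw(hand_vec)

    off = np.zeros(3)
    return {
        "ankle_l": ankle_c + np.array([0.0, ANKLE_HALF_STANCE, 0.0]),
        "ankle_r": ankle_c + np.array([0.0, -ANKLE_HALF_STANCE, 0.0]),
        "knee": knee_p + off,
        "hip": hip_p + off,
        "shoulder": shoulder_p + off,
        "elbow": elbow_p + off,
        "hand_l": hand_p + np.array([0.0, HAND_HALF_SEP, 0.0]),
        "hand_r": hand_p + np.array([0.0, -HAND_HALF_SEP, 0.0]),
    }


def forward_kinematics(posture: Posture, anthro: Anthropometrics) -> dict[str, np.ndarray]:
    """Landmark positions (m, lab frame) for a single posture.

    The chain is connected: consecutive landmarks are separated by their
    segment lengths.  With all joints at zero and the shoulder flexed to
    90 deg the hand centroid sits at height ``hip_height + trunk_length``
    and forward offset ``arm_length``.
    """
    angles = {j: np.asarray(getattr(posture, j)) for j in Posture.JOINTS}
    angles["arm_azimuth"] = np.asarray(posture.arm_azimuth)
    return forward_kinematics_arrays(angles, anthro)


def hand_centroid(landmarks: dict[str, np.ndarray]) -> np.ndarray:
    return 0.5 * (np.asarray(landmarks["hand_l"]) + np.asarray(landmarks["hand_r"]))


def ankle_centroid(landmarks: dict[str, np.ndarray]) -> np.ndarray:
    return 0.5 * (np.asarray(landmarks["ankle_l"]) + np.asarray(landmarks["ankle_r"]))


# ---------------------------------------------------------------------------
# Whole-body COM
# ---------------------------------------------------------------------------

def com_from_landmarks(
    landmarks: dict[str, np.ndarray], params: SegmentParameterTable
) -> np.ndarray:
    """Mass-fraction-weighted sum of segment COM positions.

    Linear in the landmark positions and equivariant under global
    translation.  ``landmarks`` values may carry leading time axes.
    """
    lm = dict(landmarks)
    if "ankle_c" not in lm and "ankle_l" in lm and "ankle_r" in lm:
        lm["ankle_c"] = 0.5 * (np.asarray(lm["ankle_l"]) + np.asarray(lm["ankle_r"]))
    com = None
    for name, seg in params.segments.items():
        try:
            prox = np.asarray(lm[seg["proximal"]], dtype=float)
            dist = np.asarray(lm[seg["distal"]], dtype=float)
        except KeyError as exc:
            raise ConfigurationError(
                f"segment {name!r} references missing landmark {exc}"
            ) from exc
        seg_com = prox + seg["com_fraction"] * (dist - prox)
        w = seg["mass_fraction"] * seg.get("count", 1)
        com = w * seg_com if com is None else com + w * seg_com
    if com is None:
        raise ConfigurationError("segment parameter table is empty")
    return com


def whole_body_com(
    posture: Posture, anthro: Anthropometrics, params: SegmentParameterTable | None = None
) -> np.ndarray:
    """Whole-body COM (m) of a posture: (antero-posterior, mediolateral,
    vertical) in the shared lab frame."""
    if params is None:
        params = SegmentParameterTable()
    return com_from_landmarks(forward_kinematics(posture, anthro), params)
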