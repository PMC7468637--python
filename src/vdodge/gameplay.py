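"""Virtual-dodgeball task model.

Impact heights are individualized per participant: a ball launched to IH1
(the highest height) can be blocked by flexing the lumbar spine 15 deg with
the shoulder flexed to 90 deg and the elbow extended, while IH3 (the
lowest) requires 60 deg of lumbar flexion under the same arm configuration.
Balls fly in a straight line at a constant 30 m/s from one of four
opponents toward an intended impact point on the player's frontal plane;
a colour cue 300 ms before release signals whether the ball must be
blocked (green) or ducked under (yellow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import Anthropometrics, Posture, forward_kinematics, hand_centroid
from .errors import ValidationError

__all__ = [
    "ImpactHeights",
    "BallLaunch",
    "RewardSchedule",
    "compute_impact_heights",
    "generate_set_schedule",
    "ball_position_at",
    "interception_check",
    "score_session",
    "DEFAULT_THETAS",
    "BALL_DIAMETERS",
    "BALL_SPEED",
    "DIRECTION_OFFSETS",
]

BALL_SPEED = 30.0  # m/s
CUE_LEAD = 0.300  # s
BALL_DIAMETERS = {0: 0.24, 1: 0.24, 2: 0.18, 3: 0.12}  # per game level (0 = practice)
#: lumbar flexion angles defining IH1..IH3.  Only the extremes are
#: prescribed by the task (15 and 60 deg); the middle angle defaults to
#: their midpoint and is configurable.
DEFAULT_THETAS = (15.0, 37.5, 60.0)
DIRECTION_OFFSETS = {"left": 0.20, "center": 0.0, "right": -0.20}  # m, y leftward+

MEAN_INTERVAL = 3.3  # s between launches
INTERVAL_JITTER = 0.3  # s

# opponents stand on the opposite free-throw line ~16.5 m away and shuffle
# 3 m fore-aft and 3 m left-right between launches
OPPONENT_BASE_X = 16.5
OPPONENT_YS = (-4.5, -1.5, 1.5, 4.5)
OPPONENT_FORE_AFT = 3.0
LAUNCH_HEIGHT = 1.5


@dataclass(frozen=True)
class ImpactHeights:
    """Individualized target heights (m, lab vertical) with their defining
    lumbar flexion angles (degrees).  IH1 > IH2 > IH3."""

    ih1: float
    ih2: float
    ih3: float
    thetas: tuple[float, float, float] = DEFAULT_THETAS

    def __post_init__(self) -> None:
        if not (self.ih1 > self.ih2 > self.ih3):
            raise ValidationError("impact heights must satisfy ih1 > ih2 > ih3")

    def as_dict(self) -> dict[str, float]:
        return {"IH1": self.ih1, "IH2": self.ih2, "IH3": self.ih3}


@dataclass(frozen=True)
class BallLaunch:
    """One scheduled ball: release time, straight-line flight geometry and
    the cue/kind bookkeeping needed for scoring and filtering."""

    launch_time: float
    origin: tuple[float, float, float]
    target_point: tuple[float, float, float]
    kind: str  # "block" | "duck"
    diameter: float
    ih_label: str  # "IH1" | "IH2" | "IH3" | "head"
    direction: str  # "left" | "center" | "right" (blocks; "center" for ducks)
    speed: float = BALL_SPEED
    cue_lead: float = CUE_LEAD
    level: int = 1
    set_index: int = 0
    ball_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("block", "duck"):
            raise ValidationError(f"unknown ball kind {self.kind!r}")
        if self.speed <= 0:
            raise ValidationError("ball speed must be positive")

    @property
    def cue_color(self) -> str:
        return "yellow" if self.kind == "duck" else "green"

    @property
    def flight_time(self) -> float:
        d = np.linalg.norm(np.subtract(self.target_point, self.origin))
        return float(d / self.speed)

    @property
    def arrival_time(self) -> float:
        return self.launch_time + self.flight_time


def compute_impact_heights(
    anthro: Anthropometrics, thetas: tuple[float, float, float] = DEFAULT_THETAS
) -> ImpactHeights:
    """Impact heights from lumbar flexion angles via the forward chain.

    With the shoulder flexed 90 deg relative to the trunk, the elbow
    extended, and lumbar flexion theta, the hand centroid sits at
    ``hip_height + trunk_length*cos(theta) - arm_length*sin(theta)``;
    that height is the intended impact height.
    """
    t1, t2, t3 = thetas
    if not (0.0 <= t1 < t2 < t3 <= 90.0):
        raise ValidationError(f"lumbar angles must satisfy 0 <= t1 < t2 < t3 <= 90, got {thetas}")
    heights = []
    for theta in (t1, t2, t3):
        lm = forward_kinematics(Posture(spine=theta, shoulder=90.0), anthro)
        heights.append(float(hand_centroid(lm)[2]))
    return ImpactHeights(*heights, thetas=(t1, t2, t3))


def _head_height(anthro: Anthropometrics) -> float:
    # ducks target the avatar's head, ~0.25 m above the shoulder
    return anthro.hip_height + anthro.trunk_length + 0.25


def generate_set_schedule(
    anthro: Anthropometrics,
    level: int,
    rng_seed,
    set_index: int = 0,
    t0: float = 0.0,
    thetas: tuple[float, float, float] = DEFAULT_THETAS,
    jitter: str = "uniform",
) -> list[BallLaunch]:
    """One 15-ball set: 12 block balls distributed over the three impact
    heights — at least one for every (impact height x direction) cell, the
    remaining three drawn uniformly from those cells — plus 3 duck balls
    aimed at the head.  Launch order is permuted per set; inter-launch
    intervals are 3.3 s with 0.3 s jitter (uniform on [3.0, 3.6] s by
    default, or normal(3.3, 0.3) with ``jitter="normal"``).
    """
    if level not in BALL_DIAMETERS:
        raise ValidationError(f"unknown game level {level}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    diameter = BALL_DIAMETERS[level]
    ih = compute_impact_heights(anthro, thetas)
    ih_map = ih.as_dict()

    cells = [(label, d) for label in ("IH1", "IH2", "IH3") for d in ("left", "center", "right")]
    extra_idx = rng.integers(0, len(cells), size=3)
    block_cells = cells + [cells[i] for i in extra_idx]
    balls: list[tuple[str, str, str]] = [("block",) + c for c in block_cells]
    balls += [("duck", "head", "center")] * 3
    order = rng.permutation(len(balls))

    if jitter == "uniform":
        intervals = rng.uniform(MEAN_INTERVAL - INTERVAL_JITTER, MEAN_INTERVAL + INTERVAL_JITTER, size=len(balls))
    elif jitter == "normal":
        intervals = rng.normal(MEAN_INTERVAL, INTERVAL_JITTER, size=len(balls))
    else:
        raise ValidationError(f"unknown jitter model {jitter!r}")
    launch_times = t0 + np.cumsum(intervals)

    schedule = []
    for i, k in enumerate(order):
        kind, label, direction = balls[k]
        if kind == "duck":
            target = (0.0, 0.0, _head_height(anthro))
        else:
            target = (0.0, DIRECTION_OFFSETS[direction], ih_map[label])
        origin_y = OPPONENT_YS[rng.integers(0, 4)]
        origin_x = OPPONENT_BASE_X + OPPONENT_FORE_AFT * rng.integers(0, 2)
        schedule.append(
            BallLaunch(
                launch_time=float(launch_times[i]),
                origin=(float(origin_x), float(origin_y), LAUNCH_HEIGHT),
                target_point=target,
                kind=kind,
                diameter=diameter,
                ih_label=label,
                direction=direction,
                level=level,
                set_index=set_index,
                ball_index=i,
            )
        )
    return schedule


def ball_position_at(launch: BallLaunch, t: float) -> np.ndarray:
    """Straight-line constant-speed flight position at time ``t`` (s)."""
    if t < launch.launch_time:
        raise ValidationError("t precedes the launch time")
    origin = np.asarray(launch.origin, dtype=float)
    target = np.asarray(launch.target_point, dtype=float)
    d = target - origin
    dist = np.linalg.norm(d)
    if dist == 0:
        return origin
    return origin + d / dist * launch.speed * (t - launch.launch_time)


def interception_check(
    ball: BallLaunch,
    held_ball_center,
    held_ball_diameter: float,
    t: float,
) -> bool:
    """True iff the held ball touches the oncoming ball at time ``t`` before
    the oncoming ball reaches the avatar's torso plane (boundary contact and
    exact arrival both count)."""
    if t > ball.arrival_time:
        return False
    pos = ball_position_at(ball, t)
    dist = float(np.linalg.norm(pos - np.asarray(held_ball_center, dtype=float)))
    return dist <= 0.5 * (ball.diameter + held_ball_diameter)


@dataclass(frozen=True)
class RewardSchedule:
    """Per-level block rewards (currency units) and miss penalties.

    The starting balance is derived so that failing every scheduled ball
    leaves a balance of exactly zero.  Penalties are not prescribed by the
    task description; by default a miss costs the level's block reward.
    """

    rewards: dict = field(default_factory=lambda: {0: 1.0, 1: 2.0, 2: 5.0, 3: 10.0})
    penalties: dict | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rewards.values()):
            raise ValidationError("rewards must be non-negative")
        if self.penalties is None:
            object.__setattr__(self, "penalties", dict(self.rewards))

    def starting_balance(self, scheduled_levels) -> float:
        return float(sum(self.penalties[lv] for lv in scheduled_levels))


def score_session(outcomes, schedule: RewardSchedule, scheduled_levels=None) -> float:
    """Final cash balance for a session.

    ``outcomes`` is a sequence of ``(success, level)`` pairs, one per
    scheduled ball.  balance = starting_balance + sum(success * reward)
    - sum(failure * penalty); an all-fail session ends at exactly 0.
    """
    outcomes = list(outcomes)
    if scheduled_levels is None:
        scheduled_levels = [lv for _, lv in outcomes]
    else:
        scheduled_levels = list(scheduled_levels)
        if len(scheduled_levels) != len(outcomes):
            raise ValidationError(
                f"{len(outcomes)} outcomes for {len(scheduled_levels)} scheduled balls"
            )
    balance = schedule.starting_balance(scheduled_levels)
    for success, level in outcomes:
        if success:
            balance += schedule.rewards[level]
        else:
            balance -= schedule.penalties[level]
    return float(balance)
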