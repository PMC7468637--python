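"""Condition-effect tables for the synthetic cohort.

An :class:`EffectTable` holds, for every (perspective x impact height x
sex) cell, the generating means of the quantities the reduction stage
measures — measured movement time, hand position at ball contact
(absolute, relative to the ankle centroid), antero-posterior whole-body
COM displacement, interception success probability — together with
between-subject and within-subject (trial) noise scales.

The default table transcribes the study's reported condition means.  Most
are printed as marginals (over perspective or over impact height); cells
are filled additively, ``cell = marginal_row + marginal_col - grand
mean``, which reproduces every printed marginal exactly under equal cell
weights.  Quantities never reported per cell (e.g. most joint excursions)
are imputed and documented as such.

Joint excursions are not free parameters: the contact posture must
actually place the hand and COM at the configured values for a given body.
``calibrate`` therefore solves, per cell, a redundancy-resolving inverse
kinematics problem (soft-anchored to sagittally plausible reference
excursions, with the elbow pinned to its reported values) and stores the
solved excursions back into the table.  Those solved values are the
configured truth that a noise-free pipeline run must recover; mediolateral
and vertical COM displacement are emergent from the solved postures and
recorded as derived values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .body import Anthropometrics, Posture
from .errors import ValidationError

__all__ = [
    "EffectCell",
    "EffectTable",
    "default_effect_table",
    "PERSPECTIVES",
    "IMPACT_HEIGHTS",
    "SEXES",
    "CONFIGURED_SE",
    "READY_STANCE",
]

PERSPECTIVES = ("first", "third")
IMPACT_HEIGHTS = ("IH1", "IH2", "IH3")
SEXES = ("female", "male")

#: stance from which every interception movement starts: a ready position
#: with the ball held in front of the chest and a slight crouch, matching
#: ongoing gameplay (movement onset is detected mid-game, not from rigid
#: quiet standing)
READY_STANCE = Posture(ankle=4.0, knee=8.0, hip=5.0, spine=10.0, shoulder=70.0, elbow=25.0)

# ---------------------------------------------------------------------------
# reported condition means (marginals) and their standard errors
# ---------------------------------------------------------------------------

MT_IH = {"IH1": 574.0, "IH2": 648.0, "IH3": 671.0}  # ms
HAND_AP_PERSP = {"first": 76.7, "third": 69.1}  # cm
HAND_AP_IH = {"IH1": 75.0, "IH2": 75.7, "IH3": 68.1}
HAND_VERT_IH = {"IH1": 113.9, "IH2": 92.0, "IH3": 47.7}
HAND_VERT_IH3_PERSP = {"first": 45.0, "third": 50.4}  # interaction cell
#: sex x impact-height interaction on vertical hand position: females
#: higher at IH1/IH2; offsets chosen to keep the pooled marginal intact
HAND_VERT_SEX_OFFSET = {"IH1": 1.15, "IH2": 1.45, "IH3": 0.0}  # +female / -male
COM_AP_PERSP = {"first": 2.1, "third": 1.2}  # cm
COM_AP_IH = {"IH1": 1.9, "IH2": 1.7, "IH3": 1.5}
SUCCESS_PERSP = {"first": 0.955, "third": 0.915}
SUCCESS_IH = {"IH1": 0.953, "IH2": 0.968, "IH3": 0.884}
#: male elbow excursion by perspective (sex x perspective interaction);
#: the female value is imputed (no interaction reported)
ELBOW_MALE_PERSP = {"first": 11.7, "third": 10.8}
ELBOW_FEMALE = 9.5
ELBOW_IH_OFFSET = {"IH1": -0.5, "IH2": 0.0, "IH3": 0.5}

#: standard errors of the reported marginals (cohort n = 29) — used as the
#: recovery tolerance scale for stochastic end-to-end checks
CONFIGURED_SE = {
    "mt_IH1": 40.0, "mt_IH2": 27.0, "mt_IH3": 23.0,
    "hand_ap_first": 2.2, "hand_ap_third": 2.7,
    "hand_ap_IH1": 2.2, "hand_ap_IH2": 2.4, "hand_ap_IH3": 2.6,
    "hand_vert_IH1": 1.8, "hand_vert_IH2": 2.0, "hand_vert_IH3": 1.9,
    "com_ap_first": 0.3, "com_ap_third": 0.3,
    "success_IH1": 1.1, "success_IH2": 1.0, "success_IH3": 2.5,  # percentage points
}

N_COHORT = 29  # 15 male, 14 female

#: between-subject SDs of the generator's subject-level target offsets.
#: Movement time uses the SE-reconstructed cohort SD (SE * sqrt(n)); the
#: position SDs are deliberately smaller than their SE-reconstructed
#: counterparts because in a real cohort most of the between-subject spread
#: in hand/COM position reflects anthropometric scale, while the generator
#: applies offsets directly to reach targets that must stay inside every
#: subject's reachable workspace.  Units match the cell quantities.
DEFAULT_BETWEEN_SD = {
    "mt_ms": 40.0 * np.sqrt(N_COHORT),
    "hand_ap_cm": 2.0,
    "hand_ml_cm": 2.0,
    "hand_vert_cm": 2.0,
    "com_ap_cm": 0.5,
    "success_p": 0.03,
}

#: trial-to-trial SDs (within a subject and cell); not reported, set to
#: values typical of repeated whole-body reaches
DEFAULT_WITHIN_SD = {
    "mt_ms": 50.0,
    "hand_ap_cm": 1.2,
    "hand_ml_cm": 1.5,
    "hand_vert_cm": 1.2,
    "com_ap_cm": 0.3,
    "success_p": 0.0,  # success is Bernoulli; its trial noise is inherent
}

#: sagittally plausible reference excursions (deg) used as the soft anchor
#: of the redundancy resolution, by impact height; first-person adds a
#: small whole-chain increment, matching the reported direction of the
#: perspective effect
_E_REF_IH = {
    "IH1": dict(ankle=3.0, knee=5.0, hip=6.0, spine=10.0, shoulder=18.0),
    "IH2": dict(ankle=6.0, knee=12.0, hip=14.0, spine=22.0, shoulder=20.0),
    "IH3": dict(ankle=10.0, knee=24.0, hip=26.0, spine=40.0, shoulder=22.0),
}
_E_REF_FIRST_BUMP = dict(ankle=1.0, knee=2.0, hip=2.0, spine=3.0, shoulder=3.0)


@dataclass(frozen=True)
class EffectCell:
    """Generating means for one (perspective, impact height, sex) cell.

    ``excursions`` and the derived COM components are filled by
    :meth:`EffectTable.calibrate`; until then the cell only prescribes its
    targets and the reference excursions anchoring the redundancy
    resolution.
    """

    perspective: str
    impact_height: str
    sex: str
    mt_ms: float
    hand_ap_cm: float
    hand_ml_cm: float
    hand_vert_cm: float
    com_ap_cm: float
    success_p: float
    e_ref: dict = field(default_factory=dict)  # reference excursions (deg)
    elbow_deg: float = 10.0  # pinned elbow excursion (deg)
    # filled by calibration:
    excursions: dict | None = None  # solved excursions (deg), pooled over directions
    arm_azimuth_deg: float = 0.0
    com_ml_cm: float | None = None  # derived, pooled over directions
    com_vert_cm: float | None = None  # derived, pooled over directions
    direction_warm: dict | None = None  # per-direction solver warm starts

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_p <= 1.0:
            raise ValidationError("success probability must lie in [0, 1]")
        if self.mt_ms <= 0:
            raise ValidationError("movement time must be positive")


@dataclass(frozen=True)
class EffectTable:
    """All condition cells plus the cohort noise model.

    ``noise_scale`` multiplies every SD (0 gives the deterministic,
    noise-free cohort used for exactness checks).
    """

    cells: dict
    between_sd: dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_SD))
    within_sd: dict = field(default_factory=lambda: dict(DEFAULT_WITHIN_SD))
    ready_stance: Posture = READY_STANCE
    calibrated: bool = False

    def __post_init__(self) -> None:
        for key in self.cells:
            p, ih, sex = key
            if p not in PERSPECTIVES or ih not in IMPACT_HEIGHTS or sex not in SEXES:
                raise ValidationError(f"unknown cell key {key}")
        if any(v < 0 for v in self.between_sd.values()) or any(
            v < 0 for v in self.within_sd.values()
        ):
            raise ValidationError("noise SDs must be non-negative")
        for ih_hi, ih_lo in (("IH1", "IH2"), ("IH2", "IH3")):
            for p in PERSPECTIVES:
                for s in SEXES:
                    a, b = (p, ih_hi, s), (p, ih_lo, s)
                    if a in self.cells and b in self.cells:
                        if not self.cells[a].hand_vert_cm > self.cells[b].hand_vert_cm:
                            raise ValidationError(
                                "vertical hand position must decrease from IH1 to IH3"
                            )

    def cell(self, perspective: str, impact_height: str, sex: str) -> EffectCell:
        try:
            return self.cells[(perspective, impact_height, sex)]
        except KeyError as exc:
            raise ValidationError(f"no effect cell for {exc}") from exc

    def marginal(self, quantity: str, perspective: str | None = None,
                 impact_height: str | None = None) -> float:
        """Equal-weight mean of a cell quantity over the unspecified factors."""
        vals = [
            getattr(c, quantity)
            for (p, ih, s), c in self.cells.items()
            if (perspective is None or p == perspective)
            and (impact_height is None or ih == impact_height)
        ]
        return float(np.mean(vals))

    def scaled(self, noise_scale: float) -> "EffectTable":
        """Copy with every SD multiplied by ``noise_scale``."""
        return replace(
            self,
            between_sd={k: v * noise_scale for k, v in self.between_sd.items()},
            within_sd={k: v * noise_scale for k, v in self.within_sd.items()},
        )

    def calibrate(self, anthros: dict[str, Anthropometrics] | None = None) -> "EffectTable":
        """Solve every cell's contact posture and store the excursions and
        derived COM components; returns a calibrated copy.

        ``anthros`` maps sex -> the reference body used for the solve (the
        cohort defaults when omitted).
        """
        from .gameplay import DIRECTION_OFFSETS
        from .synth import solve_contact_posture  # local import: avoid cycle

        if anthros is None:
            anthros = {s: Anthropometrics.reference(s) for s in SEXES}
        new_cells = {}
        for key, cell in self.cells.items():
            solutions, warms = {}, {}
            warm = None
            for direction in ("center", "left", "right"):
                sol = solve_contact_posture(
                    anthros[cell.sex],
                    self.ready_stance,
                    targets=dict(
                        hand_ap_cm=cell.hand_ap_cm,
                        hand_ml_cm=cell.hand_ml_cm + DIRECTION_OFFSETS[direction] * 100.0,
                        hand_vert_cm=cell.hand_vert_cm,
                        com_ap_cm=cell.com_ap_cm,
                    ),
                    e_ref=cell.e_ref,
                    elbow_deg=cell.elbow_deg,
                    cell_name=f"{key}/{direction}",
                    warm=warm,
                )
                solutions[direction] = sol
                warms[direction] = tuple(
                    [sol.excursions[j] for j in ("ankle", "knee", "hip", "spine", "shoulder")]
                    + [sol.arm_azimuth_deg]
                )
                if direction == "center":
                    warm = np.asarray(warms["center"])
            pooled_exc = {
                j: float(np.mean([s.excursions[j] for s in solutions.values()]))
                for j in solutions["center"].excursions
            }
            new_cells[key] = replace(
                cell,
                excursions=pooled_exc,
                arm_azimuth_deg=solutions["center"].arm_azimuth_deg,
                com_ml_cm=float(np.mean([s.com_ml_cm for s in solutions.values()])),
                com_vert_cm=float(np.mean([s.com_vert_cm for s in solutions.values()])),
                direction_warm=warms,
            )
        return replace(self, cells=new_cells, calibrated=True)


def load_effect_table(path) -> EffectTable:
    """Default table with YAML overrides applied.

    The file may carry ``between_sd`` / ``within_sd`` (quantity -> SD) and
    ``cells`` (``"perspective/IH/sex"`` -> field overrides for that cell,
    e.g. ``mt_ms``, ``hand_ap_cm``, ``success_p``, ``elbow_deg``).
    """
    import yaml
    from pathlib import Path

    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - {"between_sd", "within_sd", "cells"}
    if unknown:
        raise ValidationError(f"unknown effect-table keys: {sorted(unknown)}")
    table = default_effect_table()
    between = {**table.between_sd, **(data.get("between_sd") or {})}
    within = {**table.within_sd, **(data.get("within_sd") or {})}
    cells = dict(table.cells)
    for key, overrides in (data.get("cells") or {}).items():
        parts = tuple(str(key).split("/"))
        if parts not in cells:
            raise ValidationError(f"unknown effect cell {key!r}")
        cells[parts] = replace(cells[parts], **overrides)
    return replace(table, cells=cells, between_sd=between, within_sd=within)


def default_effect_table() -> EffectTable:
    """The study-derived effect table (uncalibrated).

    Cells combine the printed perspective and impact-height marginals
    additively; reported interactions (vertical hand position at IH3 by
    perspective, sex offsets at IH1/IH2, the male elbow-by-perspective
    effect) override the additive fill.
    """
    # grand means taken over the impact-height marginals so that the
    # perspective marginals — the primary recovery targets — are exact
    hand_ap_grand = float(np.mean(list(HAND_AP_IH.values())))
    com_ap_grand = float(np.mean(list(COM_AP_IH.values())))
    success_grand = float(np.mean(list(SUCCESS_IH.values())))

    cells = {}
    for p in PERSPECTIVES:
        for ih in IMPACT_HEIGHTS:
            for sex in SEXES:
                hand_vert = HAND_VERT_IH[ih]
                if ih == "IH3":
                    hand_vert = HAND_VERT_IH3_PERSP[p]
                hand_vert += HAND_VERT_SEX_OFFSET[ih] * (1 if sex == "female" else -1)
                elbow = (
                    ELBOW_MALE_PERSP[p] if sex == "male" else ELBOW_FEMALE
                ) + ELBOW_IH_OFFSET[ih]
                e_ref = dict(_E_REF_IH[ih])
                if p == "first":
                    e_ref = {j: v + _E_REF_FIRST_BUMP[j] for j, v in e_ref.items()}
                cells[(p, ih, sex)] = EffectCell(
                    perspective=p,
                    impact_height=ih,
                    sex=sex,
                    mt_ms=MT_IH[ih],
                    hand_ap_cm=HAND_AP_PERSP[p] + HAND_AP_IH[ih] - hand_ap_grand,
                    hand_ml_cm=0.0,
                    hand_vert_cm=hand_vert,
                    com_ap_cm=COM_AP_PERSP[p] + COM_AP_IH[ih] - com_ap_grand,
                    success_p=min(1.0, SUCCESS_PERSP[p] + SUCCESS_IH[ih] - success_grand),
                    e_ref=e_ref,
                    elbow_deg=elbow,
                )
    return EffectTable(cells=cells)
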