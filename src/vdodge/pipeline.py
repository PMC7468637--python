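"""Pipeline orchestration: simulate -> reduce -> analyze.

Everything is deterministic given the master seed.  Randomness is split
through documented ``numpy.random.SeedSequence`` streams:

* ``[seed, 0xA0]`` — cohort anthropometrics (in :func:`vdodge.synth.sample_cohort`),
* ``[seed, i, 1]`` — subject ``i``'s random intercepts,
* ``[seed, i, 2 + s]`` — subject ``i``'s session ``s`` (schedules, trial
  noise, success draws).

Perspective order is counterbalanced by subject index (even indices play
first-person first).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effects import EffectTable, default_effect_table, load_effect_table
from .errors import ValidationError
from .recording import TrialRecording, read_recording, write_recording
from .reduction import (
    JOINTS,
    aggregate_subject_condition,
    filter_trials,
    reduce_many,
)
from .stats import lsd_posthoc, rm_mixed_anova, simple_effects
from .synth import Subject, draw_subject_offsets, sample_cohort, synthesize_session

__all__ = [
    "PipelineConfig",
    "simulate_cohort",
    "run_simulate",
    "run_reduce",
    "run_analyze",
    "format_report",
    "DEPENDENT_MEASURES",
]

log = logging.getLogger(__name__)

DEPENDENT_MEASURES = (
    ["movement_time_ms"]
    + [f"hand_{ax}_cm" for ax in ("ap", "ml", "vert")]
    + [f"exc_{j}_deg" for j in JOINTS]
    + [f"com_{ax}_cm" for ax in ("ap", "ml", "vert")]
    + ["success_rate"]
)


@dataclass
class PipelineConfig:
    """Master configuration for a reproducible pipeline run."""

    seed: int = 1
    n_subjects: int = 29
    noise_scale: float = 1.0
    levels: tuple = (1, 2, 3)
    sets_per_level: int = 2
    savgol_window: int = 41
    savgol_order: int = 4
    onset_threshold: float = 0.05
    effect_table: str | None = None  # YAML overrides for the effect table
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.onset_threshold < 1.0):
            raise ValidationError("onset threshold must lie in (0, 1)")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValidationError("savgol window must be odd and larger than the order")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValidationError("seed must be a non-negative integer")
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        self.levels = tuple(int(v) for v in self.levels)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def perspective_order(subject_index: int) -> tuple[str, str]:
    return ("first", "third") if subject_index % 2 == 0 else ("third", "first")


def simulate_cohort(
    config: PipelineConfig, table: EffectTable | None = None
) -> tuple[list[Subject], list[TrialRecording], pd.DataFrame]:
    """Simulate the full cohort in memory.

    Returns (cohort, recordings, event log).  The effect table defaults to
    the calibrated study-derived table scaled by ``config.noise_scale``.
    """
    if table is None:
        base = (
            load_effect_table(config.effect_table)
            if config.effect_table
            else default_effect_table()
        )
        table = base.scaled(config.noise_scale)
    if not table.calibrated:
        table = table.calibrate()
    cohort = sample_cohort(config.n_subjects, config.seed, noise_scale=config.noise_scale)
    recordings: list[TrialRecording] = []
    events = []
    for subj in cohort:
        rng_b = np.random.default_rng(np.random.SeedSequence([config.seed, subj.index, 1]))
        offsets = draw_subject_offsets(rng_b, table)
        for s_idx, persp in enumerate(perspective_order(subj.index)):
            recs, ev = synthesize_session(
                subj,
                persp,
                table,
                seed=np.random.SeedSequence([config.seed, subj.index, 2 + s_idx]),
                subject_offsets=offsets,
                levels=config.levels,
                sets_per_level=config.sets_per_level,
                session_index=s_idx,
            )
            recordings.extend(recs)
            events.extend(ev)
    log.info(
        "simulated %d subjects, %d recordings, %d scheduled balls",
        len(cohort), len(recordings), len(events),
    )
    return cohort, recordings, pd.DataFrame(events)


def run_simulate(config: PipelineConfig, out_dir) -> Path:
    """Simulate and write recordings + manifest + event log to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, recordings, events = simulate_cohort(config)
    manifest_rows = []
    for rec in recordings:
        rel = Path("recordings") / rec.meta["subject_id"] / rec.meta["perspective"] / (
            rec.meta["trial_id"] + ".tsv"
        )
        write_recording(rec, out / rel)
        row = {"path": str(rel)}
        row.update({k: rec.meta[k] for k in (
            "subject_id", "sex", "perspective", "impact_height", "direction",
            "kind", "diameter", "level", "set_index", "ball_index", "success",
        )})
        manifest_rows.append(row)
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    cohort_rows = [
        dict(subject_id=s.subject_id, sex=s.sex, index=s.index,
             perspective_order="/".join(perspective_order(s.index)),
             **{k: getattr(s.anthro, k) for k in (
                 "hip_height", "trunk_length", "arm_length", "body_mass")})
        for s in cohort
    ]
    pd.DataFrame(cohort_rows).to_csv(out / "cohort.csv", index=False)
    (out / "run_info.json").write_text(json.dumps(asdict(config), default=list, indent=1))
    return out / "manifest.csv"


def run_reduce(
    manifest: str | Path | list[TrialRecording],
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce recordings (from a manifest CSV or in-memory list) into the
    per-trial measure table and the per-(subject, perspective, IH) means.

    Writes ``trial_measures.csv`` and ``cell_means.csv`` when ``out_dir``
    is given.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, (str, Path)):
        mdf = pd.read_csv(manifest)
        root = Path(manifest).parent
        recordings = (read_recording(root / p) for p in mdf["path"])
    else:
        recordings = manifest
    measures = reduce_many(
        recordings,
        window=config.savgol_window,
        order=config.savgol_order,
        threshold=config.onset_threshold,
    )
    kept = filter_trials(measures)
    if kept.empty:
        log.warning("no analyzable trials after filtering")
        agg = pd.DataFrame()
    else:
        agg = aggregate_subject_condition(kept)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        measures.to_csv(out / "trial_measures.csv", index=False)
        agg.to_csv(out / "cell_means.csv", index=False)
    return measures, agg


def condition_marginals(cell_means: pd.DataFrame) -> dict:
    """Equal-weight condition marginals of the per-cell means table.

    Each subject's cells are averaged first (so every subject and every
    cell carries equal weight), then pooled: per-perspective marginals for
    hand position, COM displacement and success, and per-impact-height
    marginals for movement time and vertical hand position.  Success is
    reported in percent.
    """
    out = {}
    for persp in ("first", "third"):
        sub = cell_means[cell_means["perspective"] == persp]
        m = sub.groupby("subject_id", observed=True).mean(numeric_only=True)
        out[f"hand_ap_{persp}"] = float(m["hand_ap_cm"].mean())
        out[f"com_ap_{persp}"] = float(m["com_ap_cm"].mean())
        if "success_rate" in m:
            out[f"success_{persp}"] = float(100.0 * m["success_rate"].mean())
    for ih in ("IH1", "IH2", "IH3"):
        sub = cell_means[cell_means["impact_height"] == ih]
        m = sub.groupby("subject_id", observed=True).mean(numeric_only=True)
        out[f"mt_{ih}"] = float(m["movement_time_ms"].mean())
        out[f"hand_vert_{ih}"] = float(m["hand_vert_cm"].mean())
        if "success_rate" in m:
            out[f"success_{ih}"] = float(100.0 * m["success_rate"].mean())
    return out


def run_analyze(cell_means: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Mixed RM-ANOVA per dependent measure, with LSD post hocs for the
    3-level impact-height factor and simple effects for significant
    perspective-by-impact-height interactions."""
    required = {"subject_id", "sex", "perspective", "impact_height"}
    missing = required - set(cell_means.columns)
    if missing:
        raise ValidationError(f"cell-means table is missing columns {sorted(missing)}")
    results = {}
    for dv in DEPENDENT_MEASURES:
        if dv not in cell_means.columns:
            continue
        anova = rm_mixed_anova(cell_means, dv)
        block = {"anova": anova, "posthoc": {}, "simple_effects": None}
        for factor in ("perspective", "impact_height"):
            if np.isfinite(anova.effect(factor).F):
                block["posthoc"][factor] = lsd_posthoc(cell_means, dv, factor)
        inter = anova.effect("perspective x impact_height")
        if np.isfinite(inter.F) and inter.p < alpha:
            block["simple_effects"] = simple_effects(
                cell_means, dv, "perspective", "impact_height"
            )
        results[dv] = block
    return results


def format_report(results: dict, alpha: float = 0.05) -> str:
    """Plain-text analysis report, one block per dependent measure."""
    lines = ["Mixed repeated-measures analysis", "=" * 34, ""]
    for dv, block in results.items():
        anova = block["anova"]
        lines.append(f"[{dv}]  (n = {anova.n_subjects})")
        for _, r in anova.effects.iterrows():
            star = " *" if (np.isfinite(r.p) and r.p < alpha) else ""
            lines.append(
                f"  {r['effect']:<36} F({r.df1:.0f},{r.df2:.0f}) = {r.F:8.3f}  p = {r.p:.4f}{star}"
            )
        for factor, ph in block["posthoc"].items():
            for _, r in ph.iterrows():
                lines.append(
                    f"    LSD {factor}: {r.level_a} - {r.level_b} = {r.difference:+.3f}"
                    f"  t({r.df:.0f}) = {r.t:.3f}, p = {r.p:.4f}"
                )
        if block["simple_effects"] is not None:
            for _, r in block["simple_effects"].iterrows():
                lines.append(
                    f"    simple effect {r['effect']}: F({r.df1:.0f},{r.df2:.0f})"
                    f" = {r.F:.3f}, p = {r.p:.4f}"
                )
        lines.append("")
    return "\n".join(lines)
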