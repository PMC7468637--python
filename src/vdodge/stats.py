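"""Mixed repeated-measures statistics.

The core analysis is a 3-way mixed-design ANOVA with one between-subject
factor (sex) and two within-subject factors (avatar perspective, 2 levels;
impact height, 3 levels), computed by the classical univariate split-plot
decomposition: per-subject cell means are projected onto an orthonormal
within-subject contrast basis, and each within-subject stratum (effect,
its interaction with sex, and its subject-by-factor error) is analyzed by
an ordinary least-squares regression of the contrast scores on the
between-subject design.  Effect sums of squares are Type III (unweighted
cell means), which matters for the slightly unbalanced 15/14 sex split.

Companions: Fisher's-LSD pairwise comparisons sharing the ANOVA error
term, simple-effects decomposition of interactions, Bonferroni-corrected
paired t-tests (perceived-workload scales), and the noncentral-F power
computation for a one-group repeated-measures within factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "AnovaResult",
    "rm_mixed_anova",
    "lsd_posthoc",
    "simple_effects",
    "paired_t_bonferroni",
    "rm_power",
    "min_n_rm_power",
    "WITHIN_FACTORS",
]

WITHIN_FACTORS = {"perspective": ("first", "third"), "impact_height": ("IH1", "IH2", "IH3")}
BETWEEN_FACTOR = "sex"


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast rows (normalized Helmert)."""
    raw = np.zeros((k - 1, k))
    for i in range(k - 1):
        raw[i, : i + 1] = 1.0
        raw[i, i + 1] = -(i + 1)
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def _pivot(table: pd.DataFrame, dv: str):
    """Subjects x (perspective x impact height) cell-mean matrix."""
    needed = {"subject_id", BETWEEN_FACTOR, "perspective", "impact_height", dv}
    missing = needed - set(table.columns)
    if missing:
        raise ValidationError(f"long table is missing columns {sorted(missing)}")
    p_levels = WITHIN_FACTORS["perspective"]
    h_levels = WITHIN_FACTORS["impact_height"]
    cells = list(itertools.product(p_levels, h_levels))
    wide = table.pivot_table(
        index="subject_id", columns=["perspective", "impact_height"], values=dv, observed=True
    )
    missing_cells = [c for c in cells if c not in wide.columns]
    if missing_cells or wide.isna().any().any():
        bad = missing_cells + [
            (s, c) for c in wide.columns for s in wide.index[wide[c].isna()]
        ]
        raise ValidationError(f"incomplete within-subject design; missing cells: {bad}")
    wide = wide[cells]
    sex = table.drop_duplicates("subject_id").set_index("subject_id")[BETWEEN_FACTOR]
    if table.groupby("subject_id", observed=True)[BETWEEN_FACTOR].nunique().max() > 1:
        raise ValidationError("a subject appears with more than one sex")
    sex = sex.loc[wide.index]
    for level, count in sex.value_counts().items():
        if count < 2:
            raise ValidationError(f"need >= 2 subjects per sex, got {count} for {level!r}")
    return wide.to_numpy(dtype=float), sex.to_numpy(), wide.index.to_numpy()


def _ols_ss(z: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Type III SS of intercept and group effect, plus residual SS, for
    columns ``z`` (n x c) regressed on [1, effect-coded group]."""
    n = z.shape[0]
    X = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss_full = float(np.sum((z - X @ beta) ** 2))
    b1, *_ = np.linalg.lstsq(X[:, 1:2], z, rcond=None)
    ss_intercept = float(np.sum((z - X[:, 1:2] @ b1) ** 2)) - rss_full
    b0, *_ = np.linalg.lstsq(X[:, 0:1], z, rcond=None)
    ss_group = float(np.sum((z - X[:, 0:1] @ b0) ** 2)) - rss_full
    return ss_intercept, ss_group, rss_full


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-design ANOVA summary.

    ``effects`` is a tidy frame (effect, ss, df1, df2, ms, F, p,
    partial_eta_sq, error_ss); ``strata`` maps each error stratum to its
    (error SS, df); ``ss_total`` is the total SS about the grand mean.
    """

    dv: str
    effects: pd.DataFrame
    strata: dict
    ss_total: float
    n_subjects: int
    gg_epsilon: dict = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        rows = self.effects[self.effects["effect"] == name]
        if rows.empty:
            raise ValidationError(f"no effect named {name!r}")
        return rows.iloc[0]

    @property
    def ss_conserved(self) -> float:
        """Relative gap between total SS and the strata decomposition
        (exactly zero for balanced between groups)."""
        acc = sum(ss for ss, _ in self.strata.values())
        acc += float(self.effects["ss"].sum())
        return abs(acc - self.ss_total) / max(self.ss_total, 1e-300)


def rm_mixed_anova(table: pd.DataFrame, dv: str) -> AnovaResult:
    """3-way mixed ANOVA: sex between; perspective and impact height within.

    Expects a long table with one row per (subject, perspective, impact
    height); each within effect is tested against its own subject-by-factor
    stratum (F = MS_effect / MS_error).  Zero-variance error strata yield
    flagged infinite (or NaN, if the effect SS is also zero) F values.
    """
    Y, sex, _ = _pivot(table, dv)
    n = Y.shape[0]
    sex_levels = sorted(set(sex))
    if len(sex_levels) != 2:
        raise ValidationError("the between factor must have exactly 2 levels")
    g = np.where(sex == sex_levels[0], 1.0, -1.0)

    cP = _orthonormal_contrasts(2)
    cH = _orthonormal_contrasts(3)
    uP = np.full((1, 2), 1 / np.sqrt(2))
    uH = np.full((1, 3), 1 / np.sqrt(3))

    bases = {
        "perspective": np.kron(cP, uH),
        "impact_height": np.kron(uP, cH),
        "perspective x impact_height": np.kron(cP, cH),
    }
    grand = Y.mean()
    ss_total = float(np.sum((Y - grand) ** 2))
    # numerical-zero threshold for SS terms, scaled to the data magnitude
    tol = max(1e-12 * ss_total, 1e-18 * (1.0 + abs(grand)) ** 2 * Y.size)

    rows = []
    strata = {}
    gg = {}

    # between stratum: scaled subject means
    u = Y @ np.kron(uP, uH).ravel()
    ss_int, ss_sex, rss = _ols_ss(u[:, None], g)
    df_err = n - 2
    rows.append(_effect_row("sex", ss_sex, 1, df_err, rss, df_err, tol))
    strata["subjects"] = (rss, df_err)

    for name, C in bases.items():
        Z = Y @ C.T
        c = Z.shape[1]
        ss_eff, ss_x_sex, rss = _ols_ss(Z, g)
        err_df = c * (n - 2)
        rows.append(_effect_row(name, ss_eff, c, err_df, rss, err_df, tol))
        rows.append(_effect_row(f"{name} x sex", ss_x_sex, c, err_df, rss, err_df, tol))
        strata[f"subjects x {name}"] = (rss, err_df)
        if c > 1:
            # Greenhouse-Geisser epsilon from the pooled within-group
            # covariance of the contrast scores
            resid = np.empty_like(Z)
            for lv in sex_levels:
                m = sex == lv
                resid[m] = Z[m] - Z[m].mean(axis=0)
            S = resid.T @ resid / (n - 2)
            tr = np.trace(S)
            gg[name] = float(tr**2 / (c * np.sum(S * S))) if tr > 0 else np.nan

    eff = pd.DataFrame(rows)
    # GG-adjusted p for multi-df within effects (reported alongside)
    eff["p_gg"] = eff["p"]
    for name, eps in gg.items():
        for effname in (name, f"{name} x sex"):
            i = eff.index[eff["effect"] == effname]
            r = eff.loc[i].iloc[0]
            if np.isfinite(r["F"]):
                eff.loc[i, "p_gg"] = float(
                    sps.f.sf(r["F"], eps * r["df1"], eps * r["df2"])
                )
    return AnovaResult(
        dv=dv, effects=eff, strata=strata, ss_total=ss_total, n_subjects=n, gg_epsilon=gg
    )


def _effect_row(name, ss, df1, df2, err_ss, err_df, tol=1e-300):
    ms = ss / df1
    mse = err_ss / err_df if err_df > 0 else np.nan
    if err_ss <= tol:
        F = np.nan if ss <= tol else np.inf
    else:
        F = ms / mse
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else (np.nan if np.isnan(F) else 0.0)
    eta = ss / (ss + err_ss) if (ss + err_ss) > 0 else np.nan
    return dict(effect=name, ss=ss, df1=df1, df2=df2, ms=ms, F=F, p=p,
                partial_eta_sq=eta, error_ss=err_ss)


# ---------------------------------------------------------------------------
# post hoc / simple effects
# ---------------------------------------------------------------------------

def _level_means(table, dv, factor):
    """Per-subject means for each level of ``factor`` (other within factor
    collapsed), plus sex coding."""
    if factor not in WITHIN_FACTORS:
        raise ValidationError(f"unknown within factor {factor!r}")
    levels = WITHIN_FACTORS[factor]
    Y, sex, subjects = _pivot(table, dv)
    p_levels, h_levels = WITHIN_FACTORS["perspective"], WITHIN_FACTORS["impact_height"]
    cells = list(itertools.product(p_levels, h_levels))
    M = np.column_stack([
        Y[:, [i for i, c in enumerate(cells) if c[0 if factor == "perspective" else 1] == lv]].mean(axis=1)
        for lv in levels
    ])
    return M, levels, sex


def lsd_posthoc(table: pd.DataFrame, dv: str, factor: str) -> pd.DataFrame:
    """Fisher's least-significant-difference pairwise comparisons.

    All pairwise t-tests for the factor's levels use the omnibus ANOVA
    error term for that factor (its subject-by-factor stratum), with
    unadjusted p values.  For a 2-level factor the single comparison
    reproduces the omnibus F exactly (F = t^2).
    """
    res = rm_mixed_anova(table, dv)
    if factor == BETWEEN_FACTOR:
        return _lsd_between(table, dv, res)
    M, levels, sex = _level_means(table, dv, factor)
    k_other = 2 if factor == "impact_height" else 3
    err_ss, err_df = res.strata[f"subjects x {factor}"]
    mse = err_ss / err_df
    sex_levels = sorted(set(sex))
    g = np.where(sex == sex_levels[0], 1.0, -1.0)
    n1, n2 = int(np.sum(g > 0)), int(np.sum(g < 0))
    out = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        z = np.sqrt(k_other / 2.0) * (M[:, i] - M[:, j])
        # Type III (unweighted) mean difference
        d_unw = 0.5 * (z[g > 0].mean() + z[g < 0].mean())
        se = np.sqrt(mse * 0.25 * (1.0 / n1 + 1.0 / n2))
        t = d_unw / se if se > 0 else np.inf * np.sign(d_unw)
        p = float(2 * sps.t.sf(abs(t), err_df)) if np.isfinite(t) else 0.0
        out.append(dict(
            level_a=levels[i], level_b=levels[j],
            difference=d_unw / np.sqrt(k_other / 2.0),
            t=t, df=err_df, p=p,
        ))
    return pd.DataFrame(out)


def _lsd_between(table, dv, res: AnovaResult) -> pd.DataFrame:
    Y, sex, _ = _pivot(table, dv)
    m = Y.mean(axis=1)
    levels = sorted(set(sex))
    err_ss, err_df = res.strata["subjects"]
    mse = err_ss / err_df / 6.0  # stratum scores are sqrt(6) x subject means
    a, b = (m[sex == lv] for lv in levels)
    d = a.mean() - b.mean()
    se = np.sqrt(mse * (1 / a.size + 1 / b.size))
    t = d / se if se > 0 else np.inf * np.sign(d)
    p = float(2 * sps.t.sf(abs(t), err_df)) if np.isfinite(t) else 0.0
    return pd.DataFrame([dict(level_a=levels[0], level_b=levels[1],
                              difference=d, t=t, df=err_df, p=p)])


def simple_effects(
    table: pd.DataFrame,
    dv: str,
    factor: str,
    moderator: str,
    pooled_error: bool = True,
) -> pd.DataFrame:
    """Effect of ``factor`` tested separately at each level of ``moderator``.

    By default the error term pools the subject-by-factor residuals across
    moderator levels (the convention implied by examining interactions
    with a simple-effects model); ``pooled_error=False`` uses each level's
    own residual stratum.
    """
    if factor not in WITHIN_FACTORS or moderator not in WITHIN_FACTORS or factor == moderator:
        raise ValidationError("factor and moderator must be distinct within factors")
    f_levels = WITHIN_FACTORS[factor]
    m_levels = WITHIN_FACTORS[moderator]
    Y, sex, _ = _pivot(table, dv)
    cells = list(itertools.product(*[WITHIN_FACTORS[f] for f in ("perspective", "impact_height")]))
    sex_levels = sorted(set(sex))
    g = np.where(sex == sex_levels[0], 1.0, -1.0)
    C = _orthonormal_contrasts(len(f_levels))

    per_level = {}
    for m_lv in m_levels:
        cols = []
        for f_lv in f_levels:
            key = (f_lv, m_lv) if factor == "perspective" else (m_lv, f_lv)
            cols.append(cells.index(key))
        Z = Y[:, cols] @ C.T
        per_level[m_lv] = _ols_ss(Z, g) + (Z.shape[1],)

    n = Y.shape[0]
    c = len(f_levels) - 1
    rss_pool = sum(v[2] for v in per_level.values())
    df_pool = c * (n - 2) * len(m_levels)
    out = []
    for m_lv, (ss_eff, _ss_x, rss, _c) in per_level.items():
        if pooled_error:
            err_ss, err_df = rss_pool, df_pool
        else:
            err_ss, err_df = rss, c * (n - 2)
        row = _effect_row(f"{factor} @ {moderator}={m_lv}", ss_eff, c, err_df, err_ss, err_df)
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# paired t tests (perceived workload scales)
# ---------------------------------------------------------------------------

def paired_t_bonferroni(pairs: dict[str, tuple]) -> pd.DataFrame:
    """Paired t-tests over k scales with Bonferroni adjustment
    (p_adj = min(1, k * p_raw)).

    ``pairs`` maps scale name -> (condition_a, condition_b) paired arrays.
    Identical pairs give t = 0, p = 1; zero-variance nonzero differences
    give an infinite-t guard with p = 0.
    """
    k = len(pairs)
    if k < 1:
        raise ValidationError("need at least one scale")
    out = []
    for name, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValidationError(f"scale {name!r}: paired samples must be equal-length 1-D")
        d = a - b
        sd = d.std(ddof=1)
        if sd == 0:
            t = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
            p = 1.0 if t == 0 else 0.0
        else:
            t, p = sps.ttest_rel(a, b)
        out.append(dict(scale=name, t=float(t), df=a.size - 1, p_raw=float(p),
                        p_adjusted=float(min(1.0, k * p))))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# repeated-measures power / sample size
# ---------------------------------------------------------------------------

def rm_power(n: int, f: float, alpha: float, m: int, rho: float) -> float:
    """Power of the within factor in a one-group repeated-measures design.

    Noncentral-F formulation with lambda = n * m * f^2 / (1 - rho),
    df1 = m - 1, df2 = (n - 1)(m - 1), nonsphericity correction 1 (the
    convention in which the effect size f does not absorb the correlation
    among the m repeated measures).
    """
    lam = n * m * f**2 / (1.0 - rho)
    df1, df2 = m - 1, (n - 1) * (m - 1)
    if df2 < 1:
        return 0.0
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def min_n_rm_power(
    f: float, alpha: float, target_power: float, m: int, rho: float, n_max: int = 10000
) -> int:
    """Smallest sample size n with ``rm_power(n, ...) >= target_power``."""
    if not (f > 0 and 0 < alpha < 1 and 0 < target_power < 1 and m >= 2 and 0 <= rho < 1):
        raise ValidationError("power parameters out of range")
    for n in range(2, n_max + 1):
        if rm_power(n, f, alpha, m, rho) >= target_power:
            return n
    raise ValidationError(f"no n <= {n_max} reaches the target power")
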