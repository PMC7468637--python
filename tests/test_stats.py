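"""Mixed RM-ANOVA, post hocs, simple effects, paired t, power."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vdodge.errors import ValidationError
from vdodge.stats import (
    lsd_posthoc,
    min_n_rm_power,
    paired_t_bonferroni,
    rm_mixed_anova,
    rm_power,
    simple_effects,
)

from conftest import make_long_table

P_LEVELS = ("first", "third")
H_LEVELS = ("IH1", "IH2", "IH3")


# ---------------------------------------------------------------------------
# brute-force split-plot oracle (balanced designs, means formulas)
# ---------------------------------------------------------------------------

def splitplot_oracle(table: pd.DataFrame, dv: str) -> dict:
    """Classical balanced split-plot sums of squares computed directly
    from cell/marginal means — independent of the package's contrast-
    projection implementation."""
    wide = table.pivot_table(index="subject_id",
                             columns=["perspective", "impact_height"], values=dv)
    cells = list(itertools.product(P_LEVELS, H_LEVELS))
    Y = wide[cells].to_numpy()
    sex = table.drop_duplicates("subject_id").set_index("subject_id").loc[wide.index, "sex"].to_numpy()
    groups = sorted(set(sex))
    n_g = {g: np.sum(sex == g) for g in groups}
    assert len(set(n_g.values())) == 1, "oracle assumes balanced groups"
    N, C = Y.shape
    P, H = 2, 3
    grand = Y.mean()

    def pmean(p):
        return Y[:, [i for i, c in enumerate(cells) if c[0] == p]].mean()

    def hmean(h):
        return Y[:, [i for i, c in enumerate(cells) if c[1] == h]].mean()

    def phmean(p, h):
        return Y[:, cells.index((p, h))].mean()

    def gmean(g):
        return Y[sex == g].mean()

    subj_mean = Y.mean(axis=1)
    ss = {}
    ss["sex"] = C * sum(n_g[g] * (gmean(g) - grand) ** 2 for g in groups)
    ss["subjects"] = C * sum(
        (subj_mean[i] - gmean(sex[i])) ** 2 for i in range(N)
    )
    ss["perspective"] = N * H * sum((pmean(p) - grand) ** 2 for p in P_LEVELS)
    ss["impact_height"] = N * P * sum((hmean(h) - grand) ** 2 for h in H_LEVELS)
    ss["perspective x impact_height"] = N * sum(
        (phmean(p, h) - pmean(p) - hmean(h) + grand) ** 2 for p, h in cells
    )

    def pgmean(p, g):
        return Y[sex == g][:, [i for i, c in enumerate(cells) if c[0] == p]].mean()

    def hgmean(h, g):
        return Y[sex == g][:, [i for i, c in enumerate(cells) if c[1] == h]].mean()

    def phgmean(p, h, g):
        return Y[sex == g][:, cells.index((p, h))].mean()

    ss["perspective x sex"] = H * sum(
        n_g[g] * (pgmean(p, g) - pmean(p) - gmean(g) + grand) ** 2
        for p in P_LEVELS for g in groups
    )
    ss["impact_height x sex"] = P * sum(
        n_g[g] * (hgmean(h, g) - hmean(h) - gmean(g) + grand) ** 2
        for h in H_LEVELS for g in groups
    )
    ss["perspective x impact_height x sex"] = sum(
        n_g[g]
        * (
            phgmean(p, h, g) - pgmean(p, g) - hgmean(h, g) - phmean(p, h)
            + pmean(p) + hmean(h) + gmean(g) - grand
        ) ** 2
        for (p, h) in cells for g in groups
    )

    # subject-level means per within combination for the error strata
    pm_s = {p: Y[:, [i for i, c in enumerate(cells) if c[0] == p]].mean(axis=1) for p in P_LEVELS}
    hm_s = {h: Y[:, [i for i, c in enumerate(cells) if c[1] == h]].mean(axis=1) for h in H_LEVELS}
    ss["err_perspective"] = H * sum(
        (pm_s[p][i] - pgmean(p, sex[i]) - subj_mean[i] + gmean(sex[i])) ** 2
        for p in P_LEVELS for i in range(N)
    )
    ss["err_impact_height"] = P * sum(
        (hm_s[h][i] - hgmean(h, sex[i]) - subj_mean[i] + gmean(sex[i])) ** 2
        for h in H_LEVELS for i in range(N)
    )
    ss_total = np.sum((Y - grand) ** 2)
    ss["err_ph"] = ss_total - sum(
        ss[k] for k in (
            "sex", "subjects", "perspective", "perspective x sex", "err_perspective",
            "impact_height", "impact_height x sex", "err_impact_height",
            "perspective x impact_height", "perspective x impact_height x sex",
        )
    )
    ss["total"] = ss_total
    return ss


def test_anova_matches_bruteforce_oracle(rng):
    """SS decomposition equals the balanced means-formula oracle to 1e-10
    relative on small tables."""
    for trial in range(5):
        df = make_long_table(rng, n_per_sex=3, persp_effect=0.4,
                             ih_effects=(0.0, 0.2, 0.7),
                             interaction={("first", "IH3"): -0.5})
        res = rm_mixed_anova(df, "val")
        oracle = splitplot_oracle(df, "val")
        tol = 1e-10 * oracle["total"]
        for name in ("sex", "perspective", "perspective x sex", "impact_height",
                     "impact_height x sex", "perspective x impact_height",
                     "perspective x impact_height x sex"):
            assert abs(res.effect(name).ss - oracle[name]) < tol, name
        assert abs(res.strata["subjects"][0] - oracle["subjects"]) < tol
        assert abs(res.strata["subjects x perspective"][0] - oracle["err_perspective"]) < tol
        assert abs(res.strata["subjects x impact_height"][0] - oracle["err_impact_height"]) < tol
        assert abs(res.strata["subjects x perspective x impact_height"][0] - oracle["err_ph"]) < tol
        assert res.ss_conserved < 1e-10


def test_anova_matches_pingouin_mixed(rng):
    """Perspective block agrees with pingouin's 2-way mixed ANOVA after
    collapsing impact height (independent implementation)."""
    pg = pytest.importorskip("pingouin")
    df = make_long_table(rng, n_per_sex=6, persp_effect=0.5, ih_effects=(0, 0.3, 0.9))
    res = rm_mixed_anova(df, "val")
    m = df.groupby(["subject_id", "sex", "perspective"], as_index=False)["val"].mean()
    aov = pg.mixed_anova(data=m, dv="val", within="perspective",
                         subject="subject_id", between="sex").set_index("Source")
    assert np.isclose(res.effect("perspective").F, aov.loc["perspective", "F"], rtol=1e-9)
    assert np.isclose(res.effect("sex").F, aov.loc["sex", "F"], rtol=1e-9)
    assert np.isclose(res.effect("perspective x sex").F, aov.loc["Interaction", "F"], rtol=1e-9)


def test_anova_matches_anovarm_within(rng):
    """Within-factor F ratios agree with statsmodels AnovaRM on a
    sex-balanced table when sex explains nothing (pooled errors differ
    only by the sex partition, which is noise here)."""
    sm = pytest.importorskip("statsmodels.stats.anova")
    df = make_long_table(rng, n_per_sex=5, persp_effect=0.6, ih_effects=(0, 0.4, 1.0),
                         subject_sd=0.8, noise_sd=0.3)
    res = rm_mixed_anova(df, "val")
    fit = sm.AnovaRM(df, "val", "subject_id",
                     within=["perspective", "impact_height"]).fit().anova_table
    # AnovaRM pools what our model splits into (effect x sex) + error; the
    # F values agree to within the small sex-attributed share
    for ours, theirs in [("perspective", "perspective"),
                         ("impact_height", "impact_height"),
                         ("perspective x impact_height", "perspective:impact_height")]:
        F1 = res.effect(ours).F
        F2 = fit.loc[theirs, "F Value"]
        assert np.isfinite(F1) and np.isfinite(F2)
        assert abs(np.log(F1 / F2)) < 0.35


def test_anova_constant_dv_flagged():
    rows = [
        dict(subject_id=f"S{s}", sex="male" if s < 2 else "female",
             perspective=p, impact_height=h, val=5.0)
        for s in range(4) for p in P_LEVELS for h in H_LEVELS
    ]
    res = rm_mixed_anova(pd.DataFrame(rows), "val")
    assert np.all(res.effects["ss"] < 1e-12)
    assert res.effects["F"].isna().all()


def test_anova_df_match_design(rng):
    """n=29 with sex between gives the classical df: perspective (1, 27),
    impact height (2, 54)."""
    df = make_long_table(rng, n_per_sex=14)
    extra = make_long_table(rng, n_per_sex=1)
    extra = extra[extra.sex == "male"].assign(subject_id="S99")
    res = rm_mixed_anova(pd.concat([df, extra], ignore_index=True), "val")
    p = res.effect("perspective")
    assert (p.df1, p.df2) == (1, 27)
    h = res.effect("impact_height")
    assert (h.df1, h.df2) == (2, 54)


def test_anova_missing_cell_errors(rng):
    df = make_long_table(rng, n_per_sex=3)
    broken = df[~((df.subject_id == "S00") & (df.impact_height == "IH2")
                  & (df.perspective == "first"))]
    with pytest.raises(ValidationError):
        rm_mixed_anova(broken, "val")


# ---------------------------------------------------------------------------
# LSD post hoc
# ---------------------------------------------------------------------------

def test_lsd_two_level_equals_omnibus(rng):
    """For the 2-level perspective factor the LSD comparison reproduces
    the omnibus test exactly (F = t^2, same p)."""
    df = make_long_table(rng, n_per_sex=6, persp_effect=0.5)
    res = rm_mixed_anova(df, "val")
    lsd = lsd_posthoc(df, "val", "perspective")
    assert len(lsd) == 1
    assert np.isclose(lsd.t.iloc[0] ** 2, res.effect("perspective").F, rtol=1e-9)
    assert np.isclose(lsd.p.iloc[0], res.effect("perspective").p, rtol=1e-9)


def test_lsd_identical_level_means(rng):
    df = make_long_table(rng, n_per_sex=4, ih_effects=(0.0, 0.0, 0.0), noise_sd=0.3)
    lsd = lsd_posthoc(df, "val", "impact_height")
    assert len(lsd) == 3
    assert (lsd.p > 0.05).all()  # no spurious differences at null levels


def test_lsd_detects_mt_pattern(rng):
    """With movement-time-like level means (574/648/671, subject scatter
    at the reported scale, n=29) the IH1-vs-IH2 and IH1-vs-IH3 contrasts
    are detected in most replicates."""
    hits = 0
    reps = 40
    for r in range(reps):
        df = make_long_table(rng, n_per_sex=14, ih_effects=(574.0, 648.0, 671.0),
                             subject_sd=215.0, noise_sd=40.0)
        lsd = lsd_posthoc(df, "val", "impact_height").set_index(["level_a", "level_b"])
        if lsd.loc[("IH1", "IH2"), "p"] < 0.05 and lsd.loc[("IH1", "IH3"), "p"] < 0.05:
            hits += 1
    assert hits / reps >= 0.8


def test_lsd_between_factor(rng):
    df = make_long_table(rng, n_per_sex=6)
    df.loc[df.sex == "male", "val"] += 2.0
    lsd = lsd_posthoc(df, "val", "sex")
    assert lsd.p.iloc[0] < 0.05
    assert np.isclose(abs(lsd.difference.iloc[0]), 2.0, atol=1.5)


# ---------------------------------------------------------------------------
# simple effects
# ---------------------------------------------------------------------------

def test_simple_effects_consistent_without_interaction(rng):
    df = make_long_table(rng, n_per_sex=8, persp_effect=1.0, noise_sd=0.2)
    se = simple_effects(df, "val", "perspective", "impact_height")
    assert len(se) == 3
    assert (se.p < 0.01).all()  # strong main effect everywhere
    Fs = se.F.to_numpy()
    assert Fs.max() / Fs.min() < 3.0


def test_simple_effects_crossover(rng):
    inter = {("first", "IH1"): 1.0, ("third", "IH1"): -1.0,
             ("first", "IH3"): -1.0, ("third", "IH3"): 1.0}
    df = make_long_table(rng, n_per_sex=8, interaction=inter, noise_sd=0.2)
    wide = df.pivot_table(index="subject_id", columns=["perspective", "impact_height"],
                          values="val")
    d_ih1 = (wide[("first", "IH1")] - wide[("third", "IH1")]).mean()
    d_ih3 = (wide[("first", "IH3")] - wide[("third", "IH3")]).mean()
    assert np.sign(d_ih1) == -np.sign(d_ih3)
    se = simple_effects(df, "val", "perspective", "impact_height").set_index("effect")
    assert se.loc["perspective @ impact_height=IH1", "p"] < 0.01
    assert se.loc["perspective @ impact_height=IH3", "p"] < 0.01
    assert se.loc["perspective @ impact_height=IH2", "p"] > 0.05


def test_simple_effects_localized_perspective_effect(rng):
    """A perspective effect present only at IH3 (the reported vertical
    hand-position pattern) is detected at IH3 and not at IH1/IH2 in the
    majority of replicates."""
    hits_ih3, false_other = 0, 0
    reps = 30
    for _ in range(reps):
        df = make_long_table(rng, n_per_sex=14, noise_sd=2.0, subject_sd=3.0,
                             interaction={("first", "IH3"): -5.4})
        se = simple_effects(df, "val", "perspective", "impact_height").set_index("effect")
        if se.loc["perspective @ impact_height=IH3", "p"] < 0.05:
            hits_ih3 += 1
        false_other += int(se.loc["perspective @ impact_height=IH1", "p"] < 0.05)
        false_other += int(se.loc["perspective @ impact_height=IH2", "p"] < 0.05)
    assert hits_ih3 / reps > 0.5
    assert false_other / (2 * reps) < 0.2


def test_simple_effects_validation(rng):
    df = make_long_table(rng, n_per_sex=3)
    with pytest.raises(ValidationError):
        simple_effects(df, "val", "perspective", "perspective")


# ---------------------------------------------------------------------------
# paired t with Bonferroni
# ---------------------------------------------------------------------------

def test_paired_t_identical_samples():
    x = np.arange(6.0)
    out = paired_t_bonferroni({"effort": (x, x)})
    assert out.t.iloc[0] == 0.0
    assert out.p_adjusted.iloc[0] == 1.0


def test_paired_t_single_scale_unadjusted(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
    out = paired_t_bonferroni({"s": (a, b)})
    assert np.isclose(out.p_adjusted.iloc[0], out.p_raw.iloc[0])


def test_paired_t_closed_form(rng):
    """t matches the closed form mean / (sd / sqrt(n)); constant nonzero
    differences hit the guarded infinite-t branch."""
    a = np.array([3.0, 4.0, 6.0, 5.0])
    b = np.array([1.0, 2.0, 2.0, 4.0])
    d = a - b
    expected = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    out = paired_t_bonferroni({"s": (a, b)})
    assert np.isclose(out.t.iloc[0], expected, rtol=1e-12)

    const = paired_t_bonferroni({"s": (np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]))})
    assert np.isinf(const.t.iloc[0]) and const.p_adjusted.iloc[0] == 0.0


def test_paired_t_bonferroni_factor(rng):
    a = rng.normal(0, 1, 12)
    pairs = {f"scale{i}": (a + rng.normal(0.4, 1, 12), a) for i in range(6)}
    out = paired_t_bonferroni(pairs)
    assert np.allclose(out.p_adjusted, np.minimum(1.0, 6 * out.p_raw))


def test_paired_t_validation():
    with pytest.raises(ValidationError):
        paired_t_bonferroni({"s": (np.zeros(3), np.zeros(4))})
    with pytest.raises(ValidationError):
        paired_t_bonferroni({})


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def test_power_monotonicities():
    base = dict(f=0.4, alpha=0.05, target_power=0.8, m=2, rho=0.5)
    n0 = min_n_rm_power(**base)
    assert min_n_rm_power(**{**base, "rho": 0.8}) <= n0
    assert min_n_rm_power(**{**base, "f": 0.6}) <= n0
    assert min_n_rm_power(**{**base, "target_power": 0.95}) >= n0


def test_power_matches_simulation():
    """Analytic power at the returned n agrees with a 10^4-replicate
    Monte-Carlo of the equivalent paired t-test."""
    from scipy import stats as sps

    n = min_n_rm_power(0.4, 0.05, 0.8, 2, 0.5)
    analytic = rm_power(n, 0.4, 0.05, 2, 0.5)
    assert analytic >= 0.8
    rng = np.random.default_rng(2024)
    # m=2, f=0.4, rho=0.5, sigma=1  <->  paired differences N(0.8, 1)
    d = rng.normal(0.8, 1.0, size=(10000, n))
    t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(n))
    mc = np.mean(np.abs(t) > sps.t.isf(0.025, n - 1))
    assert mc >= 0.8 - 0.02
    assert abs(mc - analytic) < 0.02


def test_power_validation():
    with pytest.raises(ValidationError):
        min_n_rm_power(-0.1, 0.05, 0.8, 2, 0.5)
    with pytest.raises(ValidationError):
        min_n_rm_power(0.4, 0.05, 0.8, 1, 0.5)
    with pytest.raises(ValidationError):
        min_n_rm_power(0.4, 0.05, 0.8, 2, 1.0)
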