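"""Mixed-design ANOVA against explicit sums-of-squares oracles and
pingouin, post hoc gating/dispatch, Benjamini-Hochberg closed form."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from somnarch.stats import (
    MixedAnova,
    POSTHOC_COMPARISONS,
    baseline_vs_recovery,
    benjamini_hochberg,
    posthoc_gate,
    posthoc_pressure,
    posthoc_ttests,
    rm_anova,
    two_way_within_anova,
)


# ---------------------------------------------------------------------------
# oracles


def split_plot_oracle(y):
    """Explicit marginal-means SS decomposition for a balanced
    (a x b between) x t within design; y has shape (a, b, n, t)."""
    a, b, n, t = y.shape
    G = y.mean()
    mA = y.mean(axis=(1, 2, 3))
    mB = y.mean(axis=(0, 2, 3))
    mT = y.mean(axis=(0, 1, 2))
    mAB = y.mean(axis=(2, 3))
    mAT = y.mean(axis=(1, 2))
    mBT = y.mean(axis=(0, 2))
    mABT = y.mean(axis=2)
    mS = y.mean(axis=3)
    ss = {
        "A": n * b * t * np.sum((mA - G) ** 2),
        "B": n * a * t * np.sum((mB - G) ** 2),
        "AB": n * t * np.sum((mAB - mA[:, None] - mB[None, :] + G) ** 2),
        "S": t * np.sum((mS - mAB[:, :, None]) ** 2),
        "T": n * a * b * np.sum((mT - G) ** 2),
        "AT": n * b * np.sum((mAT - mA[:, None] - mT[None, :] + G) ** 2),
        "BT": n * a * np.sum((mBT - mB[:, None] - mT[None, :] + G) ** 2),
        "ABT": n
        * np.sum(
            (
                mABT
                - mAB[:, :, None]
                - mAT[:, None, :]
                - mBT[None, :, :]
                + mA[:, None, None]
                + mB[None, :, None]
                + mT[None, None, :]
                - G
            )
            ** 2
        ),
    }
    ss["ERRW"] = np.sum((y - G) ** 2) - sum(ss.values())
    dfS = a * b * (n - 1)
    dfE = dfS * (t - 1)
    msS, msE = ss["S"] / dfS, ss["ERRW"] / dfE
    return {
        "sex": ss["A"] / (a - 1) / msS,
        "genotype": ss["B"] / (b - 1) / msS,
        "sex:genotype": ss["AB"] / ((a - 1) * (b - 1)) / msS,
        "time": ss["T"] / (t - 1) / msE,
        "sex:time": ss["AT"] / ((a - 1) * (t - 1)) / msE,
        "genotype:time": ss["BT"] / ((b - 1) * (t - 1)) / msE,
        "sex:genotype:time": ss["ABT"] / ((a - 1) * (b - 1) * (t - 1)) / msE,
    }


def _long(y):
    a, b, n, t = y.shape
    rows = []
    for ai, sex in zip(range(a), ["F", "M"]):
        for bi, gt in zip(range(b), ["MUT", "WT"]):
            for s in range(n):
                for ti in range(t):
                    rows.append((f"{sex}{gt}{s}", sex, gt, ti, y[ai, bi, s, ti]))
    return pd.DataFrame(rows, columns=["animal_id", "sex", "genotype", "hour", "y"])


@pytest.mark.parametrize("shape,seed", [((2, 2, 3, 3), 0), ((2, 2, 4, 5), 1), ((2, 2, 2, 7), 2)])
def test_mixed_anova_matches_explicit_ss_oracle(shape, seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 10, size=shape).astype(float)
    oracle = split_plot_oracle(y)
    res = MixedAnova(_long(y), "y", "hour", "animal_id", ["sex", "genotype"]).fit()
    for term, F in oracle.items():
        assert res.table.loc[term, "F"] == pytest.approx(F, abs=1e-8)


def test_mixed_anova_matches_pingouin_single_between():
    import pingouin as pg

    rng = np.random.default_rng(5)
    y = rng.normal(size=(2, 1, 4, 4))
    df = _long(y)
    res = MixedAnova(df, "y", "hour", "animal_id", ["sex"]).fit()
    pga = pg.mixed_anova(df, dv="y", within="hour", subject="animal_id",
                         between="sex").set_index("Source")
    assert res.table.loc["sex", "F"] == pytest.approx(pga.loc["sex", "F"])
    assert res.table.loc["time", "F"] == pytest.approx(pga.loc["hour", "F"])
    assert res.table.loc["sex:time", "F"] == pytest.approx(pga.loc["Interaction", "F"])


def test_f_invariant_under_affine_dv_transform():
    rng = np.random.default_rng(6)
    y = rng.normal(size=(2, 2, 3, 4))
    r1 = MixedAnova(_long(y), "y", "hour", "animal_id", ["sex", "genotype"]).fit()
    r2 = MixedAnova(_long(3.7 * y - 11.0), "y", "hour", "animal_id",
                    ["sex", "genotype"]).fit()
    assert np.allclose(r1.table["F"], r2.table["F"], rtol=1e-9)


def test_constant_dv_reports_na():
    y = np.ones((2, 2, 3, 3))
    res = MixedAnova(_long(y), "y", "hour", "animal_id", ["sex", "genotype"]).fit()
    assert res.table["F"].isna().all()
    assert res.table["p"].isna().all()


def test_incomplete_subjects_dropped_with_warning():
    rng = np.random.default_rng(7)
    df = _long(rng.normal(size=(2, 2, 3, 3)))
    df = df[~((df.animal_id == "FMUT0") & (df.hour == 2))]
    with pytest.warns(UserWarning, match="incomplete"):
        res = MixedAnova(df, "y", "hour", "animal_id", ["sex", "genotype"]).fit()
    assert res.n_subjects == 11


def test_too_small_cell_rejected():
    rng = np.random.default_rng(8)
    df = _long(rng.normal(size=(2, 2, 3, 3)))
    df = df[~df.animal_id.isin(["FMUT0", "FMUT1"])]
    with pytest.raises(ValueError, match="at least 2"):
        MixedAnova(df, "y", "hour", "animal_id", ["sex", "genotype"])


def test_summary_lists_all_terms():
    rng = np.random.default_rng(9)
    res = MixedAnova(_long(rng.normal(size=(2, 2, 3, 3))), "y", "hour",
                     "animal_id", ["sex", "genotype"]).fit()
    text = res.summary()
    for term in ("sex", "genotype", "time", "sex:genotype:time"):
        assert term in text


# ---------------------------------------------------------------------------
# two-way fully-within (baseline vs recovery)


def test_two_way_within_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(10)
    rows = []
    for s in range(5):
        for ph in ("baseline", "recovery"):
            for h in range(4):
                rows.append((f"s{s}", ph, h, rng.normal()))
    df = pd.DataFrame(rows, columns=["animal_id", "phase", "zt_hour", "y"])
    mine = baseline_vs_recovery(df, dv="y")
    pgw = pg.rm_anova(df, dv="y", within=["phase", "zt_hour"],
                      subject="animal_id").set_index("Source")
    assert mine.loc["phase", "F"] == pytest.approx(pgw.loc["phase", "F"])
    assert mine.loc["phase:zt_hour", "F"] == pytest.approx(
        pgw.loc["phase * zt_hour", "F"]
    )


def test_identical_phases_give_na_treatment_effect():
    rows = []
    rng = np.random.default_rng(11)
    for s in range(4):
        vals = rng.normal(size=3)
        for ph in ("baseline", "recovery"):
            for h in range(3):
                rows.append((f"s{s}", ph, h, vals[h]))
    df = pd.DataFrame(rows, columns=["animal_id", "phase", "zt_hour", "y"])
    res = baseline_vs_recovery(df, dv="y")
    assert np.isnan(res.loc["phase", "F"]) or res.loc["phase", "F"] == pytest.approx(0.0)


def test_injected_rebound_detected():
    """A dark-period NREM increase in recovery shows up as a treatment
    effect in the within-group comparison."""
    rng = np.random.default_rng(12)
    rows = []
    for s in range(7):
        base = 30 + rng.normal(0, 2, size=12)
        rec = base + 6 + rng.normal(0, 2, size=12)
        for h in range(12):
            rows.append((f"s{s}", "baseline", h, base[h]))
            rows.append((f"s{s}", "recovery", h, rec[h]))
    df = pd.DataFrame(rows, columns=["animal_id", "phase", "zt_hour", "y"])
    res = baseline_vs_recovery(df, dv="y")
    assert res.loc["phase", "p"] < 0.01


# ---------------------------------------------------------------------------
# post hoc machinery


def _fake_results(pvals):
    table = pd.DataFrame(
        {"p": pvals, "F": 1.0, "ss": 1.0, "df_num": 1, "df_den": 10}
    )
    from somnarch.stats import MixedAnovaResults

    return MixedAnovaResults(table=table, n_subjects=28, n_dropped=0,
                             time_levels=list(range(12)), between=["sex", "genotype"])


def test_gate_closed_when_all_terms_ns():
    res = _fake_results(pd.Series(0.5, index=[
        "sex", "genotype", "time", "sex:genotype", "sex:time",
        "genotype:time", "sex:genotype:time"]))
    assert posthoc_gate(res) == []


def test_gate_opens_on_genotype_main_effect():
    res = _fake_results(pd.Series(
        [0.5, 0.01, 0.5, 0.5, 0.5, 0.5, 0.5],
        index=["sex", "genotype", "time", "sex:genotype", "sex:time",
               "genotype:time", "sex:genotype:time"]))
    assert len(posthoc_gate(res)) == 4


def test_gate_opens_on_genotype_time_interaction_only():
    res = _fake_results(pd.Series(
        [0.5, 0.5, 0.5, 0.5, 0.5, 0.04, 0.5],
        index=["sex", "genotype", "time", "sex:genotype", "sex:time",
               "genotype:time", "sex:genotype:time"]))
    assert len(posthoc_gate(res)) == 4


def test_gate_ignores_between_interaction_and_time_main():
    res = _fake_results(pd.Series(
        [0.5, 0.5, 0.001, 0.001, 0.5, 0.5, 0.5],
        index=["sex", "genotype", "time", "sex:genotype", "sex:time",
               "genotype:time", "sex:genotype:time"]))
    assert posthoc_gate(res) == []


def _scalar_df(rng):
    rows = []
    for sex in ("M", "F"):
        for gt in ("WT", "MUT"):
            for i in range(7):
                rows.append((f"{sex}{gt}{i}", sex, gt, rng.normal()))
    return pd.DataFrame(rows, columns=["animal_id", "sex", "genotype", "value"])


def test_identical_groups_give_t0_p1():
    df = _scalar_df(np.random.default_rng(13))
    df["value"] = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0], 4)
    out = posthoc_ttests(df, POSTHOC_COMPARISONS)
    assert np.allclose(out["t"], 0.0)
    assert np.allclose(out["p_raw"], 1.0)


def test_ttest_matches_pooled_variance_formula():
    df = pd.DataFrame(
        {
            "animal_id": list("abcdef"),
            "sex": ["M"] * 6,
            "genotype": ["WT"] * 3 + ["MUT"] * 3,
            "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
    out = posthoc_ttests(df, [("sex", "M", "genotype", "WT", "MUT")])
    g1, g2 = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
    sp2 = ((2 * g1.var(ddof=1)) + (2 * g2.var(ddof=1))) / 4
    t_expected = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (2 / 3))
    assert out["t"].iloc[0] == pytest.approx(t_expected, abs=1e-12)


def test_pressure_posthoc_dispatches_to_rm_anova():
    rng = np.random.default_rng(14)
    rows = []
    for sex in ("M", "F"):
        for gt in ("WT", "MUT"):
            for i in range(4):
                for h in range(5):
                    shift = 0.8 if gt == "MUT" else 0.0
                    rows.append((f"{sex}{gt}{i}", sex, gt, h,
                                 2.0 - 0.2 * h + shift + rng.normal(0, 0.1)))
    df = pd.DataFrame(rows, columns=["animal_id", "sex", "genotype", "hour",
                                     "norm_delta"])
    out = posthoc_pressure(df, POSTHOC_COMPARISONS)
    assert {"p_group", "p_group_time", "p_group_bh"} <= set(out.columns)
    within_sex = out[out.comparison.str.startswith("sex=")]
    assert (within_sex["p_group"] < 0.05).all()


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_oracle(p):
    """Step-up closed form: p(i) m / i with monotone clamp from the top."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def test_bh_worked_example():
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


def test_bh_single_p_unchanged():
    assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)


def test_bh_equal_ps_all_unchanged():
    assert np.allclose(benjamini_hochberg([0.05] * 4), 0.05)


def test_bh_adjusted_never_below_raw():
    rng = np.random.default_rng(15)
    p = rng.uniform(size=20)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        benjamini_hochberg([0.1, 1.5])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
       st.randoms(use_true_random=False))
def test_bh_permutation_equivariant(p, rnd):
    p = np.asarray(p)
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    perm = np.asarray(perm)
    adj = benjamini_hochberg(p)
    adj_perm = benjamini_hochberg(p[perm])
    assert np.allclose(adj[perm], adj_perm)
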