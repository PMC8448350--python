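"""Condition means, RM/mixed ANOVA vs brute-force oracles, mixed-model slopes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nadlearn import (
    condition_means,
    fit_learning_slopes,
    order_check,
    rm_anova_2x2,
)
from nadlearn.group_stats import add_inclusion
from nadlearn.paradigm import NADS, RANDOM

from conftest import linear_cohort


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["participant", "condition", "trial_index", "tnt", "rt", "correct", "responded"],
    )


def _cells_from_matrix(values):
    """participants x (NADs-T, NADs-NT, Random-T, Random-NT) cell means."""
    values = np.asarray(values, dtype=float)
    idx = [f"p{i}" for i in range(values.shape[0])]
    cols = pd.Index(
        [(NADS, "Target"), (NADS, "NoTarget"), (RANDOM, "Target"), (RANDOM, "NoTarget")],
        tupleize_cols=False,
    )
    cells = pd.DataFrame(values, index=idx, columns=cols)
    cells["nads_effect"] = (values[:, 2] + values[:, 3]) / 2 - (values[:, 0] + values[:, 1]) / 2
    return cells


def rm_anova_oracle(values):
    """Classical two-way within-subject ANOVA from explicit mean decompositions."""
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    cube = y.reshape(n, 2, 2)  # participant x structure x target
    grand = cube.mean()
    m_p = cube.mean(axis=(1, 2))
    m_s = cube.mean(axis=(0, 2))
    m_t = cube.mean(axis=(0, 1))
    m_st = cube.mean(axis=0)
    m_ps = cube.mean(axis=2)
    m_pt = cube.mean(axis=1)
    ss_s = 2 * n * ((m_s - grand) ** 2).sum()
    ss_t = 2 * n * ((m_t - grand) ** 2).sum()
    ss_st = n * ((m_st - m_s[:, None] - m_t[None, :] + grand) ** 2).sum()
    ss_ps = 2 * ((m_ps - m_p[:, None] - m_s[None, :] + grand) ** 2).sum()
    ss_pt = 2 * ((m_pt - m_p[:, None] - m_t[None, :] + grand) ** 2).sum()
    ss_pst = (
        (cube - m_ps[:, :, None] - m_pt[:, None, :] - m_st[None, :, :]
         + m_p[:, None, None] + m_s[None, :, None] + m_t[None, None, :] - grand) ** 2
    ).sum()
    out = {}
    for name, ss_eff, ss_err in (
        ("Structure", ss_s, ss_ps),
        ("Target", ss_t, ss_pt),
        ("Structure x Target", ss_st, ss_pst),
    ):
        f = (ss_eff / 1.0) / (ss_err / (n - 1))
        out[name] = {
            "F": f,
            "p": stats.f.sf(f, 1, n - 1),
            "partial_eta_sq": ss_eff / (ss_eff + ss_err),
        }
    return out


# ---------------------------------------------------------------------------
# condition means
# ---------------------------------------------------------------------------


def test_condition_means_flat_participant():
    rows = [
        ("p1", cond, t, tnt, 500.0, True, True)
        for cond in (NADS, RANDOM)
        for t, tnt in enumerate(["Target", "NoTarget"] * 4, start=1)
    ] + [
        ("p2", cond, t, tnt, 400.0 if cond == NADS else 550.0, True, True)
        for cond in (NADS, RANDOM)
        for t, tnt in enumerate(["Target", "NoTarget"] * 4, start=1)
    ]
    cells = condition_means(_records(rows))
    assert cells.loc["p1", "nads_effect"] == pytest.approx(0.0)
    assert cells.loc["p2", "nads_effect"] == pytest.approx(150.0)


def test_excluded_trials_do_not_move_means():
    base_rows = [
        ("p1", cond, t, tnt, 480.0 + 10 * t, True, True)
        for cond in (NADS, RANDOM)
        for t, tnt in enumerate(["Target", "NoTarget"] * 3, start=1)
    ]
    extra = [
        ("p1", NADS, 90, "Target", 1200.0, True, True),  # too slow
        ("p1", NADS, 91, "Target", 300.0, False, True),  # incorrect
        ("p1", RANDOM, 92, "NoTarget", np.nan, False, False),  # timeout
    ]
    a = condition_means(_records(base_rows))
    b = condition_means(_records(base_rows + extra))
    pd.testing.assert_frame_equal(a, b)


def test_empty_cell_participant_dropped_with_warning():
    rows = [
        ("p1", cond, t, tnt, 500.0, True, True)
        for cond in (NADS, RANDOM)
        for t, tnt in enumerate(["Target", "NoTarget"] * 2, start=1)
    ] + [("p2", NADS, 1, "Target", 500.0, True, True)]
    with pytest.warns(UserWarning, match="p2"):
        cells = condition_means(_records(rows))
    assert list(cells.index) == ["p1"]


# ---------------------------------------------------------------------------
# RM ANOVA
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (8, 2)])
def test_rm_anova_matches_projection_oracle(n, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(600, 80, size=(n, 4))
    res = rm_anova_2x2(_cells_from_matrix(values))
    oracle = rm_anova_oracle(values)
    for name, expect in oracle.items():
        row = res.effect(name)
        assert row["F"] == pytest.approx(expect["F"], abs=1e-10, rel=1e-10)
        assert row["p"] == pytest.approx(expect["p"], abs=1e-10, rel=1e-10)
        assert row["partial_eta_sq"] == pytest.approx(
            expect["partial_eta_sq"], abs=1e-10, rel=1e-10
        )
        assert row["df_num"] == 1 and row["df_den"] == n - 1


def test_rm_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    values = rng.normal(600, 80, size=(6, 4))
    res = rm_anova_2x2(_cells_from_matrix(values))
    long = []
    for i in range(6):
        for j, (s, t) in enumerate(
            [(NADS, "Target"), (NADS, "NoTarget"), (RANDOM, "Target"), (RANDOM, "NoTarget")]
        ):
            long.append({"subj": i, "structure": s, "target": t, "rt": values[i, j]})
    pg_res = pg.rm_anova(
        data=pd.DataFrame(long), dv="rt", within=["structure", "target"], subject="subj"
    ).set_index("Source")
    assert res.effect("Structure")["F"] == pytest.approx(pg_res.loc["structure", "F"], rel=1e-9)
    assert res.effect("Target")["F"] == pytest.approx(pg_res.loc["target", "F"], rel=1e-9)
    assert res.effect("Structure x Target")["F"] == pytest.approx(
        pg_res.loc["structure * target", "F"], rel=1e-9
    )


def test_rm_anova_zero_effect():
    values = np.tile([[500.0, 520.0, 500.0, 520.0]], (5, 1))
    values += np.arange(5)[:, None] * 10  # participant offsets only
    res = rm_anova_2x2(_cells_from_matrix(values))
    assert res.effect("Structure")["F"] == pytest.approx(0.0, abs=1e-20)


def test_partial_eta_sq_half_when_ss_equal():
    # contrast scores with t^2 = n - 1 give SS_effect = SS_error
    n = 4
    d = np.array([-1.0, -1.0, 1.0, 1.0])
    d = d / d.std(ddof=1) + np.sqrt((n - 1) / n)  # sd 1, mean sqrt((n-1)/n)
    base = np.zeros((n, 4))
    base[:, 0] = d  # puts the whole contrast into the Structure score
    base[:, 1] = d
    res = rm_anova_2x2(_cells_from_matrix(base))
    assert res.effect("Structure")["partial_eta_sq"] == pytest.approx(0.5, abs=1e-12)


def test_nads_effect_equals_structure_mean_difference(small_cohort):
    records, _, _ = small_cohort
    cells = condition_means(records)
    res = rm_anova_2x2(cells)
    md = res.mean_differences.set_index("effect").loc["Structure", "mean_diff"]
    assert md == pytest.approx(cells["nads_effect"].mean(), abs=1e-9)


def test_rm_anova_requires_enough_participants():
    values = np.random.default_rng(0).normal(size=(2, 4))
    with pytest.raises(ValueError):
        rm_anova_2x2(_cells_from_matrix(values))


# ---------------------------------------------------------------------------
# mixed-design Order check
# ---------------------------------------------------------------------------


def _order_series(cells, first_half="nads_first", second_half="random_first"):
    n = cells.shape[0]
    return pd.Series(
        [first_half] * (n // 2) + [second_half] * (n - n // 2), index=cells.index
    )


def test_order_main_effect_matches_scipy_oracle():
    rng = np.random.default_rng(5)
    values = rng.normal(600, 50, size=(10, 4))
    cells = _cells_from_matrix(values)
    order = _order_series(cells)
    res = order_check(cells, order)
    avg = values.mean(axis=1)
    f, p = stats.f_oneway(avg[:5], avg[5:])
    assert res.effect("Order")["F"] == pytest.approx(f, rel=1e-10)
    assert res.effect("Order")["p"] == pytest.approx(p, rel=1e-10)
    # within x between interaction equals the two-sample t on contrast scores
    d_struct = (values[:, 0] + values[:, 1]) / 2 - (values[:, 2] + values[:, 3]) / 2
    t, p_t = stats.ttest_ind(d_struct[:5], d_struct[5:], equal_var=True)
    assert res.effect("Structure x Order")["F"] == pytest.approx(t**2, rel=1e-10)
    assert res.effect("Structure x Order")["p"] == pytest.approx(p_t, rel=1e-10)


def test_order_null_p_values_uniform():
    """Shuffled order labels on order-free data give uniform p-values."""
    rng = np.random.default_rng(6)
    values = rng.normal(600, 50, size=(12, 4))
    cells = _cells_from_matrix(values)
    pvals = []
    for _ in range(200):
        labels = rng.permutation(["nads_first"] * 6 + ["random_first"] * 6)
        res = order_check(cells, pd.Series(labels, index=cells.index))
        pvals.append(res.effect("Order")["p"])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.001


def test_order_injected_effect_detected():
    rng = np.random.default_rng(7)
    values = rng.normal(600, 30, size=(20, 4))
    values[:10] += 100.0  # one order group slower overall
    cells = _cells_from_matrix(values)
    res = order_check(cells, _order_series(cells))
    assert res.effect("Order")["p"] < 0.001


def test_order_single_level_rejected():
    values = np.random.default_rng(8).normal(size=(6, 4))
    cells = _cells_from_matrix(values)
    with pytest.raises(ValueError):
        order_check(cells, pd.Series(["nads_first"] * 6, index=cells.index))


# ---------------------------------------------------------------------------
# learning slopes
# ---------------------------------------------------------------------------


def test_slopes_equal_conditions_give_zero_beta_diff():
    rng = np.random.default_rng(9)
    records = linear_cohort(rng, slope_random=-2.0, slope_nads=-2.0, resid_sd=0.0)
    res = fit_learning_slopes(records)
    assert res.beta_diff == pytest.approx(0.0, abs=1e-6)


def test_slopes_noiseless_recovery_exact():
    rng = np.random.default_rng(10)
    records = linear_cohort(rng, slope_random=-1.0, slope_nads=-6.0, resid_sd=0.0)
    res = fit_learning_slopes(records)
    assert res.beta_diff == pytest.approx(-5.0, abs=1e-6)
    assert res.params["trial"] == pytest.approx(-1.0, abs=1e-6)
    assert res.params["condition_nads"] != 0.0  # intercept shift between conditions
    assert res.params["tnt_target"] == pytest.approx(20.0, abs=1e-6)


def test_slopes_reduce_to_ols_without_participant_variance():
    rng = np.random.default_rng(11)
    records = linear_cohort(rng, participant_sd=0.0, resid_sd=0.0)
    res = fit_learning_slopes(records)
    x = np.column_stack(
        [
            np.ones(len(records)),
            (records["condition"] == NADS).to_numpy(float),
            records["trial_index"].to_numpy(float),
            (records["tnt"] == "Target").to_numpy(float),
            (records["condition"] == NADS).to_numpy(float)
            * records["trial_index"].to_numpy(float),
        ]
    )
    beta_ols = np.linalg.lstsq(x, records["rt"].to_numpy(float), rcond=None)[0]
    assert np.allclose(res.params.to_numpy(), beta_ols, atol=1e-8)
    assert res.singular


def test_slopes_match_statsmodels_mixedlm(small_cohort):
    """Estimates and SEs agree with the general MixedLM machinery."""
    import statsmodels.formula.api as smf

    records, _, _ = small_cohort
    records = add_inclusion(records)
    inc = records[records["included"]].copy()
    inc["cond"] = (inc["condition"] == NADS).astype(float)
    inc["tgt"] = (inc["tnt"] == "Target").astype(float)
    inc["inter"] = inc["cond"] * inc["trial_index"]
    m = smf.mixedlm(
        "rt ~ cond + trial_index + tgt + inter", inc, groups=inc["participant"]
    ).fit(reml=True)
    res = fit_learning_slopes(records)
    assert res.beta_diff == pytest.approx(m.params["inter"], rel=1e-5)
    assert res.se["condition_nads:trial"] == pytest.approx(m.bse["inter"], rel=1e-3)
    assert 1.0 < res.df["condition_nads:trial"] < len(inc)
    assert res.df_method == "satterthwaite"


def test_slopes_input_validation():
    rng = np.random.default_rng(12)
    records = linear_cohort(rng, n_participants=1)
    with pytest.raises(ValueError):
        fit_learning_slopes(records)
    two = linear_cohort(rng, n_participants=2)
    with pytest.raises(ValueError):
        fit_learning_slopes(two[two["condition"] == NADS])
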