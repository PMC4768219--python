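"""Differential-expression statistics: ratios, moderation, q-values, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tfcrosstalk.errors import (
    ConfigurationError,
    DegenerateDataError,
    InputError,
    InsufficientReplicationError,
)
from tfcrosstalk.expression import (
    Contrast,
    ExpressionMatrix,
    ModerationParams,
    call_de,
    de_table,
    estimate_qvalues,
    fit_moderation,
    linear_ratio,
    moderated_test,
)
from conftest import make_null_matrix

TNF_VS_CTR = Contrast("tnf_vs_ctr", "TNF", "Ctr")


# ------------------------------------------------------------------ ratios
def test_linear_ratio_hand_example(tiny_matrix):
    # treated (4.0, 4.2) vs reference (3.0, 3.0): 2^(4.1 - 3.0)
    assert linear_ratio(tiny_matrix, TNF_VS_CTR, gene="gA") == pytest.approx(2 ** 1.1)


def test_linear_ratio_equal_means_is_one(tiny_matrix):
    assert linear_ratio(tiny_matrix, TNF_VS_CTR, gene="gB") == pytest.approx(1.0)


def test_linear_ratio_boundary_excluded_by_strict_threshold():
    values = pd.DataFrame(
        {"Ctr_1": [1.0], "Ctr_2": [1.0], "TNF_1": [1.0 + np.log2(1.2)], "TNF_2": [1.0 + np.log2(1.2)]},
        index=["g"],
    )
    m = ExpressionMatrix(values, {c: c.rsplit("_", 1)[0] for c in values.columns})
    ratio = linear_ratio(m, TNF_VS_CTR, gene="g")
    assert ratio == pytest.approx(1.2)
    assert call_de(ratio, 0.001) == "none"


def test_missing_condition_is_contract_violation(tiny_matrix):
    with pytest.raises(InputError):
        linear_ratio(tiny_matrix, Contrast("x", "HS", "Ctr"))


# ------------------------------------------------------------- moderation
def test_equal_variances_give_infinite_prior_df():
    rng = np.random.default_rng(0)
    # identical spread in every gene: no between-gene variance dispersion
    base = rng.normal(size=(50, 1))
    offsets = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]) * 0.3
    values = pd.DataFrame(
        base + offsets, index=[f"g{i}" for i in range(50)],
        columns=["Ctr_1", "Ctr_2", "Ctr_3", "TNF_1", "TNF_2", "TNF_3"],
    )
    m = ExpressionMatrix(values, {c: c.rsplit("_", 1)[0] for c in values.columns})
    params = fit_moderation(m, TNF_VS_CTR)
    assert np.isinf(params.prior_df)
    assert params.prior_variance == pytest.approx(0.09, rel=1e-6)


def test_moderation_recovers_planted_prior_df():
    rng = np.random.default_rng(42)
    d0, s0sq, d, n_genes = 4.0, 1.0, 4, 5000
    sigma2 = s0sq * d0 / rng.chisquare(d0, size=n_genes)
    cols = {}
    for cond in ("Ctr", "TNF"):
        for r in range(1, 4):
            cols[f"{cond}_{r}"] = rng.normal(0.0, 1.0, n_genes) * np.sqrt(sigma2)
    values = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    m = ExpressionMatrix(values, {c: c.rsplit("_", 1)[0] for c in values.columns})
    params = fit_moderation(m, TNF_VS_CTR)
    assert params.prior_df == pytest.approx(d0, rel=0.25)
    assert params.prior_variance == pytest.approx(s0sq, rel=0.25)


def test_all_zero_variances_are_degenerate():
    values = pd.DataFrame(
        np.tile([[1.0, 1.0, 2.0, 2.0]], (20, 1)),
        index=[f"g{i}" for i in range(20)],
        columns=["Ctr_1", "Ctr_2", "TNF_1", "TNF_2"],
    )
    m = ExpressionMatrix(values, {c: c.rsplit("_", 1)[0] for c in values.columns})
    with pytest.raises(DegenerateDataError):
        fit_moderation(m, TNF_VS_CTR)


def test_d0_zero_matches_textbook_pooled_t():
    m = make_null_matrix(200, n_rep=3, seed=7)
    params = ModerationParams(prior_df=0.0, prior_variance=1.0)
    ours = moderated_test(m, TNF_VS_CTR, params)
    a = m.condition_values("TNF")
    b = m.condition_values("Ctr")
    t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
    np.testing.assert_allclose(ours["t"].to_numpy(), t_ref, atol=1e-10)
    np.testing.assert_allclose(ours["p"].to_numpy(), p_ref, atol=1e-10)


def test_zero_delta_gives_t_zero_p_one():
    values = pd.DataFrame(
        {"Ctr_1": [1.0], "Ctr_2": [2.0], "TNF_1": [1.0], "TNF_2": [2.0]}, index=["g"]
    )
    m = ExpressionMatrix(values, {c: c.rsplit("_", 1)[0] for c in values.columns})
    res = moderated_test(m, TNF_VS_CTR, ModerationParams(0.0, 1.0))
    assert res.loc["g", "t"] == 0.0
    assert res.loc["g", "p"] == 1.0


def test_insufficient_replication_rejected():
    with pytest.raises(InputError):
        # ExpressionMatrix itself refuses single-sample conditions
        ExpressionMatrix(
            pd.DataFrame({"Ctr_1": [1.0], "TNF_1": [2.0]}, index=["g"]),
            {"Ctr_1": "Ctr", "TNF_1": "TNF"},
        )


def test_type_one_error_calibrated_at_alpha():
    m = make_null_matrix(2000, seed=123)
    params = fit_moderation(m, TNF_VS_CTR)
    res = moderated_test(m, TNF_VS_CTR, params)
    rate = (res["p"] < 0.05).mean()
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / 2000)
    assert abs(rate - 0.05) <= half_width


# ---------------------------------------------------------------- q-values
def test_bh_hand_computed_step_up():
    q = estimate_qvalues([0.01, 0.04, 0.03], method="bh")
    np.testing.assert_allclose(q, [0.03, 0.04, 0.04])


def test_all_p_one_saturates():
    assert (estimate_qvalues([1.0] * 30, method="storey") == 1.0).all()


def test_storey_never_exceeds_bh():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(size=400), rng.uniform(0, 1e-3, size=100)])
    q_bh = estimate_qvalues(p, method="bh")
    q_st = estimate_qvalues(p, method="storey")
    assert (q_st <= q_bh + 1e-12).all()


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
def test_qvalues_monotone_in_p(p):
    q = estimate_qvalues(p, method="bh")
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_empty_p_gives_empty_q():
    assert estimate_qvalues([], method="storey").size == 0


def test_invalid_p_rejected():
    with pytest.raises(InputError):
        estimate_qvalues([0.5, 1.5])


# ------------------------------------------------------------------- calls
@pytest.mark.parametrize(
    "ratio,q,expected",
    [
        (1.66, 0.01, "up"),
        (1.2, 0.001, "none"),
        (0.03, 0.001, "down"),
        (0.8, 0.001, "none"),
        (2.0, 0.05, "none"),  # q not strictly below the level
    ],
)
def test_call_de_rule(ratio, q, expected):
    assert call_de(ratio, q) == expected


def test_calls_partition_genes(small_study):
    table = de_table(small_study.expression, TNF_VS_CTR)
    assert set(table["call"]) <= {"up", "down", "none"}
    assert table["call"].notna().all()


def test_de_recovery_on_planted_effects(small_study):
    from tfcrosstalk.simulate import score_de_recovery

    tables = {"tnf_vs_ctr": de_table(small_study.expression, TNF_VS_CTR)}
    score = score_de_recovery(tables, small_study.truth)
    assert score["sensitivity"] >= 0.9
    assert score["fdr"] <= 0.15
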