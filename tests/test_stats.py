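"""Regression, ANOVA, Tukey and agreement against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from engagelab.praat_io import ValidationError
from engagelab.stats import (
    anova_eta2,
    downsample_equal,
    fit_ols,
    individual_and_total,
    interrater_agreement,
)


def normal_equations(X: np.ndarray, y: np.ndarray):
    """Independent closed-form OLS: beta, SE, R2 via (X'X)^-1 X'y."""
    Xc = np.column_stack([np.ones(len(y)), X])
    xtx_inv = np.linalg.inv(Xc.T @ Xc)
    beta = xtx_inv @ Xc.T @ y
    resid = y - Xc @ beta
    df = len(y) - Xc.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * s2)
    r2 = 1.0 - (resid @ resid) / np.sum((y - y.mean()) ** 2)
    return beta, se, r2


def test_noiseless_line():
    x = np.arange(10.0)
    y = 2.0 * x + 1.0
    fit = fit_ols(pd.DataFrame({"x": x}), y)
    assert fit.params["x"] == pytest.approx(2.0)
    assert fit.params["const"] == pytest.approx(1.0)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.df_resid == 8


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=50, deadline=None)
def test_ols_equals_normal_equations(seed):
    rng = np.random.default_rng(seed)
    n, k = 25, 3
    X = rng.normal(0, 1, size=(n, k))
    y = rng.normal(0, 1, size=n)
    fit = fit_ols(pd.DataFrame(X, columns=list("abc")), y)
    beta, se, r2 = normal_equations(X, y)
    assert np.allclose(fit.params.to_numpy(), beta, rtol=1e-8)
    assert np.allclose(fit.se.to_numpy(), se, rtol=1e-8)
    assert fit.r2 == pytest.approx(r2, rel=1e-8)


def test_p_values_from_t_distribution():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 2))
    y = X[:, 0] * 0.5 + rng.normal(size=30)
    fit = fit_ols(pd.DataFrame(X, columns=["a", "b"]), y)
    expect = 2 * scipy.stats.t.sf(np.abs(fit.t["a"]), df=fit.df_resid)
    assert fit.p["a"] == pytest.approx(expect, rel=1e-10)


def test_rank_deficiency_names_columns():
    rng = np.random.default_rng(0)
    a = rng.normal(size=30)
    X = pd.DataFrame({"a": a, "b": rng.normal(size=30), "dup": 2 * a})
    with pytest.raises(ValidationError, match="collinear"):
        fit_ols(X, rng.normal(size=30))


def test_constant_column_rejected():
    X = pd.DataFrame({"a": np.arange(10.0), "c": np.ones(10)})
    with pytest.raises(ValidationError, match="constant"):
        fit_ols(X, np.arange(10.0))


def test_too_few_rows_rejected():
    X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
    with pytest.raises(ValidationError, match="n > k"):
        fit_ols(X, np.array([1.0, 2.0]))


def test_individual_equals_total_for_single_predictor():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"x": rng.normal(size=40)})
    y = 0.3 * X["x"].to_numpy() + rng.normal(size=40)
    rep = individual_and_total(X, y)
    row = rep.table.loc["x"]
    assert row["individual_coef"] == pytest.approx(row["total_coef"])
    assert row["individual_se"] == pytest.approx(row["total_se"])
    assert rep.total_r2 == pytest.approx(row["individual_r2"])


def test_orthogonal_predictors_coefficients_match():
    """With exactly orthogonal centered predictors, joint = marginal slopes."""
    n = 32
    t = np.arange(n)
    a = np.cos(2 * np.pi * t / n)
    b = np.sin(2 * np.pi * t / n)
    rng = np.random.default_rng(2)
    y = 1.0 + 2.0 * a - 3.0 * b + rng.normal(0, 0.5, size=n)
    rep = individual_and_total(pd.DataFrame({"a": a, "b": b}), y)
    for col in ("a", "b"):
        assert rep.table.loc[col, "total_coef"] == pytest.approx(
            rep.table.loc[col, "individual_coef"], abs=1e-8
        )


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_total_r2_dominates_individual(seed):
    """Nesting: the joint model's R2 is >= every single-predictor R2."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    y = rng.normal(size=30)
    rep = individual_and_total(X, y)
    assert rep.total_r2 >= rep.table["individual_r2"].max() - 1e-12
    assert rep.error_df == 30 - 5


def test_downsample_equal_sizes_and_determinism():
    groups = {"a": np.arange(5.0), "b": np.arange(3.0), "c": np.arange(7.0)}
    out1 = downsample_equal(groups, seed=9)
    out2 = downsample_equal(groups, seed=9)
    assert all(len(v) == 3 for v in out1.values())
    for k in groups:
        assert np.array_equal(out1[k], out2[k])
        assert set(out1[k]) <= set(groups[k])
    assert np.array_equal(out1["b"], groups["b"])  # already minimal: unchanged
    different = downsample_equal(groups, seed=10)
    assert any(not np.array_equal(out1[k], different[k]) for k in ("a", "c"))


def test_eta_squared_worked_example():
    """Groups {1,2} and {3,4}: SSB 4, SST 5, eta^2 = 0.8."""
    rep = anova_eta2({"g1": [1.0, 2.0], "g2": [3.0, 4.0]})
    assert rep.eta_squared == pytest.approx(0.8)
    assert rep.group_means == {"g1": 1.5, "g2": 3.5}


def test_eta_squared_zero_when_means_equal():
    rep = anova_eta2({"g1": [1.0, 3.0], "g2": [2.0, 2.0]})
    assert rep.eta_squared == pytest.approx(0.0)


def test_two_group_f_equals_squared_t():
    rng = np.random.default_rng(4)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
    rep = anova_eta2({"a": a, "b": b})
    t, p = scipy.stats.ttest_ind(a, b)
    assert rep.f_stat == pytest.approx(t**2, abs=1e-9)
    assert rep.p_value == pytest.approx(p, abs=1e-12)


def test_zero_variance_rejected():
    with pytest.raises(ValidationError, match="variance"):
        anova_eta2({"a": [2.0, 2.0], "b": [2.0, 2.0]})


def test_tukey_matches_studentized_range_oracle():
    """Balanced 3-group example: adjusted p from the studentized range."""
    groups = {
        "g1": np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
        "g2": np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
        "g3": np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0]),
    }
    rep = anova_eta2(groups)
    arrays = list(groups.values())
    n = 6
    k = 3
    df = k * (n - 1)
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    for _, row in rep.tukey.iterrows():
        m1 = groups[row["group1"]].mean()
        m2 = groups[row["group2"]].mean()
        q = abs(m2 - m1) / np.sqrt(msw / n)
        p_expect = scipy.stats.studentized_range.sf(q, k, df)
        assert float(row["p_adj"]) == pytest.approx(p_expect, abs=1e-3)


def test_agreement_identical_and_worked_example():
    rep = interrater_agreement([1, 2, 3], [1, 2, 3])
    assert (rep.pct_exact, rep.pct_within_one, rep.pct_approx) == (100.0, 0.0, 100.0)
    rep2 = interrater_agreement([1, 3], [2, 5])
    assert (rep2.pct_exact, rep2.pct_within_one, rep2.pct_approx) == (0.0, 50.0, 50.0)


@given(st.lists(st.integers(1, 5), min_size=1, max_size=50),
       st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_agreement_identity(scores, seed):
    rng = np.random.default_rng(seed)
    r2 = [int(np.clip(s + rng.integers(-2, 3), 1, 5)) for s in scores]
    rep = interrater_agreement(scores, r2)
    assert rep.pct_approx == pytest.approx(rep.pct_exact + rep.pct_within_one)
    assert 0 <= rep.pct_exact <= 100 and 0 <= rep.pct_approx <= 100


def test_agreement_length_mismatch():
    with pytest.raises(ValidationError):
        interrater_agreement([1, 2], [1, 2, 3])
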