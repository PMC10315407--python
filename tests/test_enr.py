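"""Elastic-net solver oracles, KKT conditions, and stability selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidfa.enr import (
    ENRConfig,
    confirmatory_lm,
    enr_solve,
    lambda_grid,
    stability_select,
    tune,
)


def _instance(seed, n=60, p=8, sparse=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.zeros(p)
    beta[:3] = [1.5, -1.0, 0.5]
    y = X @ beta + rng.standard_normal(n)
    return X, y


def test_ols_limit_at_zero_lambda():
    X, y = _instance(0)
    b, b0 = enr_solve(X, y, alpha=0.5, lam=0.0)
    ols = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)[0]
    np.testing.assert_allclose(b, ols[1:], atol=1e-6)
    assert b0 == pytest.approx(ols[0], abs=1e-6)


def test_univariate_soft_threshold_closed_form(rng):
    x = rng.standard_normal(150)
    x = (x - x.mean()) / x.std()
    y = 0.6 * x + rng.standard_normal(150)
    lam = 0.25
    b, _ = enr_solve(x[:, None], y, alpha=1.0, lam=lam)
    n = len(y)
    rho = (x - x.mean()) @ (y - y.mean()) / n
    ss = ((x - x.mean()) ** 2).sum() / n
    expected = np.sign(rho) * max(abs(rho) - lam, 0.0) / ss
    assert b[0] == pytest.approx(expected, abs=1e-10)


def test_ridge_closed_form():
    X, y = _instance(3)
    n, p = X.shape
    lam = 0.7
    b, _ = enr_solve(X, y, alpha=0.0, lam=lam)
    xc = X - X.mean(0)
    yc = y - y.mean()
    expected = np.linalg.solve(xc.T @ xc / n + lam * np.eye(p), xc.T @ yc / n)
    np.testing.assert_allclose(b, expected, atol=1e-6)


def test_sklearn_cross_check():
    from sklearn.linear_model import ElasticNet

    X, y = _instance(5)
    ours, _ = enr_solve(X, y, alpha=0.7, lam=0.3)
    ref = ElasticNet(alpha=0.3, l1_ratio=0.7, tol=1e-12, max_iter=10**6).fit(X, y)
    np.testing.assert_allclose(ours, ref.coef_, atol=1e-6)


@given(seed=st.integers(0, 1000), alpha=st.floats(0.1, 1.0), lam=st.floats(0.01, 1.0))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_kkt_conditions_hold_at_solution(seed, alpha, lam):
    """Subgradient optimality of the elastic-net objective at the output."""
    X, y = _instance(seed)
    n = X.shape[0]
    b, b0 = enr_solve(X, y, alpha, lam)
    resid = y - b0 - X @ b
    grad = -(X - X.mean(0)).T @ resid / n + lam * (1 - alpha) * b
    for j in range(X.shape[1]):
        if b[j] != 0:
            assert grad[j] + lam * alpha * np.sign(b[j]) == pytest.approx(0, abs=1e-5)
        else:
            assert abs(grad[j]) <= lam * alpha + 1e-5


def test_monotone_sparsity_along_lambda_path():
    X, y = _instance(11)
    lams = lambda_grid(X, y, alpha=1.0, n_lambdas=30)
    nnz = [np.count_nonzero(enr_solve(X, y, 1.0, lam)[0]) for lam in lams]
    assert all(a <= b for a, b in zip(nnz, nnz[1:]))  # lams descend, support grows
    assert nnz[0] == 0  # lambda_max zeroes everything


def test_tune_one_point_grid_and_small_n_error():
    X, y = _instance(2)
    assert tune(X, y, ENRConfig(seed=0), grid=[(0.5, 0.1)]) == (0.5, 0.1)
    with pytest.raises(ValueError):
        tune(X[:4], y[:4], ENRConfig(seed=0, train_fraction=0.9))


def test_tune_shrinks_toward_null_without_signal():
    """y independent of X: selected lambda lands in the grid's upper half."""
    rng = np.random.default_rng(8)
    high = 0
    runs = 10
    for s in range(runs):
        X = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        lams = lambda_grid(X, y, alpha=0.5, n_lambdas=20)
        grid = [(0.5, lam) for lam in lams]
        _, lam = tune(X, y, ENRConfig(seed=s, folds=10), grid=grid)
        high += lam >= np.median(lams)
    assert high / runs >= 0.8


def test_tune_recovers_sparse_signal_support():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((100, 10))
    beta = np.zeros(10)
    beta[:2] = [2.0, -1.5]
    y = X @ beta  # noiseless
    a, lam = tune(X, y, ENRConfig(seed=1, alphas=(0.5, 1.0), n_lambdas=25))
    lams = lambda_grid(X, y, a, 25)
    assert lam < np.median(lams)
    b, _ = enr_solve(X, y, a, lam)
    assert set(np.nonzero(np.abs(b) > 0.05)[0]) >= {0, 1}


class TestStabilitySelection:
    def test_signal_retained_with_full_count(self):
        rng = np.random.default_rng(21)
        n = 113
        X = rng.standard_normal((n, 21))
        y = 2.0 * X[:, 0] + 0.5 * rng.standard_normal(n)
        cols = [f"fa{j}" for j in range(21)]
        model = stability_select(pd.DataFrame(X, columns=cols), y,
                                 alpha=1.0, lam=0.15, seed=4)
        retained = {name: (coef, count) for name, coef, count in model.retained}
        assert "fa0" in retained
        coef, count = retained["fa0"]
        assert count == 10
        assert coef == pytest.approx(2.0, rel=0.25)  # shrinkage expected
        assert model.pearson_r > 0.9

    def test_selection_counts_invariant_to_column_order(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((80, 6))
        y = 1.5 * X[:, 2] + rng.standard_normal(80)
        cols = [f"c{j}" for j in range(6)]
        m1 = stability_select(pd.DataFrame(X, columns=cols), y, 1.0, 0.2, seed=9)
        perm = [3, 1, 5, 0, 2, 4]
        m2 = stability_select(pd.DataFrame(X[:, perm], columns=[cols[j] for j in perm]),
                              y, 1.0, 0.2, seed=9)
        assert m1.selection_counts == m2.selection_counts

    def test_retain_min_zero_keeps_every_selected(self):
        rng = np.random.default_rng(41)
        X = rng.standard_normal((60, 5))
        y = X[:, 0] + rng.standard_normal(60)
        model = stability_select(X, y, 1.0, 0.1, seed=2, retain_min=0)
        assert {n for n, _, _ in model.retained} == set(model.selection_counts)

    def test_pure_noise_usually_empty(self):
        rng = np.random.default_rng(51)
        empties = 0
        for s in range(10):
            X = rng.standard_normal((113, 20))
            y = rng.standard_normal(113)
            a, lam = tune(X, y, ENRConfig(seed=s, alphas=(0.5, 1.0), n_lambdas=20))
            empties += stability_select(X, y, a, lam, seed=1000 + s).empty
        assert empties >= 8

    def test_collated_pearson_near_zero_on_noise(self):
        rng = np.random.default_rng(61)
        rs = []
        for s in range(40):
            X = rng.standard_normal((60, 8))
            y = rng.standard_normal(60)
            m = stability_select(X, y, 0.5, 0.05, seed=s)
            if not np.isnan(m.pearson_r):
                rs.append(m.pearson_r)
        assert abs(np.mean(rs)) < 0.1


def test_confirmatory_lm_exact_on_noiseless_outcome(rng):
    n = 113
    arms = np.repeat(["SFA", "MUFA", "MUFA_PUFA"], (38, 39, 36))
    preds = pd.DataFrame(
        {"TG[12:0]": rng.standard_normal(n), "CE[18:0]": rng.standard_normal(n)}
    )
    covs = pd.DataFrame(
        {
            "age": rng.normal(44, 10, n),
            "sex": rng.integers(0, 2, n),
            "bmi": rng.normal(27, 4, n),
            "base_marker": rng.normal(3.8, 1.0, n),
            "arm": arms,
        }
    )
    y = pd.Series(0.15 * preds["TG[12:0]"] + 0.20 * preds["CE[18:0]"] + 0.01 * covs["age"])
    results = {r.predictor: r for r in confirmatory_lm(y, preds, covs, marker="LDL")}
    assert results["TG[12:0]"].beta == pytest.approx(0.15, abs=1e-8)
    assert results["CE[18:0]"].beta == pytest.approx(0.20, abs=1e-8)
    for r in results.values():
        assert r.ci_low <= r.beta <= r.ci_high


def test_confirmatory_lm_coverage_of_generating_betas(rng):
    """Table-style generating truths fall inside their 95% CIs most of the time."""
    n = 113
    arms = np.repeat(["SFA", "MUFA", "MUFA_PUFA"], (38, 39, 36))
    cover = 0
    total = 0
    for _ in range(60):
        preds = pd.DataFrame(
            {"TG[12:0]": rng.standard_normal(n), "CE[18:0]": rng.standard_normal(n)}
        )
        covs = pd.DataFrame(
            {
                "age": rng.normal(44, 10, n),
                "sex": rng.integers(0, 2, n),
                "bmi": rng.normal(27, 4, n),
                "base_marker": rng.normal(3.8, 1.0, n),
                "arm": arms,
            }
        )
        y = pd.Series(
            0.15 * preds["TG[12:0]"] + 0.20 * preds["CE[18:0]"]
            - 0.2 * covs["base_marker"] + 0.3 * rng.standard_normal(n)
        )
        for r in confirmatory_lm(y, preds, covs):
            truth = {"TG[12:0]": 0.15, "CE[18:0]": 0.20}[r.predictor]
            cover += r.ci_low <= truth <= r.ci_high
            total += 1
    assert cover / total >= 0.90


def test_confirmatory_lm_rejects_empty_predictor_set(rng):
    covs = pd.DataFrame(
        {"age": [1.0], "sex": [0], "bmi": [25.0], "base_marker": [1.0], "arm": ["SFA"]}
    )
    with pytest.raises(ValueError, match="empty"):
        confirmatory_lm(pd.Series([1.0]), pd.DataFrame(index=[0]), covs)
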