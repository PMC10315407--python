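"""Elastic-net stability selection for risk-marker / lipid-change models.

Links changes (week 16 − week 0) in within-class FA concentrations to
changes in individual cardiometabolic risk markers.  The procedure is:

1. ``tune``: pick the penalty mixing parameter α and strength λ by
   minimizing mean test-set MSE over 10 seeded random 80/20 train/test
   splits of the data, tie-broken toward the sparser model.
2. ``stability_select``: with (α, λ) fixed, refit on 10 fresh seeded 80/20
   splits; retain predictors with nonzero coefficients in at least 9 of the
   10 iterations, averaging each retained coefficient over the iterations
   where it was nonzero.  Out-of-fold predictions from all iterations are
   collated and their Pearson correlation with the measured outcome is the
   model's performance proxy.
3. ``confirmatory_lm``: re-test the retained predictors jointly in a fully
   adjusted OLS (age, sex, BMI, baseline marker, diet arm), reporting β per
   SD of FA change with t-based 95% CIs.

The elastic-net solver itself is cyclic coordinate descent with
soft-thresholding on the objective

    (1/2n)·‖y − β₀ − Xβ‖² + λ·(α‖β‖₁ + (1−α)/2·‖β‖²),

intercept unpenalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ENRConfig",
    "StabilityModel",
    "ConfirmatoryResult",
    "enr_solve",
    "lambda_grid",
    "tune",
    "stability_select",
    "confirmatory_lm",
]


@dataclass
class ENRConfig:
    """Tuning/selection settings for the elastic-net procedure."""

    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))
    n_lambdas: int = 50
    lambda_decades: float = 4.0
    folds: int = 10
    train_fraction: float = 0.8
    retain_min: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.retain_min > self.folds:
            raise ValueError("retain_min cannot exceed the number of iterations")


@dataclass
class StabilityModel:
    """Retained predictors and performance for one risk marker."""

    marker: str
    retained: list[tuple[str, float, int]]  # (predictor, averaged coef, count)
    pearson_r: float
    alpha: float
    lam: float
    seed: int
    selection_counts: dict[str, int] = field(default_factory=dict)
    empty: bool = False


@dataclass
class ConfirmatoryResult:
    """Fully adjusted OLS estimate for one retained predictor."""

    marker: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def enr_solve(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Cyclic coordinate descent for the elastic net; returns (beta, intercept).

    Converges when the largest coefficient change in a full sweep is below
    ``tol``.  Columns of ``X`` are expected standardized (the update is
    exact for any scaling, but λ is only comparable across standardized
    columns).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in X or y")
    if not (0.0 <= alpha <= 1.0) or lam < 0:
        raise ValueError(f"need alpha in [0,1] and lambda >= 0, got {alpha}, {lam}")
    n, p = X.shape
    xc = X - X.mean(axis=0)  # centring absorbs the unpenalized intercept
    yc = y - y.mean()
    col_ss = (xc**2).sum(axis=0) / n
    beta = np.zeros(p)
    resid = yc.copy()
    thr = lam * alpha
    denom = col_ss + lam * (1.0 - alpha)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            if col_ss[j] == 0.0:
                continue
            old = beta[j]
            rho = (xc[:, j] @ resid) / n + col_ss[j] * old
            new = np.sign(rho) * max(abs(rho) - thr, 0.0) / denom[j]
            if new != old:
                resid += xc[:, j] * (old - new)
                beta[j] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    else:
        raise RuntimeError(f"coordinate descent did not converge; last delta {delta:.3e}")
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    return beta, intercept


def lambda_grid(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int = 50, decades: float = 4.0
) -> np.ndarray:
    """Log-spaced λ path from λ_max (all-zero solution) down ``decades`` decades."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.max(np.abs(xc.T @ yc)) / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambdas)


def _splits(n: int, n_splits: int, train_fraction: float, seed: int):
    """Seeded random train/test index pairs (not disjoint folds)."""
    n_test = n - int(round(n * train_fraction))
    if n_test < 2:
        raise ValueError(f"n = {n} too small for a {1 - train_fraction:.0%} test set")
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_splits):
        perm = np.random.default_rng(child).permutation(n)
        out.append((perm[n_test:], perm[:n_test]))
    return out


def tune(
    X: np.ndarray,
    y: np.ndarray,
    config: ENRConfig | None = None,
    grid: list[tuple[float, float]] | None = None,
    one_se: bool = True,
) -> tuple[float, float]:
    """Choose (α, λ) by cross-validated test MSE over seeded 80/20 splits.

    ``grid`` may supply explicit (α, λ) pairs; otherwise each α gets its own
    λ path from ``lambda_grid``.  With ``one_se`` (default) the returned
    pair is the least complex whose mean test MSE is within one standard
    error (of the per-split MSEs at the minimizing configuration) of the
    minimum — complexity measured as the number of nonzero coefficients in
    a full-data fit, ties broken toward larger λ then larger α.  Minimizing
    MSE while penalizing complexity guards against the winner's curse
    across a large grid.  With ``one_se=False`` the strict minimizer is
    returned, ties broken toward larger λ then larger α.
    """
    config = config or ENRConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = [
            (a, lam)
            for a in config.alphas
            for lam in lambda_grid(X, y, a, config.n_lambdas, config.lambda_decades)
        ]
    if not grid:
        raise ValueError("empty tuning grid")
    splits = _splits(len(y), config.folds, config.train_fraction, config.seed)
    by_alpha: dict[float, list[float]] = {}
    for a, lam in grid:
        by_alpha.setdefault(a, []).append(lam)
    # per config: mean/SE over splits of the test MSE, plus full-data sparsity
    results: list[tuple[float, float, float, float, int]] = []  # (mean, se, a, lam, nnz)
    for a, lams in by_alpha.items():
        order = np.argsort(lams)[::-1]  # warm start from the sparsest end
        split_mse = np.zeros((len(splits), len(lams)))
        for k, (tr, te) in enumerate(splits):
            beta = np.zeros(X.shape[1])
            for idx in order:
                beta, b0 = _warm_enr(X[tr], y[tr], a, lams[idx], beta)
                pred = X[te] @ beta + b0
                split_mse[k, idx] = np.mean((y[te] - pred) ** 2)
        nnz = np.zeros(len(lams), dtype=int)
        beta = np.zeros(X.shape[1])
        for idx in order:
            beta, _ = _warm_enr(X, y, a, lams[idx], beta)
            nnz[idx] = np.count_nonzero(beta)
        means = split_mse.mean(axis=0)
        ses = split_mse.std(axis=0, ddof=1) / np.sqrt(len(splits))
        for lam, mu, se, k in zip(lams, means, ses, nnz):
            results.append((mu, se, a, lam, int(k)))
    best = min(results, key=lambda r: r[0])
    cutoff = best[0] + (best[1] if one_se else best[0] * 1e-12)
    eligible = [r for r in results if r[0] <= cutoff]
    # least complex model in the eligible band, then larger lambda, larger alpha
    eligible.sort(key=lambda r: (-r[4], r[3], r[2]))
    _, _, a, lam, _ = eligible[-1]
    return float(a), float(lam)


def _warm_enr(X, y, alpha, lam, beta0):
    """Coordinate descent warm-started at beta0 (path fitting)."""
    n, p = X.shape
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    col_ss = (xc**2).sum(axis=0) / n
    beta = beta0.copy()
    resid = yc - xc @ beta
    thr = lam * alpha
    denom = col_ss + lam * (1.0 - alpha)
    for _ in range(10_000):
        delta = 0.0
        for j in range(p):
            if col_ss[j] == 0.0:
                continue
            old = beta[j]
            rho = (xc[:, j] @ resid) / n + col_ss[j] * old
            new = np.sign(rho) * max(abs(rho) - thr, 0.0) / denom[j]
            if new != old:
                resid += xc[:, j] * (old - new)
                beta[j] = new
                delta = max(delta, abs(new - old))
        if delta < 1e-7:
            break
    b0 = float(y.mean() - X.mean(axis=0) @ beta)
    return beta, b0


def stability_select(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    seed: int,
    n_splits: int = 10,
    train_fraction: float = 0.8,
    retain_min: int = 9,
    marker: str = "",
) -> StabilityModel:
    """Stability selection over seeded 80/20 splits at fixed (α, λ).

    A predictor counts as selected in an iteration iff its training-set
    coefficient is nonzero.  Retained predictors were selected in at least
    ``retain_min`` iterations; their reported coefficient is the mean over
    the iterations where they were nonzero.  Test-set predictions from all
    iterations are collated and the overall Pearson r against the measured
    outcome is reported (NaN, flagged, when no predictor is ever retained
    and predictions are intercept-only constants within iterations).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    counts = np.zeros(Xa.shape[1], dtype=int)
    coef_sums = np.zeros(Xa.shape[1])
    preds, meas = [], []
    for tr, te in _splits(len(y), n_splits, train_fraction, seed):
        beta, b0 = enr_solve(Xa[tr], y[tr], alpha, lam)
        nz = beta != 0.0
        counts += nz
        coef_sums[nz] += beta[nz]
        preds.append(Xa[te] @ beta + b0)
        meas.append(y[te])
    retained_idx = [j for j in np.nonzero(counts >= retain_min)[0]] if retain_min > 0 else [
        j for j in np.nonzero(counts > 0)[0]
    ]
    retained = [(names[j], float(coef_sums[j] / counts[j]), int(counts[j])) for j in retained_idx]
    pred_all = np.concatenate(preds)
    meas_all = np.concatenate(meas)
    empty = len(retained) == 0
    if np.std(pred_all) == 0 or np.std(meas_all) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred_all, meas_all).statistic)
    return StabilityModel(
        marker=marker,
        retained=retained,
        pearson_r=float("nan") if empty and np.isnan(r) else r,
        alpha=alpha,
        lam=lam,
        seed=seed,
        selection_counts={names[j]: int(c) for j, c in enumerate(counts) if c > 0},
        empty=empty,
    )


def confirmatory_lm(
    marker_delta: pd.Series,
    predictor_deltas: pd.DataFrame,
    covariates: pd.DataFrame,
    marker: str = "",
) -> list[ConfirmatoryResult]:
    """Fully adjusted OLS of a marker change on all retained predictors jointly.

    ``predictor_deltas`` columns are z-scored within-class FA changes;
    ``covariates`` must contain ``age``, ``sex``, ``bmi``, ``base_marker``
    and ``arm`` (3-level factor, dummy-coded).  β is the marker change per
    SD of FA change, with t-based 95% CI.
    """
    if predictor_deltas.shape[1] == 0:
        raise ValueError("retained predictor set is empty")
    dummies = pd.get_dummies(covariates["arm"], drop_first=True, dtype=float, prefix="arm")
    X = pd.concat(
        [
            predictor_deltas.astype(float),
            covariates[["age", "sex", "bmi", "base_marker"]].astype(float),
            dummies,
        ],
        axis=1,
    )
    X = sm.add_constant(X)
    fit = sm.OLS(marker_delta.astype(float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = []
    for name in predictor_deltas.columns:
        out.append(
            ConfirmatoryResult(
                marker=marker,
                predictor=str(name),
                beta=float(fit.params[name]),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                p=float(fit.pvalues[name]),
                n=int(fit.nobs),
            )
        )
    return out
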