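"""Prentice-weighted Cox proportional-hazards models for nested case-cohorts.

A nested case-cohort pairs a random subcohort with all incident cases from
the full cohort.  Under Prentice weighting, subcohort members contribute to
every risk set spanning their observation window, while cases outside the
subcohort enter only the risk set at their own failure time.  Time is
attained age, with left truncation at entry age.

The fit maximizes the resulting pseudo-partial-likelihood (Breslow tie
handling) by Newton–Raphson, and reports a robust sandwich variance grouped
by individual, which is the appropriate variance under case-cohort
weighting (the model-based inverse information is anti-conservative).

Multiple-testing control across a panel of exposures offers both
Benjamini–Hochberg FDR and Bonferroni side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxAssociation",
    "PrenticeCoxFit",
    "ConvergenceError",
    "SeparationError",
    "validate_records",
    "prentice_riskset",
    "fit_prentice_cox",
    "cox_association_table",
    "fdr_bh",
    "schoenfeld_check",
]

REQUIRED_COLUMNS = ("id", "in_subcohort", "is_case", "entry_age", "exit_age", "event")


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge."""


class SeparationError(ConvergenceError):
    """Monotone likelihood (estimate diverging); consider penalization."""


@dataclass
class CoxAssociation:
    """One exposure–outcome association on the hazard-ratio scale."""

    target: str
    outcome: str
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p_raw: float
    n: int
    n_cases: int
    p_fdr: float | None = None
    p_bonf: float | None = None


@dataclass
class PrenticeCoxFit:
    """Converged fit: coefficients, robust covariance, and bookkeeping."""

    params: pd.Series
    cov: pd.DataFrame  # robust sandwich, grouped by id
    cov_model: pd.DataFrame  # inverse information (diagnostic only)
    loglik: float
    n: int
    n_events: int
    n_iter: int
    event_times: np.ndarray

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        se = self.se
        z = self.params / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": np.exp(self.params),
                "se_robust": se,
                "ci_low": np.exp(self.params - 1.959963984540054 * se),
                "ci_high": np.exp(self.params + 1.959963984540054 * se),
                "p": p,
            }
        )


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the case-cohort record invariants; returns the frame unchanged.

    Exit age must exceed entry age (each participant contributes until
    diagnosis, death, loss to follow-up or the censoring date, whichever is
    first); every case has the event flag; every record outside the
    subcohort must be a case.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"case-cohort table missing column {col!r}")
    if (records["entry_age"] >= records["exit_age"]).any():
        bad = records.loc[records["entry_age"] >= records["exit_age"], "id"].tolist()
        raise ValueError(f"entry_age >= exit_age for ids: {bad}")
    if (records["is_case"].astype(bool) != records["event"].astype(bool)).any():
        raise ValueError("is_case and event flags disagree")
    outside = ~records["in_subcohort"].astype(bool)
    if (outside & ~records["is_case"].astype(bool)).any():
        bad = records.loc[outside & ~records["is_case"].astype(bool), "id"].tolist()
        raise ValueError(f"non-subcohort non-cases present: {bad}")
    return records


def prentice_riskset(records: pd.DataFrame, t: float) -> set:
    """IDs at risk at failure age ``t`` under Prentice weighting.

    Subcohort members are at risk whenever ``entry_age < t <= exit_age``;
    a case outside the subcohort is at risk only at its own failure age.
    An age outside all observation windows yields an empty set.
    """
    sub = records["in_subcohort"].astype(bool)
    in_window = (records["entry_age"] < t) & (t <= records["exit_age"])
    own_failure = records["event"].astype(bool) & (records["exit_age"] == t)
    mask = (sub & in_window) | (~sub & own_failure)
    return set(records.loc[mask, "id"])


def _prepare(records: pd.DataFrame, covariates: list[str]):
    records = validate_records(records)
    X = records[covariates].to_numpy(dtype=float)
    entry = records["entry_age"].to_numpy(dtype=float)
    exit_ = records["exit_age"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    sub = records["in_subcohort"].to_numpy(dtype=bool)
    times = np.unique(exit_[event])
    if times.size == 0:
        raise ValueError("zero events in case-cohort table")
    # membership[i, j]: subject i in the Prentice risk set of failure time j
    in_window = (entry[:, None] < times[None, :]) & (times[None, :] <= exit_[:, None])
    own = event[:, None] & (exit_[:, None] == times[None, :])
    membership = (sub[:, None] & in_window) | (~sub[:, None] & own)
    # fails[i, j]: subject i fails at time j
    fails = event[:, None] & (exit_[:, None] == times[None, :])
    return X, membership, fails, times, event


def _loglik_score_info(beta, X, membership, fails):
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; cancels in ratios
    w = np.exp(eta)
    WM = w[:, None] * membership  # n x D
    S0 = WM.sum(axis=0)  # D
    S1 = WM.T @ X  # D x p
    d = fails.sum(axis=0)  # failures per time (Breslow)
    xbar = S1 / S0[:, None]
    # the eta shift adds the same constant to failure terms and log S0 terms
    ll = float(eta[fails.any(axis=1)].sum() - (d * np.log(S0)).sum())
    score = (fails.T @ X - d[:, None] * xbar).sum(axis=0)
    # information: sum_j d_j * (S2_j/S0_j - xbar_j xbar_j')
    info = np.zeros((p, p))
    for j in range(len(S0)):
        Wj = WM[:, j]
        S2 = (X * Wj[:, None]).T @ X
        V = S2 / S0[j] - np.outer(xbar[j], xbar[j])
        info += d[j] * V
    return ll, score, info, w, S0, xbar, d


def fit_prentice_cox(
    records: pd.DataFrame,
    covariates: list[str],
    max_iter: int = 50,
    score_tol: float = 1e-9,
    ll_tol: float = 1e-12,
) -> PrenticeCoxFit:
    """Maximize the Prentice pseudo-partial-likelihood by Newton–Raphson.

    ``covariates`` names numeric columns of ``records`` (the exposure of
    interest conventionally first).  Convergence when max |score| <
    ``score_tol`` or the relative log-likelihood change < ``ll_tol``.
    Coefficients wandering beyond |β| > 10 raise :class:`SeparationError`.
    """
    X, membership, fails, times, event = _prepare(records, covariates)
    p = X.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, score, info, *_ = _loglik_score_info(beta, X, membership, fails)
        # a per-SD log hazard ratio beyond 10 is monotone-likelihood territory
        if np.max(np.abs(beta)) > 10:
            raise SeparationError(
                f"separation suspected (|beta| > 10 at iteration {n_iter}); "
                "consider penalization"
            )
        if np.max(np.abs(score)) < score_tol:
            break
        if np.isfinite(ll_old) and abs(ll - ll_old) < ll_tol * max(1.0, abs(ll_old)):
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {n_iter}") from exc
        # halve steps that do not improve the likelihood
        factor = 1.0
        for _ in range(30):
            new_ll = _loglik_score_info(beta + factor * step, X, membership, fails)[0]
            if new_ll >= ll - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        ll_old = ll
    else:
        raise ConvergenceError(
            f"Newton–Raphson did not converge in {max_iter} iterations; "
            f"max |score| = {np.max(np.abs(score)):.3e}"
        )
    ll, score, info, w, S0, xbar, d = _loglik_score_info(beta, X, membership, fails)
    info_inv = np.linalg.inv(info)
    # score residuals per subject (one record per individual here):
    #   U_i = sum_j fails_ij (x_i - xbar_j) - sum_j mem_ij w_i d_j / S0_j (x_i - xbar_j)
    r = d / S0
    a = membership @ r  # n
    U = (fails.sum(axis=1)[:, None] * X) - (fails @ xbar)
    U -= w[:, None] * (X * a[:, None] - membership @ (r[:, None] * xbar))
    B = U.T @ U
    cov_robust = info_inv @ B @ info_inv
    idx = pd.Index(covariates)
    return PrenticeCoxFit(
        params=pd.Series(beta, index=idx),
        cov=pd.DataFrame(cov_robust, index=idx, columns=idx),
        cov_model=pd.DataFrame(info_inv, index=idx, columns=idx),
        loglik=ll,
        n=len(records),
        n_events=int(event.sum()),
        n_iter=n_iter,
        event_times=times,
    )


def cox_association_table(
    records: pd.DataFrame,
    exposures: pd.DataFrame,
    outcome: str,
    adjust: list[str],
    class_total_col: str | None = "class_total",
    bonferroni_m: int | None = None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Fit one Prentice-Cox model per exposure column and adjust p-values.

    ``exposures`` holds log+z within-class FA columns aligned with
    ``records``; each model is adjusted for ``adjust`` covariate columns of
    ``records`` plus (when present) the exposure's class total.  Both BH-FDR
    and Bonferroni (0.05/m) adjusted p-values are reported side by side.
    """
    rows: list[CoxAssociation] = []
    for col in exposures.columns:
        df = records.copy()
        df["_exposure"] = exposures[col].to_numpy(dtype=float)
        covs = ["_exposure"] + list(adjust)
        if class_total_col and class_total_col in df.columns:
            covs.append(class_total_col)
        fit = fit_prentice_cox(df, covs)
        s = fit.summary().loc["_exposure"]
        rows.append(
            CoxAssociation(
                target=str(col),
                outcome=outcome,
                log_hr=float(fit.params["_exposure"]),
                hr=float(s["hr"]),
                ci_low=float(s["ci_low"]),
                ci_high=float(s["ci_high"]),
                p_raw=float(s["p"]),
                n=fit.n,
                n_cases=fit.n_events,
            )
        )
    p_raw = np.array([r.p_raw for r in rows])
    p_fdr = fdr_bh(p_raw)
    m = bonferroni_m if bonferroni_m is not None else len(rows)
    p_bonf = np.minimum(1.0, m * p_raw)
    for r, pf, pb in zip(rows, p_fdr, p_bonf):
        r.p_fdr, r.p_bonf = float(pf), float(pb)
    table = pd.DataFrame([vars(r) for r in rows])
    table.attrs["bonferroni_threshold"] = 0.05 / m
    table.attrs["fdr_q"] = fdr_q
    return table


def fdr_bh(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def schoenfeld_check(fit: PrenticeCoxFit, records: pd.DataFrame) -> pd.DataFrame:
    """Scaled Schoenfeld residuals correlated against event age.

    A diagnostic for proportional hazards, reported per covariate as a
    Pearson correlation with its p-value — never a gate.  Needs at least
    two events; otherwise returns an empty frame.
    """
    covariates = list(fit.params.index)
    X, membership, fails, times, event = _prepare(records, covariates)
    if event.sum() < 2:
        return pd.DataFrame(columns=["covariate", "rho", "p"])
    beta = fit.params.to_numpy()
    _, _, _, w, S0, xbar, d = _loglik_score_info(beta, X, membership, fails)
    resid_rows, resid_times = [], []
    for j, t in enumerate(times):
        for i in np.nonzero(fails[:, j])[0]:
            resid_rows.append(X[i] - xbar[j])
            resid_times.append(t)
    resid = np.asarray(resid_rows)
    scaled = fit.n_events * resid @ fit.cov_model.to_numpy() + beta  # Grambsch–Therneau
    ages = np.asarray(resid_times)
    out = []
    for k, name in enumerate(covariates):
        col = scaled[:, k]
        if np.std(col) == 0 or np.std(ages) == 0:
            rho, pv = np.nan, np.nan
        else:
            res = stats.pearsonr(col, ages)
            rho, pv = float(res.statistic), float(res.pvalue)
        out.append({"covariate": name, "rho": rho, "p": pv})
    return pd.DataFrame(out)
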