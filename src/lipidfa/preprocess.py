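"""Missingness filtering, left-censored imputation, and transforms.

Concentration matrices are pandas DataFrames with sample IDs on the index
and species shorthand names as columns, values in μmol/L, missing cells as
NaN.  Missingness in this assay is left-censoring: a species is absent when
its concentration falls below the platform's detection limit, so imputed
values must sit below the species' observed minimum.

The imputation is quantile-regression imputation of left-censored data
(QRILC): per species, on the natural-log scale, the mean and SD of the
uncensored distribution are estimated by least-squares regression of the
observed order statistics against standard-normal quantiles at plotting
positions shifted for the censored fraction; missing cells are then drawn
from that normal truncated above at the observed minimum.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImputationReport",
    "missingness_filter",
    "qrilc_impute",
    "log_z",
    "change_from_baseline",
]


@dataclass
class ImputationReport:
    """Audit record of an exclusion/imputation pass."""

    excluded_species: dict[str, float] = field(default_factory=dict)
    imputed_cell_count: int = 0
    censor_threshold: dict[str, float] = field(default_factory=dict)
    fallback_species: list[str] = field(default_factory=list)
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Per-species audit table (one row per excluded or imputed species)."""
        rows = []
        for sp, frac in self.excluded_species.items():
            rows.append({"species": sp, "action": "excluded", "missing_fraction": frac,
                         "censor_threshold": np.nan})
        for sp, thr in self.censor_threshold.items():
            rows.append({"species": sp,
                         "action": "fallback" if sp in self.fallback_species else "imputed",
                         "missing_fraction": np.nan, "censor_threshold": thr})
        return pd.DataFrame(rows, columns=["species", "action", "missing_fraction",
                                           "censor_threshold"])


def missingness_filter(
    values: pd.DataFrame, threshold: float = 0.75
) -> tuple[pd.DataFrame, ImputationReport]:
    """Drop species whose missing fraction is >= ``threshold``.

    The rule is inclusive: a species missing in exactly 75% of samples is
    excluded at the default threshold.  Samples are never dropped.
    """
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("empty concentration matrix")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"missingness threshold must be in (0, 1], got {threshold}")
    frac = values.isna().mean(axis=0)
    excluded = frac[frac >= threshold]
    report = ImputationReport(excluded_species=dict(excluded))
    return values.drop(columns=excluded.index), report


def _column_seed(master: int, observed: np.ndarray, n_missing: int) -> np.random.Generator:
    # Substream keyed by the observed data itself, so identical columns impute
    # identically under one master seed.
    h = hashlib.sha256()
    h.update(np.int64(master).tobytes())
    h.update(np.sort(observed).astype(np.float64).tobytes())
    h.update(np.int64(n_missing).tobytes())
    key = int.from_bytes(h.digest()[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([master & 0x7FFFFFFF, key]))


def _qrilc_fit(log_obs: np.ndarray, n_total: int) -> tuple[float, float]:
    """Estimate (mu, sigma) of the uncensored log-normal by order-statistic regression.

    The k smallest of ``n_total`` values are censored, so the sorted observed
    values occupy ranks k+1..n_total; Blom plotting positions at those ranks
    give the normal quantiles regressed against.
    """
    n_obs = log_obs.size
    k = n_total - n_obs
    ranks = np.arange(k + 1, n_total + 1)
    pp = (ranks - 0.375) / (n_total + 0.25)
    q = stats.norm.ppf(pp)
    A = np.column_stack([np.ones(n_obs), q])
    (mu, sigma), *_ = np.linalg.lstsq(A, np.sort(log_obs), rcond=None)
    if sigma <= 0:  # degenerate tiny-n geometry; fall back to the sample SD
        sigma = float(np.std(log_obs, ddof=1)) or 1e-8
    return float(mu), float(sigma)


def qrilc_impute(
    values: pd.DataFrame, seed: int, tune_sigma: float = 1.0
) -> tuple[pd.DataFrame, ImputationReport]:
    """Impute left-censored cells per species; observed cells never change.

    Per species with missing cells: estimate (μ, σ) of the uncensored
    log-scale distribution by quantile regression of order statistics, then
    draw each missing cell from Normal(μ, ``tune_sigma``·σ) truncated above
    at the species' minimum observed log-concentration, and exponentiate.
    Deterministic given ``seed``.

    Species with fewer than 3 observed values cannot support the regression
    and are imputed with half the global minimum observed concentration,
    flagged in the report.
    """
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("empty concentration matrix")
    obs_all = values.to_numpy(dtype=float)
    if np.any(obs_all[~np.isnan(obs_all)] <= 0):
        raise ValueError("non-positive observed concentration; values must be > 0")
    out = values.copy()
    report = ImputationReport(seed=seed)
    global_min = np.nanmin(obs_all)
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        miss = np.isnan(v)
        if not miss.any():
            continue
        observed = v[~miss]
        n_missing = int(miss.sum())
        if observed.size < 3:
            fill = global_min / 2.0
            out.loc[miss, col] = fill
            report.censor_threshold[col] = fill
            report.fallback_species.append(col)
            report.imputed_cell_count += n_missing
            continue
        log_obs = np.log(observed)
        mu, sigma = _qrilc_fit(log_obs, v.size)
        sigma *= tune_sigma
        upper = float(log_obs.min())
        rng = _column_seed(seed, observed, n_missing)
        b = (upper - mu) / sigma
        draws = stats.truncnorm.rvs(-np.inf, b, loc=mu, scale=sigma,
                                    size=n_missing, random_state=rng)
        out.loc[miss, col] = np.exp(draws)
        report.censor_threshold[col] = float(np.exp(upper))
        report.imputed_cell_count += n_missing
    return out, report


def log_z(v) -> np.ndarray:
    """Natural-log transform then z-normalize (mean 0, SD 1, n−1 denominator)."""
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("log_z needs a 1-d vector of length >= 2")
    if np.any(arr <= 0):
        name = getattr(v, "name", None)
        raise ValueError(f"non-positive value in {name or 'vector'}; cannot log-transform")
    lv = np.log(arr)
    sd = lv.std(ddof=1)
    if sd == 0:
        name = getattr(v, "name", None)
        raise ValueError(f"zero variance in {name or 'vector'}")
    out = (lv - lv.mean()) / sd
    if isinstance(v, pd.Series):
        return pd.Series(out, index=v.index, name=v.name)
    return out


def change_from_baseline(week16, week0, z_normalize: bool = False):
    """Element-wise week16 − week0, aligned by sample ID.

    No log transform is applied (deltas can be negative).  With
    ``z_normalize`` the deltas are centred and scaled to unit SD — used for
    within-class FA deltas entering penalized models, not for risk markers.
    """
    w16, w0 = pd.Series(week16), pd.Series(week0)
    if not w16.index.equals(w0.index):
        unmatched = sorted(set(w16.index).symmetric_difference(w0.index))
        raise ValueError(f"sample-ID misalignment between visits: {unmatched}")
    delta = w16 - w0
    if z_normalize:
        sd = delta.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in delta of {w16.name or 'vector'}")
        delta = (delta - delta.mean()) / sd
    return delta
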