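"""Arm-versus-reference linear models for post-intervention within-class FAs.

Each within-class FA's week-16 concentration (log-transformed, z-normalized)
is regressed on dummy-coded diet arm (SFA-rich reference vs MUFA-rich and
MUFA/PUFA-rich), adjusting for age, sex, BMI, the baseline concentration of
the same within-class FA, and the baseline and post-intervention totals of
its lipid class.  Arm coefficients are z-score shifts versus the reference;
familywise error across the panel is controlled by Bonferroni.

Per-model residual diagnostics (Shapiro–Wilk normality, Breusch–Pagan
heteroscedasticity) are reported as numbers, never used as gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .nomenclature import parse_wcfa_label, total_label
from .preprocess import log_z

__all__ = ["DietEffect", "ARMS", "fit_diet_effect", "bonferroni", "diet_effects_table"]

ARMS = ("SFA", "MUFA", "MUFA_PUFA")


@dataclass
class DietEffect:
    """One arm-dummy coefficient on the z scale for one within-class FA."""

    target: str
    arm: str
    z_score: float
    se: float
    p_raw: float
    n: int
    p_adj: float | None = None
    shapiro_p: float | None = None
    breusch_pagan_p: float | None = None


def _design(data: pd.DataFrame, reference_arm: str) -> tuple[pd.DataFrame, list[str]]:
    covar_cols = ["base_fa", "base_total", "post_total", "age", "sex", "bmi"]
    missing = data[covar_cols + ["arm"]].isna().any(axis=1)
    if missing.any():
        raise ValueError(f"missing covariates for samples: {list(data.index[missing])}")
    arms = pd.Categorical(data["arm"])
    levels = [reference_arm] + [a for a in arms.categories if a != reference_arm]
    if len(levels) != 3:
        raise ValueError(f"arm must have exactly 3 levels, got {list(arms.categories)}")
    dummies = pd.get_dummies(
        pd.Categorical(data["arm"], categories=levels), drop_first=True, dtype=float
    )
    arm_cols = list(dummies.columns)
    X = pd.concat([dummies.set_axis(data.index), data[covar_cols].astype(float)], axis=1)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns involved in the deficiency for the error message
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, arm_cols


def fit_diet_effect(data: pd.DataFrame, reference_arm: str = "SFA") -> list[DietEffect]:
    """OLS of a log+z week-16 within-class FA on arm dummies and covariates.

    ``data`` needs columns: ``outcome`` (already log+z), ``base_fa``,
    ``base_total``, ``post_total`` (log scale), ``age``, ``sex``, ``bmi``,
    ``arm`` (3 levels, ``reference_arm`` the reference).  Returns one
    :class:`DietEffect` per non-reference arm, with two-sided t-test
    p-values on residual degrees of freedom.
    """
    X, arm_cols = _design(data, reference_arm)
    y = data["outcome"].astype(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"n = {len(y)} too small for {X.shape[1]} parameters")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid.to_numpy()
    shapiro_p = float(stats.shapiro(resid).pvalue) if len(resid) <= 5000 else np.nan
    bp_p = float(het_breuschpagan(resid, X.to_numpy())[1])
    target = str(data.attrs.get("target", ""))
    out = []
    for col in arm_cols:
        out.append(
            DietEffect(
                target=target,
                arm=str(col),
                z_score=float(fit.params[col]),
                se=float(fit.bse[col]),
                p_raw=float(fit.pvalues[col]),
                n=int(fit.nobs),
                shapiro_p=shapiro_p,
                breusch_pagan_p=bp_p,
            )
        )
    return out


def bonferroni(p_raw, m: int) -> tuple[np.ndarray, float]:
    """Bonferroni adjustment: p_adj = min(1, m·p); threshold 0.05/m.

    ``m`` is the number of tests in the family and may exceed the length of
    ``p_raw`` (e.g. when a panel-wide family is corrected in chunks).
    """
    p = np.asarray(p_raw, dtype=float)
    if m < 1:
        raise ValueError(f"Bonferroni m must be >= 1, got {m}")
    if m < p.size:
        raise ValueError(f"m = {m} smaller than number of p-values ({p.size})")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return np.minimum(1.0, m * p), 0.05 / m


def diet_effects_table(
    fa_week0: pd.DataFrame,
    fa_week16: pd.DataFrame,
    totals_week0: pd.DataFrame,
    totals_week16: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_arm: str = "SFA",
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Fit one diet-effect model per within-class FA column and correct.

    Inputs are the aggregation module's interchange tables (concentrations,
    μmol/L) and a metadata frame with ``age``, ``sex``, ``bmi``, ``arm``.
    Baseline FA and class-total covariates enter on the log scale,
    consistent with the outcome transform.  ``bonferroni_m`` defaults to the
    number of models actually fitted (arm coefficients share their model's
    family size).
    """
    rows: list[DietEffect] = []
    fitted = 0
    for col in fa_week16.columns:
        if col not in fa_week0.columns:
            continue
        cls, _ = parse_wcfa_label(col)
        tot = total_label(cls.code)
        data = pd.DataFrame(
            {
                "outcome": log_z(fa_week16[col]),
                "base_fa": np.log(fa_week0[col]),
                "base_total": np.log(totals_week0[tot]),
                "post_total": np.log(totals_week16[tot]),
                "age": metadata["age"],
                "sex": metadata["sex"],
                "bmi": metadata["bmi"],
                "arm": metadata["arm"],
            }
        )
        data.attrs["target"] = col
        rows.extend(fit_diet_effect(data, reference_arm=reference_arm))
        fitted += 1
    m = bonferroni_m if bonferroni_m is not None else fitted
    # each arm's coefficients form one family of size m (the models fitted)
    for arm in {r.arm for r in rows}:
        arm_rows = [r for r in rows if r.arm == arm]
        p_adj, threshold = bonferroni([r.p_raw for r in arm_rows], max(m, 1))
        for r, pa in zip(arm_rows, p_adj):
            r.p_adj = float(pa)
    threshold = 0.05 / max(m, 1)
    table = pd.DataFrame(
        {
            "target": [r.target for r in rows],
            "arm": [r.arm for r in rows],
            "z_score": [r.z_score for r in rows],
            "se": [r.se for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adj": [r.p_adj for r in rows],
            "significant": [r.p_raw < threshold for r in rows],
            "n": [r.n for r in rows],
            "shapiro_p": [r.shapiro_p for r in rows],
            "breusch_pagan_p": [r.breusch_pagan_p for r in rows],
        }
    )
    table.attrs["bonferroni_m"] = m
    table.attrs["bonferroni_threshold"] = threshold
    return table
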