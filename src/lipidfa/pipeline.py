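"""End-to-end pipeline: config, stage orchestration, audit manifest.

Ties preprocessing, aggregation and the three analysis stages into one
reproducible run: every intermediate table is written as CSV, every source
of randomness comes from the config's master seed, and a manifest records
SHA-256 hashes of inputs and outputs so identical config + inputs give
byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import class_totals, within_class_fa
from .casecohort import cox_association_table
from .diet_effects import diet_effects_table
from .enr import ENRConfig, confirmatory_lm, stability_select, tune
from .preprocess import change_from_baseline, log_z, missingness_filter, qrilc_impute

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: str
    week0_path: str | None = None
    week16_path: str | None = None
    markers_path: str | None = None
    metadata_path: str | None = None
    casecohort_path: str | None = None
    run_diet_effects: bool = True
    run_enr: bool = True
    run_casecohort: bool = True
    missingness_threshold: float = 0.75
    bonferroni_m: int | None = None
    fdr_q: float = 0.05
    retain_min: int = 9
    reference_arm: str = "SFA"
    cox_adjust: tuple[str, ...] = ("sex", "conf")
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.missingness_threshold <= 1.0):
            raise ValueError(
                f"missingness_threshold must be in (0, 1], got {self.missingness_threshold}"
            )
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if self.retain_min < 0 or self.retain_min > 10:
            raise ValueError(f"retain_min must be in [0, 10], got {self.retain_min}")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cox_adjust" in raw:
            raw["cox_adjust"] = tuple(raw["cox_adjust"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cox_adjust"] = list(d["cox_adjust"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format="%.12g")
    manifest["outputs"][path.name] = _sha256(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Stage order: missingness filter → per-visit QRILC imputation →
    within-class FA aggregation + class totals → diet-effect models,
    elastic-net stability selection per marker, and case-cohort Cox models,
    as toggled.  Input files are never modified.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {**asdict(config), "cox_adjust": list(config.cox_adjust)},
        "inputs": {},
        "outputs": {},
        "stages": [],
    }
    for key in ("week0_path", "week16_path", "markers_path", "metadata_path",
                "casecohort_path"):
        p = getattr(config, key)
        if p is not None:
            path = Path(p)
            if not path.exists():
                raise FileNotFoundError(f"{key} does not exist: {p}")
            manifest["inputs"][key] = _sha256(path)

    fa0 = fa16 = tot0 = tot16 = meta = None
    if config.week0_path and config.week16_path:
        week0 = pd.read_csv(config.week0_path, index_col=0)
        week16 = pd.read_csv(config.week16_path, index_col=0)
        # one exclusion pass across both visits jointly, then per-visit imputation
        pooled = pd.concat([week0, week16], axis=0)
        _, report = missingness_filter(pooled, config.missingness_threshold)
        keep = [c for c in week0.columns if c not in report.excluded_species]
        imp0, rep0 = qrilc_impute(week0[keep], seed=config.seed)
        imp16, rep16 = qrilc_impute(week16[keep], seed=config.seed + 1)
        frames = [report.to_frame().assign(visit="both"),
                  rep0.to_frame().assign(visit="week0"),
                  rep16.to_frame().assign(visit="week16")]
        audit = pd.concat([f for f in frames if not f.empty]) if any(
            not f.empty for f in frames
        ) else frames[0]
        _write(audit, out / "imputation_report.csv", manifest, index=False)
        _write(imp0, out / "imputed_week0.csv", manifest)
        _write(imp16, out / "imputed_week16.csv", manifest)
        fa0, tot0 = within_class_fa(imp0), class_totals(imp0)
        fa16, tot16 = within_class_fa(imp16), class_totals(imp16)
        _write(pd.concat([fa0, tot0], axis=1), out / "within_class_fa_week0.csv", manifest)
        _write(pd.concat([fa16, tot16], axis=1), out / "within_class_fa_week16.csv", manifest)
        manifest["stages"] += ["preprocess", "aggregate"]

    if config.metadata_path:
        meta = pd.read_csv(config.metadata_path, index_col=0)

    if config.run_diet_effects and fa0 is not None and meta is not None:
        table = diet_effects_table(
            fa0, fa16, tot0, tot16, meta,
            reference_arm=config.reference_arm, bonferroni_m=config.bonferroni_m,
        )
        _write(table, out / "diet_effects.csv", manifest, index=False)
        manifest["stages"].append("diet_effects")

    if config.run_enr and fa0 is not None and meta is not None and config.markers_path:
        markers = pd.read_csv(config.markers_path, index_col=0)
        X = pd.DataFrame(
            {c: change_from_baseline(fa16[c], fa0[c], z_normalize=True) for c in fa0.columns}
        )
        rows, confirm_rows = [], []
        marker_names = sorted({c.rsplit("_week", 1)[0] for c in markers.columns})
        ss = np.random.SeedSequence([config.seed, 0xE7A])
        for name, child in zip(marker_names, ss.spawn(len(marker_names))):
            y = change_from_baseline(markers[f"{name}_week16"], markers[f"{name}_week0"])
            tune_seed, sel_seed = (int(s.generate_state(1)[0]) & 0x7FFFFFFF
                                   for s in child.spawn(2))
            alpha, lam = tune(X.to_numpy(), y.to_numpy(), ENRConfig(seed=tune_seed))
            model = stability_select(
                X, y.to_numpy(), alpha, lam, seed=sel_seed,
                retain_min=config.retain_min, marker=name,
            )
            for pred, coef, count in model.retained:
                rows.append({"marker": name, "predictor": pred, "coef": coef,
                             "count": count, "pearson_r": model.pearson_r,
                             "alpha": model.alpha, "lambda": model.lam})
            if model.retained:
                covs = meta[["age", "sex", "bmi", "arm"]].copy()
                covs["base_marker"] = markers[f"{name}_week0"]
                confirm = confirmatory_lm(
                    y, X[[p for p, _, _ in model.retained]], covs, marker=name
                )
                confirm_rows += [vars(c) for c in confirm]
        _write(pd.DataFrame(rows), out / "enr_stability.csv", manifest, index=False)
        _write(pd.DataFrame(confirm_rows), out / "enr_confirmatory.csv", manifest, index=False)
        manifest["stages"].append("enr_stability")

    if config.run_casecohort and config.casecohort_path:
        records = pd.read_csv(config.casecohort_path)
        exposures = pd.DataFrame({"exposure": log_z(np.exp(records["exposure"]))})
        table = cox_association_table(
            records, exposures, outcome="T2D", adjust=list(config.cox_adjust),
            bonferroni_m=config.bonferroni_m, fdr_q=config.fdr_q,
        )
        _write(table, out / "casecohort_cox.csv", manifest, index=False)
        manifest["stages"].append("casecohort_cox")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
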