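"""Synthetic lipidomics fixtures: trial and case-cohort generators.

These generators emulate the statistical structure the analysis stages
assume, at desk scale, so that the full pipeline can run and be validated
with no external data:

* a parallel three-arm dietary-fat trial (default arm sizes 38/39/36,
  n = 113): per-class multivariate log-normal species concentrations with
  exchangeable within-class correlation, detection-limit left-censoring,
  arm-specific shifts applied on the within-class-FA log scale and
  back-propagated to contributing species, and risk markers responding
  linearly to z-scored within-class-FA changes;
* a nested case-cohort drawn from a simulated full cohort with exponential
  baseline hazard on the attained-age timescale, configured hazard ratios
  per SD of exposure, administrative censoring, and a random subcohort plus
  all incident cases.

True generating parameters are returned alongside every table so recovery
tests can compare estimates against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import within_class_fa
from .nomenclature import parse_species, parse_wcfa_label, wcfa_label

__all__ = [
    "SpeciesSpec",
    "PanelSpec",
    "ArmEffect",
    "MarkerModel",
    "TrialSpec",
    "CohortSpec",
    "TrialData",
    "gen_trial",
    "gen_casecohort",
    "default_panel",
    "default_trial",
    "default_cohort",
]

ARM_LABELS = ("SFA", "MUFA", "MUFA_PUFA")


@dataclass(frozen=True)
class SpeciesSpec:
    """One species' generating marginal (log scale) and censoring quantile."""

    name: str
    log_mean: float
    log_sd: float = 0.5
    detection_quantile: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_quantile < 1.0):
            raise ValueError("detection quantile must be in [0, 1)")
        parse_species(self.name)  # validates the shorthand


@dataclass
class PanelSpec:
    """The species panel: marginals, within-class correlation."""

    species: list[SpeciesSpec]
    rho: float = 0.4  # exchangeable within-class correlation of log-concentrations

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not self.species:
            raise ValueError("panel needs at least one species")


@dataclass(frozen=True)
class ArmEffect:
    """A diet-arm shift of one within-class FA, in z (log-SD) units."""

    target: str  # CLASS[C:D]
    arm: str
    z_shift: float


@dataclass(frozen=True)
class MarkerModel:
    """A risk marker responding linearly to z-scored within-class FA changes."""

    name: str
    predictors: tuple[tuple[str, float], ...]  # (CLASS[C:D], beta in marker units / SD)
    noise_sd: float
    baseline_mean: float
    baseline_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("marker noise SD must be > 0")


@dataclass
class TrialSpec:
    """Design of the synthetic three-arm dietary intervention."""

    n_per_arm: tuple[int, int, int] = (38, 39, 36)
    arm_effects: list[ArmEffect] = field(default_factory=list)
    markers: list[MarkerModel] = field(default_factory=list)
    week_noise_sd: float = 1.7  # week-to-week noise, in units of species log-SD;
    # calibrated so arm-coefficient SEs at n = 113 sit near the reported 0.17
    age_mean: float = 43.8
    age_sd: float = 10.2
    bmi_mean: float = 26.8
    bmi_sd: float = 4.3
    p_female: float = 0.602

    def __post_init__(self) -> None:
        for eff in self.arm_effects:
            if eff.arm not in ARM_LABELS[1:]:
                raise ValueError(f"arm effects must target {ARM_LABELS[1:]}, got {eff.arm!r}")


@dataclass
class CohortSpec:
    """Scaled-down nested case-cohort design."""

    cohort_size: int = 5000
    subcohort_size: int = 300
    log_hr_exposure: float = math.log(2.84)
    covariate_log_hrs: dict[str, float] = field(
        default_factory=lambda: {"class_total": 0.10, "sex": 0.20, "conf": 0.10}
    )
    baseline_hazard: float = 0.0021  # events / person-year
    follow_up_years: float = 10.0
    entry_age_range: tuple[float, float] = (35.0, 65.0)

    def __post_init__(self) -> None:
        if self.subcohort_size > self.cohort_size:
            raise ValueError("subcohort cannot exceed the cohort")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")


@dataclass
class TrialData:
    """A generated trial bundle plus the generating truth."""

    week0: pd.DataFrame  # samples x species, NaN where censored
    week16: pd.DataFrame
    markers: pd.DataFrame  # <name>_week0 / <name>_week16 columns
    metadata: pd.DataFrame  # age, sex, bmi, arm
    truth: dict


def default_panel(seed: int = 0) -> PanelSpec:
    """A ~60-species miniature spanning all 16 classes and ~12 fatty acids.

    Log-means are drawn once (seeded) from a realistic plasma range; every
    class appears, multi-chain classes carry mixed-FA species so the
    multiplicity weighting is exercised, and a few species have detection
    quantiles high enough to produce left-censoring (one at 0.8 to trip the
    75% exclusion rule in most draws).
    """
    fa = ["12:0", "14:0", "15:0", "16:0", "17:0", "18:0", "20:0",
          "16:1", "18:1", "22:1", "24:1", "18:2"]
    rng = np.random.default_rng(seed)
    species: list[SpeciesSpec] = []

    def add(name: str, q: float = 0.0) -> None:
        species.append(
            SpeciesSpec(name=name, log_mean=float(rng.uniform(-1.5, 2.0)),
                        log_sd=0.5, detection_quantile=q)
        )

    one_chain = {
        "CE": ["16:0", "18:0", "18:1", "18:2", "12:0"],
        "MAG": ["16:0", "18:1", "12:0"],
        "SM": ["16:0", "18:0", "24:1", "14:0"],
        "CER": ["16:0", "18:0", "24:1"],
        "DCER": ["16:0", "18:0"],
        "HCER": ["14:0", "16:0", "18:1"],
        "LCER": ["16:0", "24:1"],
        "LPC": ["15:0", "16:0", "17:0", "18:0"],
        "LPE": ["18:0", "18:1"],
    }
    for code, fas in one_chain.items():
        for f in fas:
            add(f"{code}({f})")
    two_chain = {
        "DAG": [("16:0", "16:0"), ("16:0", "14:0"), ("18:0", "18:1"),
                ("20:0", "20:0"), ("16:0", "18:2")],
        "PC": [("16:0", "18:1"), ("16:0", "18:2"), ("18:0", "18:1")],
        "PE": [("16:0", "18:1"), ("18:0", "18:2")],
        # no FA may appear with the same multiplicity in every species of a
        # class, else that within-class FA duplicates the class total and the
        # diet-effect adjustment set is rank deficient
        "PEO": [("16:0", "18:1"), ("18:0", "18:2")],
        "PEP": [("16:0", "18:1"), ("18:0", "20:0")],
        "PI": [("16:0", "18:1"), ("18:0", "18:2")],
    }
    for code, pairs in two_chain.items():
        for a, b in pairs:
            add(f"{code}({a}/{b})")
    for chains in [("16:0", "18:1", "18:2"), ("16:0", "16:0", "18:1"),
                   ("22:1", "18:1", "16:0"), ("12:0", "14:0", "16:0"),
                   ("18:0", "18:0", "18:1")]:
        add("TG({}/{}/{})".format(*chains))
    # censoring: two moderately censored species, one past the exclusion rule
    species[0] = SpeciesSpec(species[0].name, species[0].log_mean, 0.5, 0.20)
    species[7] = SpeciesSpec(species[7].name, species[7].log_mean, 0.5, 0.30)
    species[12] = SpeciesSpec(species[12].name, species[12].log_mean, 0.5, 0.80)
    assert all(f in fa for f in one_chain["CE"])  # panel stays inside the FA alphabet
    return PanelSpec(species=species, rho=0.4)


def default_trial() -> TrialSpec:
    """Arm effects and marker models matching the magnitudes the trial reported."""
    effects = [
        ArmEffect("DAG[20:0]", "MUFA", -1.08),
        ArmEffect("HCER[14:0]", "MUFA", -1.08),
        ArmEffect("SM[24:1]", "MUFA", 0.55),
        ArmEffect("TG[22:1]", "MUFA", 0.53),
        ArmEffect("DAG[18:2]", "MUFA_PUFA", 0.29),
        ArmEffect("TG[18:2]", "MUFA_PUFA", 0.30),
    ]
    markers = [
        MarkerModel("LDL_C", (("TG[12:0]", 0.15), ("CE[18:0]", 0.20)), 0.40, 3.79, 1.02),
        MarkerModel("total_cholesterol", (("CE[18:0]", 0.26),), 0.50, 5.52, 1.12),
        MarkerModel("NEFA", (("PE[16:0]", 19.8),), 80.0, 471.0, 171.0),
        MarkerModel("stiffness_index", (("LPC[15:0]", 0.34),), 0.9, 6.72, 1.81),
        MarkerModel("P_selectin", (("CE[12:0]", 2.41),), 7.0, 41.7, 12.9),
        MarkerModel("TNF_alpha", (("MAG[16:0]", 0.04),), 0.35, 1.17, 0.74),
    ]
    return TrialSpec(arm_effects=effects, markers=markers)


def default_cohort() -> CohortSpec:
    return CohortSpec()


def _species_shifts(panel: PanelSpec, trial: TrialSpec) -> dict[str, dict[str, float]]:
    """Per-arm log-scale shift for each species, back-propagated from FA targets.

    An arm effect is stated on the scale the analysis reports: SD units of
    the pooled, z-normalized post-intervention log concentration.  That
    pooled SD includes the week-to-week noise and the between-arm variance
    the shift itself induces, so the log-scale shift Δ is backed out
    self-consistently: for target z-shifts ``z_a`` across arms with
    fractions ``p_a``, the pooled variance is σ²(1+τ²)/(1−v) with
    v = Σp_a z_a² − (Σp_a z_a)², and Δ_a = z_a·σ·sqrt((1+τ²)/(1−v)).

    Each contributing species receives the shift in proportion to the
    fraction of its chains made of the target FA, so a pure-FA species
    carries the full shift; for FAs reached only through mixed species the
    induced shift is approximate.  This back-propagation is a fixture
    convention; the underlying study design has no generative model for it.
    """
    n_total = sum(trial.n_per_arm)
    p_arm = {arm: cnt / n_total for arm, cnt in zip(ARM_LABELS, trial.n_per_arm)}
    tau2 = trial.week_noise_sd**2
    by_target: dict[str, dict[str, float]] = {}
    for eff in trial.arm_effects:
        by_target.setdefault(eff.target, {})[eff.arm] = (
            by_target.get(eff.target, {}).get(eff.arm, 0.0) + eff.z_shift
        )
    shifts: dict[str, dict[str, float]] = {arm: {} for arm in ARM_LABELS[1:]}
    for target, z_by_arm in by_target.items():
        cls, fa = parse_wcfa_label(target)
        mean_z = sum(p_arm[a] * z for a, z in z_by_arm.items())
        mean_z2 = sum(p_arm[a] * z**2 for a, z in z_by_arm.items())
        v = mean_z2 - mean_z**2
        if v >= 1.0:
            raise ValueError(f"arm z-shifts on {target} too large to realize (v = {v:.2f})")
        scale = math.sqrt((1.0 + tau2) / (1.0 - v))
        hit = False
        for sp in panel.species:
            parsed = parse_species(sp.name)
            if parsed.lipid_class.code != cls.code:
                continue
            mult = sum(1 for c in parsed.chains if c == fa)
            if mult == 0:
                continue
            frac = mult / parsed.lipid_class.chains_per_molecule
            for arm, z in z_by_arm.items():
                delta = z * sp.log_sd * scale * frac
                shifts[arm][sp.name] = shifts[arm].get(sp.name, 0.0) + delta
            hit = True
        if not hit:
            raise ValueError(f"arm effect target {target} has no species in the panel")
    return shifts


def gen_trial(
    trial: TrialSpec | None = None,
    panel: PanelSpec | None = None,
    seed: int = 0,
) -> TrialData:
    """Generate one synthetic trial (two visits, markers, metadata, truth).

    Baseline log-concentrations are multivariate normal with exchangeable
    within-class correlation ρ; week-16 adds the arm shifts plus independent
    week-to-week noise.  Censoring replaces values below each species'
    detection-quantile threshold (empirical, pooled over visits) with NaN.
    Markers respond to z-scored changes of the *uncensored* within-class
    FAs, so marker truth is unaffected by the censoring mechanism.
    """
    trial = trial or default_trial()
    panel = panel or default_panel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    n = sum(trial.n_per_arm)
    arms = np.repeat(ARM_LABELS, trial.n_per_arm)
    samples = [f"S{i:03d}" for i in range(1, n + 1)]

    age = rng.normal(trial.age_mean, trial.age_sd, n).clip(21, 60)
    sex = (rng.random(n) < trial.p_female).astype(int)  # 1 = female
    bmi = rng.normal(trial.bmi_mean, trial.bmi_sd, n).clip(17, 45)
    metadata = pd.DataFrame({"age": age, "sex": sex, "bmi": bmi, "arm": arms}, index=samples)

    by_class: dict[str, list[SpeciesSpec]] = {}
    for sp in panel.species:
        by_class.setdefault(parse_species(sp.name).lipid_class.code, []).append(sp)

    log0 = {}
    log16 = {}
    shifts = _species_shifts(panel, trial)
    sqr, sqi = math.sqrt(panel.rho), math.sqrt(1.0 - panel.rho)
    for code, specs in by_class.items():
        z_class = rng.standard_normal(n)
        for sp in specs:
            z = sqr * z_class + sqi * rng.standard_normal(n)
            base = sp.log_mean + sp.log_sd * z
            shift = np.zeros(n)
            for arm in ARM_LABELS[1:]:
                if sp.name in shifts[arm]:
                    shift[arms == arm] = shifts[arm][sp.name]
            log0[sp.name] = base
            log16[sp.name] = base + shift + trial.week_noise_sd * sp.log_sd * rng.standard_normal(n)

    week0 = pd.DataFrame({k: np.exp(v) for k, v in log0.items()}, index=samples)
    week16 = pd.DataFrame({k: np.exp(v) for k, v in log16.items()}, index=samples)

    # markers respond to true (pre-censoring) within-class FA changes
    fa0 = within_class_fa(week0)
    fa16 = within_class_fa(week16)
    markers = {}
    for mm in trial.markers:
        base = rng.normal(mm.baseline_mean, mm.baseline_sd, n)
        delta = np.zeros(n)
        for target, beta in mm.predictors:
            if target not in fa0.columns:
                raise ValueError(f"marker {mm.name} references absent FA {target}")
            d = (fa16[target] - fa0[target]).to_numpy()
            sd = d.std(ddof=1)
            delta += beta * (d - d.mean()) / sd
        delta += 0.01 * (age - age.mean()) + 0.1 * (sex - sex.mean()) * mm.baseline_sd / 4
        markers[f"{mm.name}_week0"] = base
        markers[f"{mm.name}_week16"] = base + delta + rng.normal(0, mm.noise_sd, n)
    markers_df = pd.DataFrame(markers, index=samples)

    censor_thresholds = {}
    for sp in panel.species:
        if sp.detection_quantile <= 0.0:
            continue
        pooled = np.concatenate([week0[sp.name], week16[sp.name]])
        thr = float(np.quantile(pooled, sp.detection_quantile))
        censor_thresholds[sp.name] = thr
        week0.loc[week0[sp.name] < thr, sp.name] = np.nan
        week16.loc[week16[sp.name] < thr, sp.name] = np.nan

    truth = {
        "arm_effects": [vars(e) for e in trial.arm_effects],
        "marker_models": [
            {"name": m.name, "predictors": list(m.predictors), "noise_sd": m.noise_sd}
            for m in trial.markers
        ],
        "species_shifts": shifts,
        "censor_thresholds": censor_thresholds,
        "seed": seed,
    }
    return TrialData(week0=week0, week16=week16, markers=markers_df,
                     metadata=metadata, truth=truth)


def gen_casecohort(spec: CohortSpec | None = None, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort, then emit the nested case-cohort sample.

    Event ages follow a Cox model with exponential baseline hazard on the
    attained-age timescale (entry at a uniform age, memoryless residual
    time), administratively censored at entry + follow-up.  The output
    contains the random subcohort plus every incident case, with the
    subcohort/case flags the Prentice risk sets rely on.
    """
    spec = spec or default_cohort()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0C0]))
    n = spec.cohort_size
    exposure = rng.standard_normal(n)  # already z-scored
    class_total = 0.3 * exposure + rng.normal(0, 0.5, n)
    sex = rng.integers(0, 2, n).astype(float)
    conf = rng.standard_normal(n)
    lin = spec.log_hr_exposure * exposure
    for name, lhr in spec.covariate_log_hrs.items():
        lin += lhr * {"class_total": class_total, "sex": sex, "conf": conf}[name]
    entry = rng.uniform(*spec.entry_age_range, n)
    rate = spec.baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / rate)
    censor_age = entry + spec.follow_up_years
    event_age = entry + t_event
    event = event_age <= censor_age
    exit_age = np.minimum(event_age, censor_age)
    if not event.any():
        raise ValueError("zero cases generated; increase the baseline hazard")

    sub_idx = rng.choice(n, size=spec.subcohort_size, replace=False)
    in_sub = np.zeros(n, dtype=bool)
    in_sub[sub_idx] = True
    keep = in_sub | event
    table = pd.DataFrame(
        {
            "id": np.arange(n)[keep],
            "in_subcohort": in_sub[keep],
            "is_case": event[keep],
            "entry_age": entry[keep],
            "exit_age": exit_age[keep],
            "event": event[keep].astype(int),
            "exposure": exposure[keep],
            "class_total": class_total[keep],
            "sex": sex[keep],
            "conf": conf[keep],
        }
    ).reset_index(drop=True)
    truth = {
        "log_hr_exposure": spec.log_hr_exposure,
        "covariate_log_hrs": dict(spec.covariate_log_hrs),
        "baseline_hazard": spec.baseline_hazard,
        "n_cohort": n,
        "n_subcohort": spec.subcohort_size,
        "n_cases": int(event.sum()),
        "seed": seed,
    }
    return table, truth
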