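# Methods

This note documents the statistical procedures `lipidfa` implements, the
choices made where the design was open, and what the synthetic-data
generators do and do not emulate.

## Nomenclature and aggregation

Species names follow the shorthand `CLASS(C:D/...)`. Sixteen classes are
supported; the taxonomy (category, chains per molecule) ships as a packaged
TSV so it can be audited or extended without touching code. Chain identity
is the pair (carbons, double bonds): the measurement platform provides no
double-bond position or cis/trans information, so two chains are equal iff
C and D match. `SPE` is accepted as an alias of LPE (both denote the
1-chain ethanolamine lysophospholipid in vendor exports); ether and
plasmalogen chains (PEO, PEP) count as ordinary chains.

Within-class FA concentrations are multiplicity-weighted sums over the
class's species; class totals are unweighted sums. Two consequences are
enforced by property tests: the conservation law
Σ_f FA(c,f) = arity(c) × total(c) per sample (exact to floating-point),
and equivalence with a brute-force oracle that expands every molecule into
its chain multiset. (class, FA) pairs with no contributing species are
absent, not zero. Aggregation requires an imputed (complete) matrix;
imputation precedes aggregation.

## Missingness and QRILC imputation

Missingness here is left-censoring at the detection limit. Species missing
in ≥ 75% of samples (inclusive) are excluded; the threshold is assessed per
species across all samples and visits jointly, in one pass before any
analysis. Imputation then runs per visit stratum (week 0 and week 16
separately) so intervention effects cannot leak into baseline imputations.

QRILC per species, on the natural-log scale: with k of n cells censored,
the sorted observed values occupy ranks k+1…n; Blom plotting positions
(r − 0.375)/(n + 0.25) at those ranks give standard-normal quantiles, and
least squares of the order statistics on those quantiles estimates
(μ, σ) of the uncensored distribution. Missing cells are drawn from
N(μ, (tune_sigma·σ)²) truncated above at the species' minimum observed
log-concentration and exponentiated; observed cells are never altered.
`tune_sigma` defaults to 1.0. Species with fewer than 3 observed values
cannot support the regression and are filled with half the global minimum
observed concentration, flagged in the audit report.

Determinism: each species' RNG substream is derived from the master seed
plus a hash of its sorted observed values and missing count, so identical
columns impute identically and reruns reproduce exactly. Recovery checks:
at n = 1000 and 20% censoring the generating (μ, σ) of a log-normal
species are recovered within 5% (measured ≈ 1% each), and every imputed
value sits below the detection limit by construction.

## Diet-effect models

For each within-class FA, the week-16 concentration is log-transformed and
z-normalized (mean 0, SD 1, n−1 denominator) and regressed by OLS on
dummy-coded diet arm (SFA-rich reference; MUFA-rich and MUFA/PUFA-rich
dummies), age, sex, BMI, the baseline log concentration of the same FA,
and the baseline and post-intervention log class totals. Baseline
covariates enter on the log scale, consistent with the outcome transform.
Arm coefficients are SD shifts versus the reference, with two-sided
t-tests on residual degrees of freedom; no robust standard errors.

Bonferroni control: p_adj = min(1, m·p), threshold 0.05/m. m defaults to
the number of models fitted and is configurable; because each model
contributes one test per non-reference arm, each arm's coefficients form
one family of size m. Model diagnostics (Shapiro–Wilk on residuals,
Breusch–Pagan) are logged per model as numbers, never used as gates. A
genuinely rank-deficient design (e.g. a within-class FA that identically
equals its class total because one FA appears with the same multiplicity
in every species of the class) raises an error naming the collinear
columns; a merely *constant* adjustor folds into the intercept and leaves
arm coefficients unchanged.

## Elastic-net stability selection

Solver: cyclic coordinate descent with soft-thresholding on
(1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²), intercept unpenalized,
convergence when the largest coefficient change in a sweep is below 1e-7.
Oracle reductions are tested: λ = 0 → OLS, α = 1 univariate →
soft-threshold closed form, α = 0 → ridge closed form, plus KKT
subgradient checks and agreement with scikit-learn's ElasticNet at 1e-6.

Inputs: within-class FA changes (week 16 − week 0), z-normalized; marker
changes left in natural units (deltas can be negative, so no log).

Tuning: the α grid is {0.1, …, 1.0}; each α gets 50 log-spaced λ values
from λ_max (smallest λ zeroing all coefficients) down four decades. Mean
test MSE is computed over 10 seeded random 80/20 train/test splits — the
"10-fold, 80/20" description is internally inconsistent (10 disjoint folds
imply 90/10), and the explicit percentage is honored. Selection uses a
one-standard-error rule: among configurations whose mean MSE is within one
SE (of the per-split MSEs at the minimizing configuration) of the minimum,
the one with the fewest nonzero coefficients in a full-data fit wins,
remaining ties broken toward larger λ then larger α. Model complexity is
deliberately measured as the number of predictors selected, not as raw λ:
λ scales as 1/α across mixing values, so comparing λ across α values would
systematically favor ridge-like models that retain every predictor with
tiny coefficients. The strict MSE minimizer is available via
`one_se=False`; with ~500 configurations and only 10 noisy splits it
suffers a winner's curse that inflates false selections under the null.

Stability selection: with (α, λ) fixed, 10 fresh seeded 80/20 splits;
"selected" means a nonzero training coefficient; predictors selected in
≥ 9 of 10 iterations are retained, and their reported coefficient is the
mean over the iterations where they were nonzero (zero-padding would mix
selection with estimation). Test-set predictions from all iterations are
collated and their Pearson correlation with the measured outcome is the
model's performance proxy; an empty retained set is a valid model with the
correlation flagged. Tuning and selection use fresh splits derived from
one master seed.

Confirmatory models: all retained predictors enter one OLS jointly with
age, sex, BMI, baseline marker value and diet arm; β is the marker change
per SD of FA change with a t-based 95% CI.

## Prentice-weighted case-cohort Cox

Records carry subcohort and case flags, entry/exit ages and an event
indicator; exit is the earliest of diagnosis, death, loss to follow-up or
the censoring date. Validation enforces entry < exit, case ⇔ event, and
that every non-subcohort record is a case.

Time is attained age with left truncation at entry. The Prentice risk set
at failure age t contains subcohort members with entry < t ≤ exit plus any
case failing exactly at t; non-subcohort cases appear in no other risk
set. The pseudo-partial-likelihood with Breslow tie handling is maximized
by Newton–Raphson with step halving (convergence: max |score| < 1e-9 or
relative log-likelihood change < 1e-12; both tighter than needed for the
1e-6 oracle agreement with an independent Cox implementation on
full-cohort data). |β| exceeding 10 raises a separation error suggesting
penalization. Variance is a robust sandwich grouped by individual
(Barlow-type score residuals); the model-based inverse information is
anti-conservative under case-cohort weighting and is kept only as a
diagnostic. Exposures are log-transformed and z-normalized, so log HRs are
per SD; each model also adjusts for the exposure's log class total.

Proportional hazards are screened by Grambsch–Therneau scaled Schoenfeld
residuals correlated against event age, reported per covariate with a
p-value — a diagnostic, never a gate; it is skipped below 2 events.

Multiple testing: Benjamini–Hochberg adjusted values (via statsmodels) and
Bonferroni (0.05/m) are computed side by side, since both conventions are
common for this design and they answer different error-rate questions.

## Synthetic data

The generators define the study conditions the tests run under.

**Trial** (default): 113 participants in arms of 38/39/36; age ~
N(43.8, 10.2²) clipped to 21–60, BMI ~ N(26.8, 4.3²), 60.2% female. The
default panel has 49 species spanning all 16 classes and 12 fatty acids;
baseline log concentrations are multivariate normal with exchangeable
within-class correlation ρ = 0.4 and per-species log-SD 0.5. Week 16 adds
the arm shifts plus week-to-week noise with SD 1.7 × the species log-SD —
calibrated once, analytically, so that arm-coefficient SEs at this design
sit near 0.17, the precision scale of the effects the generator plants.
Arm z-shifts are stated on the scale the analysis reports (SD units of
the pooled post-intervention z), and the generator backs out the log-scale
shift self-consistently — the pooled SD includes both the week noise and
the between-arm variance the shift itself induces: for target shifts z_a
with arm fractions p_a, Δ_a = z_a·σ·√((1+τ²)/(1−v)) with
v = Σp_a z_a² − (Σp_a z_a)². Shifts back-propagate to species in
proportion to the fraction of chains made of the target FA; this is a
fixture convention (the real design has no generative model), so a target
reached only through mixed-FA species receives an approximate shift, and
recovery tests use a target with a pure contributing species (DAG[20:0]).
Left-censoring replaces values below each species' detection-quantile
threshold (empirical, pooled over visits) with missing; one default
species is censored at the 0.8 quantile to exercise the ≥ 75% exclusion.
Six risk markers respond linearly (in marker units per SD of FA change) to
z-scored changes of the *uncensored* within-class FAs plus small covariate
terms and Gaussian noise, with baselines matching typical clinical scales.

**Case-cohort** (default scaled design): cohort 5000, random subcohort
300, entry age uniform on 35–65, exponential baseline hazard 0.0021/yr on
the attained-age timescale, administrative censoring at entry + 10 years —
about 180 cases in expectation under a hazard ratio of 2.84 per SD of the
exposure. Event ages use the memoryless construction (entry + exponential
residual time), which is exact for a constant baseline hazard. The
confounder set is reduced (a correlated class total, sex, one continuous
confounder): emulating the full 17-covariate adjustment adds nothing the
estimator exercises. Designs for other hazard ratios rescale the baseline
hazard to keep the expected case count comparable.

What the generators do **not** emulate: mass-spectrometry noise physics,
batch or drift structure, realistic inter-class correlation, skewed or
heavy-tailed marker distributions, informative censoring, competing risks,
and covariate-dependent missingness. Passing tests therefore demonstrate
correctness of the estimators under the stated generating models — not
robustness to those real-data complications.

## Numerical conventions and limitations

Sample SDs use the n−1 denominator throughout. All randomness flows from
explicit seeds; per-stream seeds are derived via `numpy` SeedSequence and
recorded in outputs. Pipeline outputs are written with a fixed float
format so identical config + inputs give byte-identical tables.

Simulation sizes in tests and the acceptance script (e.g. 200 case-cohort
replicates for coverage, 500 global-null simulations, 40 pure-noise
stability-selection replicates, 100 random panels for the conservation
law) were chosen to keep Monte-Carlo error comfortably below the margins
being asserted while completing in minutes on one CPU.

Known limitations: the elastic-net path uses plain cyclic (not randomized
or strong-rule-screened) coordinate descent, adequate at panel scale
(hundreds of predictors) but not for very wide designs; the Cox fit
assumes one record per individual (no time-varying covariates); and
weightings other than Prentice (Barlow, Self–Prentice, Lin–Ying) are not
implemented.
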