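# lipidfa

Within-class fatty-acid lipidomics analysis: from molecular-species
concentration tables to diet-intervention effects, risk-marker prediction,
and case-cohort disease associations.

## The problem

Lipidomics platforms report hundreds of molecular species — e.g.
`DAG(16:0/18:1)`, a diacylglycerol carrying one palmitic and one oleic
chain — in absolute concentrations (μmol/L). Species-level analyses are
hard to interpret and heavily multiple-tested, so a common analytic unit is
the **within-class fatty acid**: for a lipid class *c* and fatty acid *f*,

&nbsp;&nbsp;&nbsp;&nbsp;FA<sub>c,f</sub> = Σ<sub>s ∈ c</sub> m<sub>s,f</sub> · x<sub>s</sub>,

where x<sub>s</sub> is the species concentration and m<sub>s,f</sub> counts
how many chains of *f* the molecule of species *s* carries (a DAG with two
16:0 chains contributes twice to DAG[16:0]). Class totals are plain sums,
giving the conservation law Σ<sub>f</sub> FA<sub>c,f</sub> = (chains per
molecule of *c*) × total<sub>c</sub>.

`lipidfa` implements the full chain a dietary-fat intervention / cohort
analysis needs around this unit:

1. **Nomenclature** — parsing of `CLASS(C:D/...)` shorthand across 16 lipid
   classes (1–3 acyl chains per molecule), with an auditable packaged
   taxonomy.
2. **Preprocessing** — exclusion of species with ≥ 75% missing values, and
   QRILC imputation of left-censored (below-detection-limit) cells: per
   species, (μ, σ) of the uncensored log distribution are estimated by
   regressing observed order statistics on censoring-shifted normal
   quantiles, then missing cells are drawn from N(μ, σ²) truncated above at
   the observed minimum.
3. **Diet effects** — per within-class FA, OLS of the log-transformed,
   z-normalized week-16 concentration on dummy-coded diet arm (SFA-rich
   reference vs MUFA-rich and MUFA/PUFA-rich), adjusted for age, sex, BMI,
   baseline FA, and baseline + post class totals; Bonferroni familywise
   control.
4. **Elastic-net stability selection** — changes in within-class FAs
   predicting changes in cardiometabolic risk markers: a coordinate-descent
   elastic net (objective (1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖²)),
   (α, λ) tuned by cross-validated MSE with a one-SE sparsity rule,
   predictors retained when selected in ≥ 9 of 10 seeded 80/20 splits,
   coefficients averaged across selecting iterations, collated out-of-fold
   Pearson r as performance, and confirmatory fully adjusted regressions.
5. **Case-cohort Cox** — Prentice-weighted proportional-hazards models on
   the attained-age timescale for nested case-cohort designs (subcohort
   members at risk over their window; outside cases only at their own
   failure time), Breslow ties, Newton–Raphson, robust sandwich variance;
   Benjamini–Hochberg FDR and Bonferroni side by side.
6. **Synthetic data** — generators for a three-arm fat-exchange trial
   (n = 113; arms 38/39/36) and a scaled nested case-cohort (cohort 5000,
   subcohort 300), with known truths recorded for every run, so the whole
   pipeline is testable without any external download.

## Worked example

```python
import pandas as pd
from lipidfa import within_class_fa, class_totals

conc = pd.DataFrame({"DAG(16:0/16:0)": [1.0], "DAG(16:0/14:0)": [2.0]},
                    index=["sample_1"])
print(within_class_fa(conc))   #           DAG[14:0]  DAG[16:0]
                               # sample_1        2.0        4.0
print(class_totals(conc))      #           DAG[total]
                               # sample_1         3.0
```

DAG[16:0] = 1.0·2 + 2.0·1 = 4.0 — the di-palmitic species counts twice;
2.0 + 4.0 = 2 × 3.0 checks the conservation law.

Running the diet-effect stage end to end on a generated trial
(`python examples/03_diet_effects.py`) prints:

```
    target       arm   z_score       se        p_raw  significant
 DAG[20:0]      MUFA -1.184761 0.174132 6.674107e-10         True
HCER[14:0]      MUFA -0.793074 0.140853 1.537193e-07         True
```

The configured −1.08 SD reduction of DAG[20:0] in the MUFA-rich arm is
recovered as the strongest signal (z-score = SD shift versus the SFA-rich
arm, SE ≈ 0.17). The other examples cover imputation, stability selection,
the Prentice-Cox fit (recovering a generated HR of 2.84 per SD), and the
pipeline driver with its reproducibility manifest; each prints the numbers
it computes and one line on what they mean.

A thin CLI wraps the same library calls:

```bash
lipidfa fixtures --out-dir data --seed 7
lipidfa run-all --config config.yaml
```

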