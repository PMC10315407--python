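"""Left-censored imputation of below-detection-limit lipid concentrations.

Species missing in >= 75% of samples are dropped; the rest are imputed by
QRILC: a normal distribution is fitted to the observed log concentrations
by regressing order statistics on censoring-shifted normal quantiles, and
missing cells are drawn from that normal truncated above at the observed
minimum — imputed values always sit below the detection limit.
"""

import numpy as np
import pandas as pd

from lipidfa import missingness_filter, qrilc_impute

rng = np.random.default_rng(0)
n = 200
truth_mu, truth_sigma = 1.0, 0.5
values = pd.DataFrame(
    {
        "CE(16:0)": np.exp(rng.normal(truth_mu, truth_sigma, n)),
        "SM(24:1)": np.exp(rng.normal(0.0, 0.4, n)),
        "LPC(15:0)": np.exp(rng.normal(-1.0, 0.3, n)),
    }
)
# censor CE(16:0) below its 25% quantile, LPC(15:0) below 80% (-> excluded)
for col, q in [("CE(16:0)", 0.25), ("LPC(15:0)", 0.80)]:
    limit = values[col].quantile(q)
    values.loc[values[col] < limit, col] = np.nan

kept, report = missingness_filter(values, threshold=0.75)
print("excluded species (>= 75% missing):", report.excluded_species)

imputed, imp_report = qrilc_impute(kept, seed=42)
print(f"imputed {imp_report.imputed_cell_count} cells")
miss = values["CE(16:0)"].isna()
print("max imputed CE(16:0):", round(imputed.loc[miss, 'CE(16:0)'].max(), 3),
      "| min observed:", round(kept['CE(16:0)'].min(), 3))
print("pooled log-mean after imputation:",
      round(float(np.log(imputed['CE(16:0)']).mean()), 3),
      f"(generating mean {truth_mu})")
print("Imputation restores the censored left tail without touching observed cells.")
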