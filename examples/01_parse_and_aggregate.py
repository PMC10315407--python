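"""Parse lipid shorthand names and aggregate to within-class fatty acids.

A DAG carrying two palmitic (16:0) chains contributes twice its
concentration to the DAG[16:0] within-class FA; a mixed DAG(16:0/14:0)
contributes once each to DAG[16:0] and DAG[14:0].  Class totals are the
plain sum of species, so summing all within-class FAs of a class recovers
(chains per molecule) x (class total).
"""

import pandas as pd

from lipidfa import FattyAcid, class_totals, fa_multiplicity, parse_species, within_class_fa

species = parse_species("DAG(16:0/16:0)")
print(f"{species} -> class {species.lipid_class.code}, "
      f"{species.lipid_class.chains_per_molecule} chains per molecule")
print("multiplicity of 16:0 in DAG(16:0/16:0):",
      fa_multiplicity(species, FattyAcid(16, 0)))

conc = pd.DataFrame(
    {"DAG(16:0/16:0)": [1.0], "DAG(16:0/14:0)": [2.0], "CE(18:0)": [0.5]},
    index=["sample_1"],
)
print("\nconcentrations (umol/L):")
print(conc.to_string())

fa = within_class_fa(conc)
tot = class_totals(conc)
print("\nwithin-class FAs (umol/L):")
print(fa.to_string())
print("\nclass totals (umol/L):")
print(tot.to_string())
print("\nDAG[16:0] = 1.0*2 + 2.0*1 = 4.0: the double palmitic DAG counts twice.")
print("DAG[16:0] + DAG[14:0] =", float(fa[["DAG[16:0]", "DAG[14:0]"]].sum(axis=1).iloc[0]),
      "= 2 x DAG[total] =", 2 * float(tot["DAG[total]"].iloc[0]))
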