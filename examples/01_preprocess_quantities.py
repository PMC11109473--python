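"""Derive the three quantity types from corrected isotopologue intensities.

A metabolite with n carbons has isotopologues m+0..m+n. From the absolute
corrected intensities we derive: the total pool size m = ΣMj, the mass
distribution vector (MDV) ci = Mi/ΣMj, and the fractional contribution
(mean ¹³C enrichment) φ = Σ(cj·j)/n.
"""

import pandas as pd

from isodiff import fractional_contribution, isotopologue_proportions, total_abundance
from isodiff.tables import IsotopologueTable

data = pd.DataFrame(
    {"sample1": [10.0, 30.0, 60.0], "sample2": [80.0, 15.0, 5.0]},
    index=pd.MultiIndex.from_tuples(
        [("Alanine", 0), ("Alanine", 1), ("Alanine", 2)],
        names=["metabolite", "isotopologue_index"],
    ),
)
table = IsotopologueTable(data=data, mode="absolute")

abundance = total_abundance(table)
mdv = isotopologue_proportions(table)
phi = fractional_contribution(mdv)

print("total abundance (ΣMj):")
print(abundance.data, "\n")
print("isotopologue proportions (MDV):")
print(mdv.data, "\n")
print("fractional contribution φ:")
print(phi.data)
# sample1 has most mass in m+2 → φ = 0.75: three quarters of alanine's
# carbons carry the tracer; sample2 is mostly unlabeled (φ = 0.125).
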