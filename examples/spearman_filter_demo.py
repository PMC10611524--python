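"""The correlation screen on a tiny hand-built table, removals audited.

Five samples, one designated indicator contaminant, and three taxa: one
tracking the indicator perfectly (rho = 1), one sitting exactly on the 0.3
threshold (retained -- the cutoff is strictly 'exceeding'), and one
anti-correlated resident.  Prints the per-taxon disposition and evidence.
"""

import pandas as pd

from decontab import DecontamParams, IndicatorSet, TaxaCountTable, correlation_filter

counts = pd.DataFrame(
    {
        "s1": [10, 20, 1, 50],
        "s2": [20, 40, 5, 40],
        "s3": [30, 60, 2, 30],
        "s4": [40, 80, 4, 20],
        "s5": [50, 100, 3, 10],
    },
    index=["indicator_otu", "tracks_indicator", "boundary_taxon", "resident"],
)
# boundary_taxon's ranks vs the indicator's are the permutation (1,5,2,4,3):
# Spearman rho is exactly 0.30, which does NOT exceed the 0.3 threshold.
counts.loc["boundary_taxon"] = [1, 5, 2, 4, 3]

table = TaxaCountTable(counts=counts)
params = DecontamParams(transform="raw_counts")  # keep the example's ranks exact
filtered, removed, rho = correlation_filter(
    table, IndicatorSet.from_ids(["indicator_otu"]), params
)

print("pairwise rho against the indicator:")
print(rho.round(3).to_string())
print("\ndispositions:")
for record in removed:
    print(f"  {record.taxon_id}: {record.disposition} {record.evidence}")
for taxon in filtered.taxon_ids:
    print(f"  {taxon}: retained")
# tracks_indicator is removed (rho 1.0 > 0.3) with the indicator recorded as
# evidence; boundary_taxon (rho 0.30) and the anti-correlated resident stay.
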