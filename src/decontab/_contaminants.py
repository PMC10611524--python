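"""A bundled list of genera widely reported as reagent/laboratory contaminants.

Convenience default for simulations and quick exploratory runs.  It is a
small synthetic compilation of genera repeatedly flagged in published
contaminant surveys of DNA extraction kits and reagents (water- and
soil-associated taxa that dominate low-biomass negative controls); it is NOT
a reconstruction of any single published curated list, and real analyses
should supply their own exclusion-list files.
"""

CONTAMINANT_GENERA: tuple[str, ...] = (
    "Acinetobacter",
    "Afipia",
    "Aquabacterium",
    "Bradyrhizobium",
    "Brevundimonas",
    "Burkholderia",
    "Caulobacter",
    "Comamonas",
    "Cupriavidus",
    "Curvibacter",
    "Delftia",
    "Duganella",
    "Escherichia",
    "Flavobacterium",
    "Herbaspirillum",
    "Janthinobacterium",
    "Leifsonia",
    "Massilia",
    "Mesorhizobium",
    "Methylobacterium",
    "Novosphingobium",
    "Ochrobactrum",
    "Pedobacter",
    "Pelomonas",
    "Phyllobacterium",
    "Propionibacterium",
    "Pseudomonas",
    "Ralstonia",
    "Rhizobium",
    "Rhodococcus",
    "Sediminibacterium",
    "Sphingobium",
    "Sphingomonas",
    "Sphingopyxis",
    "Stenotrophomonas",
    "Undibacterium",
    "Variovorax",
    "Xanthomonas",
)
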