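"""Simulate a FACS-sorted reporter CRISPR screen with planted regulators.

Builds a toy genome and guide library, plants activators, repressors and
centromere-proximal artifact genes for one reporter, and simulates sorted
low/high-bin sgRNA counts.
"""

import reporterscreen as rs

annotation = rs.make_genome(n_chromosomes=2, genes_per_chromosome=50, seed=1)
library = rs.make_library(annotation, guides_per_gene=4, n_controls=20, seed=2)
reporter = annotation.genes["gene"].iloc[10]
truth = rs.plant_truth(
    annotation, reporter, n_activators=4, n_repressors=4,
    effect_size=2.0, n_artifacts=2, seed=3,
)
config = rs.ScreenConfig(
    replicates=3, cells_per_replicate=60_000, reads_per_bin=60_000, seed=4
)
screen = rs.simulate_screen(library, truth, reporter, config)

matrix = screen.counts.to_matrix()
print(f"reporter screen: {reporter}")
print(f"guides x samples: {matrix.shape[0]} x {matrix.shape[1]}")
print(f"reads per bin: {matrix.sum(axis=0).iloc[0]} (fixed sequencing depth)")
print("planted truth:", screen.truth_labels.value_counts().to_dict())
# Activator knockouts lower the reporter, so their guides pile up in the
# low bin; artifact genes mimic reporter-allele loss in a cell subset.
g = truth.effects["gene"].iloc[0]
guides = library.entries.loc[library.entries["gene"] == g, "sgrna"]
low = matrix.loc[guides, [c for c in matrix if c.endswith("_low")]].sum().sum()
high = matrix.loc[guides, [c for c in matrix if c.endswith("_high")]].sum().sum()
print(f"planted activator {g}: low-bin reads {low} vs high-bin reads {high}")
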