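"""Cross-screen co-regulation: overlaps, screen groups, condition effects.

Builds screens with planted shared-regulator structure, computes the
shared-activator / shared-repressor matrices, clusters the screens into
the two-group partition, and runs a treated-vs-untreated intersection.
"""

import numpy as np
import pandas as pd

import reporterscreen as rs

rng = np.random.default_rng(31)
shared_act = [f"ACT{i}" for i in range(60)]
shared_rep = [f"REP{i}" for i in range(60)]
tables = {}
for block, pool, sense in (("A", shared_act, "activator"),
                           ("B", shared_rep, "repressor")):
    other = "repressor" if sense == "activator" else "activator"
    for k in range(5):
        name = f"{block}{k}"
        rows = [
            {"screen": name, "gene": g, "sense": sense, "score": 1e-4, "fdr": 0.01}
            for g in rng.choice(pool, 30, replace=False)
        ] + [
            {"screen": name, "gene": f"{name}_x{i}", "sense": other,
             "score": 1e-4, "fdr": 0.01}
            for i in range(10)
        ]
        tables[name] = rs.HitTable(pd.DataFrame(rows))

matrices = rs.overlap_matrices(tables)
print("shared activators A0 vs A1:", matrices.activator.loc["A0", "A1"],
      f"(Jaccard {matrices.activator_jaccard.loc['A0', 'A1']:.2f})")

assignment = rs.cluster_screens(matrices)
print("group 1 (shared activators):", assignment.screens_in(1))
print("group 2 (shared repressors):", assignment.screens_in(2))
print(f"silhouette of the 2-split: {assignment.silhouette:.2f}")

common, regions = rs.shared_regulators(tables, ["A0", "A1", "A2"], "activator")
print(f"\nactivators shared by A0/A1/A2: {len(common)}")

treated = {"T0": tables["A0"], "T1": tables["A1"]}
untreated = {"U0": tables["B0"]}
common, specific = rs.condition_specific_regulators(treated, untreated)
print(f"common to all treated screens: {len(common)}; "
      f"treated-specific (absent untreated): {len(specific)}")
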