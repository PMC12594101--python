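"""Assemble per-screen hit tables into a directed regulatory network.

Each hit becomes a regulator -> target edge with sense (activation /
repression) and -log10 RRA weight; regulators are classified as
activator-only, repressor-only or context-dependent.
"""

import pandas as pd

import reporterscreen as rs


def hit_table(screen, activators=(), repressors=()):
    rows = [
        {"screen": screen, "gene": g, "sense": "activator", "score": 1e-4, "fdr": 0.01}
        for g in activators
    ] + [
        {"screen": screen, "gene": g, "sense": "repressor", "score": 1e-5, "fdr": 0.01}
        for g in repressors
    ]
    return rs.HitTable(pd.DataFrame(rows))


tables = {
    "REP1": hit_table("REP1", activators=["KIN1", "TF2", "UBQ3"], repressors=["COR4"]),
    "REP2": hit_table("REP2", activators=["KIN1"], repressors=["TF2", "COR4"]),
    "REP3": hit_table("REP3", activators=["KIN1", "UBQ3"], repressors=["COR4", "TF5"]),
}

network = rs.build_network(tables)
print("network summary:", network.summary())
classes = rs.classify_regulators(network)
print(classes.to_string(index=False))
# TF2 activates REP1 but represses REP2: a context-dependent regulator.

ranked = rs.rank_regulators(network, "activator", by="appearance_count")
print("\nbroadest activator:", ranked.iloc[0]["regulator"],
      f"(in {ranked.iloc[0]['appearance_count']} screens)")

rs.export_network(network, "network.sif", "sif")
print("wrote network.sif (Cytoscape-ready, 'activates'/'represses' edges)")
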