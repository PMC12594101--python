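"""Directed, signed regulatory network assembled from per-screen hits.

Each retained hit becomes one edge regulator -> target (the screened
reporter gene), with sense 1 for activation and 0 for repression, the
RRA score, and weight -log10(score).  Regulators detected as activators
for some targets and repressors for others are "context-dependent".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .filtering import HitTable

__all__ = [
    "RegulatoryNetwork",
    "build_network",
    "classify_regulators",
    "rank_regulators",
    "export_network",
    "import_network_tsv",
]

_SENSE_CODE = {"activator": 1, "repressor": 0}
_EDGE_COLS = ["regulator", "target", "sense", "score", "weight"]


@dataclass
class RegulatoryNetwork:
    """Edge list with convenience accessors.

    ``edges`` columns: ``regulator, target, sense`` (1 activation /
    0 repression), ``score`` (RRA), ``weight`` (-log10 score).
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.edges.reset_index(drop=True)[_EDGE_COLS]
        if df.duplicated(["regulator", "target", "sense"]).any():
            raise ValueError("duplicate (regulator, target, sense) edges")
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def regulators(self) -> set[str]:
        return set(self.edges["regulator"])

    @property
    def targets(self) -> set[str]:
        return set(self.edges["target"])

    @property
    def self_loops(self) -> pd.DataFrame:
        return self.edges[self.edges["regulator"] == self.edges["target"]]

    def summary(self) -> dict:
        e = self.edges
        return {
            "edges": len(e),
            "activating": int((e["sense"] == 1).sum()),
            "repressing": int((e["sense"] == 0).sum()),
            "regulators": len(self.regulators),
            "targets": len(self.targets),
            "self_loops": len(self.self_loops),
        }

    def to_graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for _, r in self.edges.iterrows():
            g.add_edge(
                r["regulator"],
                r["target"],
                sense=int(r["sense"]),
                score=float(r["score"]),
                weight=float(r["weight"]),
            )
        return g


def build_network(hit_tables: list[HitTable] | dict[str, HitTable]) -> RegulatoryNetwork:
    """Combine filtered per-screen hit tables into one network.

    One edge per retained hit; the screen name becomes the target node.
    A dict maps screen name -> table (overriding the tables' own screen
    column); a list uses each table's ``screen`` column.
    """
    frames = []
    if isinstance(hit_tables, dict):
        items = [(name, t.hits.assign(screen=name)) for name, t in hit_tables.items()]
    else:
        items = [(None, t.hits) for t in hit_tables]
    for _, hits in items:
        if hits.empty:
            continue
        df = pd.DataFrame(
            {
                "regulator": hits["gene"].to_numpy(),
                "target": hits["screen"].to_numpy(),
                "sense": hits["sense"].map(_SENSE_CODE).to_numpy(),
                "score": hits["score"].to_numpy(),
            }
        )
        frames.append(df)
    if not frames:
        edges = pd.DataFrame(columns=_EDGE_COLS)
        return RegulatoryNetwork(edges)
    edges = pd.concat(frames, ignore_index=True)
    edges["weight"] = edges["score"].map(
        lambda s: math.inf if s <= 0 else -math.log10(s)
    )
    return RegulatoryNetwork(edges)


def classify_regulators(network: RegulatoryNetwork) -> pd.DataFrame:
    """Partition regulators into activator-only / repressor-only /
    context-dependent, with per-sense target counts and the number of
    screens each regulator appears in."""
    e = network.edges
    rows = []
    for reg, sub in e.groupby("regulator"):
        n_act = int((sub["sense"] == 1).sum())
        n_rep = int((sub["sense"] == 0).sum())
        if n_act and n_rep:
            cls = "context-dependent"
        elif n_act:
            cls = "activator-only"
        else:
            cls = "repressor-only"
        rows.append(
            {
                "regulator": reg,
                "class": cls,
                "n_activated": n_act,
                "n_repressed": n_rep,
                "n_screens": int(sub["target"].nunique()),
            }
        )
    return pd.DataFrame(
        rows, columns=["regulator", "class", "n_activated", "n_repressed", "n_screens"]
    )


def rank_regulators(
    network: RegulatoryNetwork, sense: str, by: str = "best_score"
) -> pd.DataFrame:
    """Rank regulators of one sense by best (minimum) RRA score or by the
    number of screens they appear in; ties broken by gene symbol."""
    if len(network) == 0:
        raise ValueError("empty network")
    code = _SENSE_CODE[sense]
    sub = network.edges[network.edges["sense"] == code]
    agg = (
        sub.groupby("regulator")
        .agg(best_score=("score", "min"), appearance_count=("target", "nunique"))
        .reset_index()
    )
    if by == "best_score":
        agg = agg.sort_values(["best_score", "regulator"], ascending=[True, True])
    elif by == "appearance_count":
        agg = agg.sort_values(
            ["appearance_count", "regulator"], ascending=[False, True]
        )
    else:
        raise ValueError(f"unknown ranking: {by}")
    return agg.reset_index(drop=True)


def export_network(network: RegulatoryNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write the network as TSV (lossless), SIF or GraphML."""
    path = Path(path)
    if format == "tsv":
        network.edges.to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for _, r in network.edges.iterrows():
                label = "activates" if r["sense"] == 1 else "represses"
                fh.write(f"{r['regulator']}\t{label}\t{r['target']}\n")
    elif format == "graphml":
        nx.write_graphml(network.to_graph(), path)
    else:
        raise ValueError(f"unknown format: {format}")


def import_network_tsv(path: str | Path) -> RegulatoryNetwork:
    return RegulatoryNetwork(pd.read_csv(path, sep="\t"))
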