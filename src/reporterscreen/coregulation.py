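"""Cross-screen co-regulation analysis.

Shared-regulator overlap matrices between screens, hierarchical
clustering of screens into two groups (group 1: screens sharing
activators; group 2: screens sharing repressors), multi-screen shared
regulator queries with Venn-region counts, condition-specific regulator
intersection, and functional-class hit distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .filtering import HitTable

__all__ = [
    "OverlapMatrices",
    "GroupAssignment",
    "overlap_matrices",
    "cluster_screens",
    "shared_regulators",
    "condition_specific_regulators",
    "class_distribution",
    "plot_overlap_heatmap",
]


def _hit_sets(
    hit_tables: dict[str, HitTable] | dict[str, pd.DataFrame], sense: str
) -> dict[str, set[str]]:
    out = {}
    for name, table in hit_tables.items():
        hits = table.hits if isinstance(table, HitTable) else table
        out[name] = set(hits.loc[hits["sense"] == sense, "gene"])
    return out


@dataclass
class OverlapMatrices:
    """Symmetric screen-by-screen shared-regulator counts per sense,
    with companion Jaccard matrices; diagonals hold per-screen hit
    counts (Jaccard diagonal is 1 for non-empty screens)."""

    activator: pd.DataFrame
    repressor: pd.DataFrame
    activator_jaccard: pd.DataFrame
    repressor_jaccard: pd.DataFrame

    @property
    def screens(self) -> list[str]:
        return list(self.activator.index)

    def to_tsv(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        self.activator.to_csv(f"{prefix}.activator_overlap.tsv", sep="\t")
        self.repressor.to_csv(f"{prefix}.repressor_overlap.tsv", sep="\t")
        self.activator_jaccard.to_csv(f"{prefix}.activator_jaccard.tsv", sep="\t")
        self.repressor_jaccard.to_csv(f"{prefix}.repressor_jaccard.tsv", sep="\t")


def _overlap_pair(sets: dict[str, set[str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    names = list(sets)
    n = len(names)
    counts = np.zeros((n, n), dtype=int)
    jac = np.zeros((n, n))
    for i, a in enumerate(names):
        counts[i, i] = len(sets[a])
        jac[i, i] = 1.0 if sets[a] else 0.0
        for j in range(i + 1, n):
            inter = len(sets[a] & sets[names[j]])
            union = len(sets[a] | sets[names[j]])
            counts[i, j] = counts[j, i] = inter
            jac[i, j] = jac[j, i] = inter / union if union else 0.0
    return (
        pd.DataFrame(counts, index=names, columns=names),
        pd.DataFrame(jac, index=names, columns=names),
    )


def overlap_matrices(hit_tables: dict[str, HitTable]) -> OverlapMatrices:
    """Compute shared-activator and shared-repressor matrices across screens."""
    if len(hit_tables) < 2:
        raise ValueError("need at least two screens")
    act_counts, act_jac = _overlap_pair(_hit_sets(hit_tables, "activator"))
    rep_counts, rep_jac = _overlap_pair(_hit_sets(hit_tables, "repressor"))
    return OverlapMatrices(act_counts, rep_counts, act_jac, rep_jac)


@dataclass
class GroupAssignment:
    """Two-way screen partition from regulator-overlap clustering."""

    groups: pd.Series  # screen -> 1 / 2 / "unassigned"
    linkage_matrix: np.ndarray
    silhouette: float

    def screens_in(self, group) -> list[str]:
        return sorted(self.groups.index[self.groups == group])

    def to_tsv(self, path: str | Path) -> None:
        self.groups.rename("group").rename_axis("screen").to_csv(path, sep="\t")


def cluster_screens(
    matrices: OverlapMatrices, linkage_method: str = "average", k: int = 2
) -> GroupAssignment:
    """Average-linkage clustering of screens on shared-regulator similarity.

    Distance between two screens is ``1 - mean(Jaccard_act, Jaccard_rep)``.
    The tree is cut at ``k`` clusters (default 2); the cluster with the
    higher mean within-group activator Jaccard is labeled group 1, the
    other group 2.  Degenerate input (all screens identical) yields
    "unassigned" everywhere.
    """
    screens = matrices.screens
    if len(screens) < 3:
        raise ValueError("need at least three screens to cluster")
    sim = (matrices.activator_jaccard.to_numpy() + matrices.repressor_jaccard.to_numpy()) / 2
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method=linkage_method)
    labels = fcluster(z, t=k, criterion="maxclust")
    if len(set(labels)) < 2:
        groups = pd.Series("unassigned", index=pd.Index(screens, name="screen"))
        return GroupAssignment(groups, z, float("nan"))

    act = matrices.activator_jaccard.to_numpy()

    def within_act(cluster_id: int) -> float:
        idx = np.flatnonzero(labels == cluster_id)
        if len(idx) < 2:
            return 0.0
        block = act[np.ix_(idx, idx)]
        off = block[~np.eye(len(idx), dtype=bool)]
        return float(off.mean())

    ids = sorted(set(labels))
    group1 = max(ids, key=within_act)
    mapped = np.where(labels == group1, 1, 2)
    sil = float(silhouette_score(dist, mapped, metric="precomputed"))
    groups = pd.Series(mapped, index=pd.Index(screens, name="screen"))
    return GroupAssignment(groups, z, sil)


def shared_regulators(
    hit_tables: dict[str, HitTable], screens: list[str], sense: str
) -> tuple[set[str], dict[frozenset, int]]:
    """Regulators of one sense shared by 2-4 screens, with Venn regions.

    Returns the full intersection plus counts for every exclusive Venn
    region keyed by the subset of screens containing it.
    """
    if not 2 <= len(screens) <= 4:
        raise ValueError("query 2-4 screens")
    unknown = [s for s in screens if s not in hit_tables]
    if unknown:
        raise KeyError(f"unknown screens: {unknown}")
    sets = {s: _hit_sets({s: hit_tables[s]}, sense)[s] for s in screens}
    common = set.intersection(*sets.values())
    regions: dict[frozenset, int] = {}
    union = set.union(*sets.values())
    for gene in union:
        member = frozenset(s for s in screens if gene in sets[s])
        regions[member] = regions.get(member, 0) + 1
    return common, regions


def condition_specific_regulators(
    treated: dict[str, HitTable],
    untreated: dict[str, HitTable],
    sense: str | None = None,
) -> tuple[set[str], set[str]]:
    """Regulators common to all treated screens, and the subset absent
    from every untreated screen.

    With ``sense=None`` a regulator counts regardless of sense.
    """
    def genes(table: HitTable) -> set[str]:
        hits = table.hits
        if sense is not None:
            hits = hits[hits["sense"] == sense]
        return set(hits["gene"])

    common = set.intersection(*(genes(t) for t in treated.values())) if treated else set()
    baseline = set().union(*(genes(t) for t in untreated.values())) if untreated else set()
    return common, common - baseline


def plot_overlap_heatmap(
    matrices: OverlapMatrices,
    path: str | Path,
    assignment: GroupAssignment | None = None,
) -> None:
    """Write a two-panel heatmap of the activator (blues) and repressor
    (reds) overlap-count matrices, screens ordered by the clustering
    leaf order (or by group when an assignment is given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list

    screens = matrices.screens
    if assignment is not None and not (assignment.groups == "unassigned").any():
        order = list(leaves_list(assignment.linkage_matrix))
    else:
        order = list(range(len(screens)))
    names = [screens[i] for i in order]
    fig, axes = plt.subplots(1, 2, figsize=(2 + 0.25 * len(names) * 2, 3 + 0.25 * len(names)))
    for ax, mat, cmap, title in (
        (axes[0], matrices.activator, "Blues", "shared activators"),
        (axes[1], matrices.repressor, "Reds", "shared repressors"),
    ):
        im = ax.imshow(mat.iloc[order, order], cmap=cmap)
        ax.set_xticks(range(len(names)), names, rotation=90, fontsize=6)
        ax.set_yticks(range(len(names)), names, fontsize=6)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def class_distribution(
    hit_tables: dict[str, HitTable], class_map: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-screen hit counts and fractions by functional class and sense.

    ``class_map`` assigns genes to user-supplied functional classes
    (e.g. from an external enrichment analysis); unmapped genes fall in
    no class.  Returns columns ``screen, sense, class, count, fraction``
    where fraction is relative to the screen's hits of that sense.
    """
    if isinstance(class_map, pd.Series):
        class_map = class_map.to_dict()
    rows = []
    classes = sorted(set(class_map.values()))
    for screen, table in hit_tables.items():
        hits = table.hits if isinstance(table, HitTable) else table
        for sense in ("activator", "repressor"):
            genes = hits.loc[hits["sense"] == sense, "gene"]
            total = len(genes)
            for cls in classes:
                count = int(sum(class_map.get(g) == cls for g in genes))
                rows.append(
                    {
                        "screen": screen,
                        "sense": sense,
                        "class": cls,
                        "count": count,
                        "fraction": count / total if total else 0.0,
                    }
                )
    return pd.DataFrame(rows, columns=["screen", "sense", "class", "count", "fraction"])
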