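"""Hit filtering for reporter screens.

Three filters produce the final per-screen hit table:

1. RRA score cutoff (strict ``< 1e-3`` by default) per direction —
   ``pos`` hits are activators, ``neg`` hits repressors.
2. Centromere-interval filter: genes lying between the centromere and
   the knock-in reporter locus are removed as reporter-loss artifacts
   (Cas9 cutting there can delete the reporter allele outright).
3. Transcriptional-inactivity filter: hits with rpkm below 0.1 are
   removed; genes absent from the expression table are retained.

Plus the validation-labeling rule for individually re-tested hits: a
reporter MFI shift of more than 5% in the expected direction counts as
a true positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import GenomeAnnotation
from .simulate import _artifact_span

__all__ = [
    "FilterConfig",
    "HitTable",
    "apply_rra_cutoff",
    "filter_centromere_interval",
    "filter_inactive",
    "classify_validation",
]

_HIT_COLS = ["screen", "gene", "sense", "score", "fdr"]
_REMOVAL_COLS = ["screen", "gene", "sense", "score", "fdr", "reason"]


@dataclass
class FilterConfig:
    rra_cutoff: float = 1e-3  # strict <
    min_rpkm: float = 0.1  # strict < removes
    target_gene: str | None = None  # knock-in gene of the screen

    def __post_init__(self) -> None:
        if not 0 < self.rra_cutoff < 1:
            raise ValueError("rra_cutoff must be in (0, 1)")
        if self.min_rpkm < 0:
            raise ValueError("min_rpkm must be >= 0")


@dataclass
class HitTable:
    """Per-screen hits with removal provenance.

    ``hits``: columns ``screen, gene, sense, score, fdr`` with sense in
    {activator, repressor}.  ``removed`` adds a ``reason`` column and
    accumulates across filters, so ``len(input) = len(output) +
    removals`` holds for every filtering step.
    """

    hits: pd.DataFrame
    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_REMOVAL_COLS)
    )

    def __post_init__(self) -> None:
        self.hits = self.hits.reset_index(drop=True)[_HIT_COLS]
        self.removed = self.removed.reset_index(drop=True)[_REMOVAL_COLS]
        bad = ~self.hits["sense"].isin(["activator", "repressor"])
        if bad.any():
            raise ValueError("sense must be activator or repressor")

    def __len__(self) -> int:
        return len(self.hits)

    def genes(self, sense: str | None = None) -> set[str]:
        df = self.hits if sense is None else self.hits[self.hits["sense"] == sense]
        return set(df["gene"])

    def to_tsv(self, path: str | Path, removal_path: str | Path | None = None) -> None:
        self.hits.to_csv(path, sep="\t", index=False)
        if removal_path is not None:
            self.removed.to_csv(removal_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HitTable":
        return cls(pd.read_csv(path, sep="\t"))


def apply_rra_cutoff(
    gene_scores: pd.DataFrame,
    config: FilterConfig | None = None,
    screen: str = "screen",
) -> HitTable:
    """Call hits from a gene score table at the RRA cutoff.

    Activators are genes with ``pos_score < cutoff`` (low-bin
    enrichment), repressors those with ``neg_score < cutoff``; a gene
    passing in both directions appears twice, once per sense.  The
    cutoff is strict: a score exactly at the threshold is excluded.
    """
    config = config or FilterConfig()
    rows = []
    for direction, sense in (("pos", "activator"), ("neg", "repressor")):
        sub = gene_scores[gene_scores[f"{direction}_score"] < config.rra_cutoff]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "screen": screen,
                    "gene": r["gene"],
                    "sense": sense,
                    "score": r[f"{direction}_score"],
                    "fdr": r[f"{direction}_fdr"],
                }
            )
    return HitTable(pd.DataFrame(rows, columns=_HIT_COLS))


def filter_centromere_interval(
    table: HitTable, annotation: GenomeAnnotation, target_gene: str
) -> HitTable:
    """Remove hits lying between the centromere and the knock-in locus.

    The excluded region is the closed span from the centromere boundary
    nearest the target gene through the target gene's far coordinate; a
    hit is removed when its gene body overlaps that span on the target's
    chromosome.  Hits on other chromosomes, or on the opposite side of
    the centromere, are retained.
    """
    target = annotation.gene(target_gene)  # raises KeyError if missing
    cen_start, cen_end = annotation.centromere(target["chrom"])
    span_lo, span_hi = _artifact_span(
        cen_start, cen_end, int(target["start"]), int(target["end"])
    )
    genes = annotation.genes.set_index("gene")
    known = table.hits["gene"].isin(genes.index)
    chrom = table.hits["gene"].map(genes["chrom"])
    start = table.hits["gene"].map(genes["start"])
    end = table.hits["gene"].map(genes["end"])
    in_span = (
        known
        & (chrom == target["chrom"])
        & (start < span_hi)
        & (end > span_lo)
        # the knock-in gene itself bounds the span; self-hits are kept
        # (they surface as flagged self-loops in the network)
        & (table.hits["gene"] != target_gene)
    )
    removed = table.hits[in_span].assign(reason="centromere_interval")
    kept = table.hits[~in_span]
    return HitTable(kept, _append_removed(table.removed, removed))


def filter_inactive(
    table: HitTable, expression: pd.Series | pd.DataFrame, min_rpkm: float = 0.1
) -> HitTable:
    """Remove hits on transcriptionally inactive genes (rpkm strictly
    below ``min_rpkm``); genes missing from the expression table are
    retained."""
    if isinstance(expression, pd.DataFrame):
        expression = expression.set_index("gene")["rpkm"]
    rpkm = table.hits["gene"].map(expression)
    inactive = rpkm.notna() & (rpkm < min_rpkm)
    removed = table.hits[inactive].assign(reason="inactive")
    kept = table.hits[~inactive]
    return HitTable(kept, _append_removed(table.removed, removed))


def _append_removed(existing: pd.DataFrame, new: pd.DataFrame) -> pd.DataFrame:
    frames = [df for df in (existing, new) if not df.empty]
    if not frames:
        return pd.DataFrame(columns=_REMOVAL_COLS)
    return pd.concat(frames, ignore_index=True)[_REMOVAL_COLS]


def classify_validation(relative_mfi: float, expected_sense: str) -> str:
    """Label an individually validated hit.

    ``relative_mfi`` is reporter mean fluorescence after targeting the
    hit, relative to a non-targeting control.  A change of more than 5%
    in the expected direction (reduction for activators, increase for
    repressors) is a true positive; anything else a false positive.
    """
    if relative_mfi <= 0:
        raise ValueError("relative MFI must be positive")
    if expected_sense == "activator":
        return "true_positive" if relative_mfi < 0.95 else "false_positive"
    if expected_sense == "repressor":
        return "true_positive" if relative_mfi > 1.05 else "false_positive"
    raise ValueError(f"unknown sense: {expected_sense}")
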