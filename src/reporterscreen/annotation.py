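"""Genome annotation: chromosomes, centromeres, gene intervals, expression.

Coordinates are 0-based half-open internally; BED-like text output keeps
that convention, while human-readable reports print 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["GenomeAnnotation"]

_CHROM_COLS = ["chrom", "length", "cen_start", "cen_end"]
_GENE_COLS = ["gene", "chrom", "start", "end", "strand", "rpkm"]


@dataclass
class GenomeAnnotation:
    """Chromosome sizes with centromere intervals plus gene bodies.

    Parameters
    ----------
    chromosomes
        Columns ``chrom, length, cen_start, cen_end``.
    genes
        Columns ``gene, chrom, start, end, strand, rpkm``.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.chromosomes = self.chromosomes.reset_index(drop=True)[_CHROM_COLS]
        self.genes = self.genes.reset_index(drop=True)[_GENE_COLS]
        self._validate()

    def _validate(self) -> None:
        chroms = self.chromosomes
        if chroms["chrom"].duplicated().any():
            raise ValueError("duplicate chromosome names")
        bad = (
            (chroms["cen_start"] < 0)
            | (chroms["cen_end"] > chroms["length"])
            | (chroms["cen_start"] >= chroms["cen_end"])
        )
        if bad.any():
            raise ValueError("centromere interval outside chromosome bounds")
        genes = self.genes
        if genes["gene"].duplicated().any():
            dup = genes.loc[genes["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene symbol: {dup}")
        merged = genes.merge(chroms, on="chrom", how="left")
        if merged["length"].isna().any():
            raise ValueError("gene on unannotated chromosome")
        bad = (merged["start"] < 0) | (merged["end"] > merged["length"]) | (
            merged["start"] >= merged["end"]
        )
        if bad.any():
            raise ValueError("gene interval outside chromosome bounds")

    def gene(self, symbol: str) -> pd.Series:
        rows = self.genes[self.genes["gene"] == symbol]
        if rows.empty:
            raise KeyError(f"gene not annotated: {symbol}")
        return rows.iloc[0]

    def centromere(self, chrom: str) -> tuple[int, int]:
        rows = self.chromosomes[self.chromosomes["chrom"] == chrom]
        if rows.empty:
            raise KeyError(f"chromosome not annotated: {chrom}")
        r = rows.iloc[0]
        return int(r["cen_start"]), int(r["cen_end"])

    @property
    def rpkm(self) -> pd.Series:
        """Expression per gene symbol."""
        return self.genes.set_index("gene")["rpkm"]

    # ---- text round trip (BED-like TSVs) ---------------------------------

    def to_tsv(self, chrom_path: str | Path, gene_path: str | Path) -> None:
        self.chromosomes.to_csv(chrom_path, sep="\t", index=False)
        self.genes.to_csv(gene_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, chrom_path: str | Path, gene_path: str | Path) -> "GenomeAnnotation":
        return cls(
            pd.read_csv(chrom_path, sep="\t"),
            pd.read_csv(gene_path, sep="\t"),
        )
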