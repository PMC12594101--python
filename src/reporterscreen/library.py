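"""sgRNA library table: guides, gene mapping, non-targeting controls."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["CONTROL", "SgRNALibrary"]

#: Gene label marking non-targeting control guides.
CONTROL = "CONTROL"

_VALID = set("ACGT")


@dataclass
class SgRNALibrary:
    """A pooled sgRNA library.

    ``entries`` has columns ``sgrna`` (unique id), ``sequence`` (20-nt
    protospacer over A/C/G/T) and ``gene`` (target symbol, or
    :data:`CONTROL` for non-targeting guides).
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.entries.reset_index(drop=True)[["sgrna", "sequence", "gene"]].copy()
        df["sequence"] = df["sequence"].str.upper()
        if df["sgrna"].duplicated().any():
            raise ValueError("sgRNA ids must be unique")
        lens = df["sequence"].str.len()
        if (lens != 20).any():
            raise ValueError("sgRNA sequences must be 20 nt")
        if not df["sequence"].map(lambda s: set(s) <= _VALID).all():
            raise ValueError("sgRNA sequences must be over {A,C,G,T}")
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def targeting(self) -> pd.DataFrame:
        return self.entries[self.entries["gene"] != CONTROL]

    @property
    def controls(self) -> pd.DataFrame:
        return self.entries[self.entries["gene"] == CONTROL]

    @property
    def genes(self) -> list[str]:
        return sorted(self.targeting["gene"].unique())

    def gene_of(self) -> pd.Series:
        """sgRNA id -> gene symbol (controls map to CONTROL)."""
        return self.entries.set_index("sgrna")["gene"]

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SgRNALibrary":
        return cls(pd.read_csv(path, sep="\t"))
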