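"""Staggered readout primers and amplicon templates.

Pooled sgRNA readout amplicons share a fixed structure::

    stagger + 8-nt index + Template1 + 20-nt sgRNA + Template2

The stagger (1-9 nt) provides base-composition complexity on the flow
cell, the index identifies the sample (replicate x sorted bin), and the
two templates are the constant vector sequence flanking the guide.  The
twelve stock primers below allow twelve samples -- six replicates times
two FACS bins -- to be pooled in one lane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TEMPLATE1",
    "TEMPLATE2",
    "Primer",
    "PrimerSet",
    "default_primers",
    "default_sample_layout",
]

#: Constant sequence between the sample index and the 20-nt guide.
TEMPLATE1 = "TCTTGTGGAAAGGACGAAACACCG"

#: Constant vector sequence downstream of the guide (sgRNA scaffold and
#: flanking vector; only a prefix is sequenced on a 75-bp read).
TEMPLATE2 = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGG"
    "CACCGAGTCGGTGCTTTTTTAAGCTTGGCGTAACTAGATCTTGAGACAAATGGCAGTATTCA"
    "TCCACAATTTTAAAAGAAAAGGGGGGATTGGGGGGTACAGTGCAGGGGAAAGAATAGTAGA"
)

_DEFAULT_PRIMER_TABLE = [
    ("F01", "T", "AAGTAGAG"),
    ("F02", "AT", "ACACGATC"),
    ("F03", "GAT", "CGCGCGGT"),
    ("F04", "CGAT", "CATGATCG"),
    ("F05", "TCGAT", "CGTTACCA"),
    ("F06", "ATCGAT", "TCCTTGGT"),
    ("F07", "GATCGAT", "AACGCATT"),
    ("F08", "CGATCGAT", "ACAGGTAT"),
    ("F09", "ACGATCGAT", "AGGTAAGG"),
    ("F10", "T", "AACAATGG"),
    ("F11", "AT", "ACTGTATC"),
    ("F12", "GAT", "AGGTCGCA"),
]


@dataclass(frozen=True)
class Primer:
    name: str
    stagger: str
    index: str

    @property
    def prefix(self) -> str:
        """Stagger + index: the exact-match demultiplexing key."""
        return self.stagger + self.index


@dataclass(frozen=True)
class PrimerSet:
    """An ordered set of readout primers with unique (stagger, index) pairs."""

    primers: tuple[Primer, ...]
    template1: str = TEMPLATE1
    template2: str = TEMPLATE2

    def __post_init__(self) -> None:
        pairs = [(p.stagger, p.index) for p in self.primers]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(stagger, index) pairs must be unique")
        names = [p.name for p in self.primers]
        if len(set(names)) != len(names):
            raise ValueError("primer names must be unique")
        for p in self.primers:
            if len(p.index) != 8:
                raise ValueError(f"index of {p.name} is not 8 nt")
            if not 1 <= len(p.stagger) <= 9:
                raise ValueError(f"stagger of {p.name} not in 1-9 nt")

    def __len__(self) -> int:
        return len(self.primers)

    def __iter__(self):
        return iter(self.primers)

    def get(self, name: str) -> Primer:
        for p in self.primers:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.primers]


def default_primers() -> PrimerSet:
    """The twelve stock staggered readout primers (F01-F12)."""
    return PrimerSet(tuple(Primer(n, s, i) for n, s, i in _DEFAULT_PRIMER_TABLE))


def default_sample_layout(n_replicates: int = 6) -> dict[str, str]:
    """Map primer name -> sample name for the standard pooling scheme.

    Odd primers carry the low-fluorescence bin, even primers the high
    bin, walking through replicates in order: F01 = rep1_low, F02 =
    rep1_high, ... F12 = rep6_high.
    """
    if not 1 <= n_replicates <= 6:
        raise ValueError("standard layout supports 1-6 replicates")
    layout: dict[str, str] = {}
    for rep in range(1, n_replicates + 1):
        layout[f"F{2 * rep - 1:02d}"] = f"rep{rep}_low"
        layout[f"F{2 * rep:02d}"] = f"rep{rep}_high"
    return layout
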