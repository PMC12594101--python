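"""Amplicon reference construction and read-to-count demultiplexing.

Readout amplicons have a fixed-position structure (stagger + index +
Template1 + guide + Template2), so counting is done by positional
substitution-tolerant (Hamming) matching rather than general alignment:
the stagger/index prefix must match one primer exactly, the Template1
region may carry a bounded number of substitutions, and the 20-nt guide
region is assigned to its unique best library match within the mismatch
budget (ties are discarded).  This makes counting exactly reproducible.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .library import SgRNALibrary
from .primers import PrimerSet, default_primers

__all__ = [
    "ReferenceIndex",
    "CountTable",
    "build_reference",
    "count_reads",
    "count_qc",
]


# ---------------------------------------------------------------------------
# count table


@dataclass
class CountTable:
    """Per-sample sgRNA counts.

    ``counts`` has columns ``sample, gene, sgrna, count, fraction`` with
    every library guide present in every sample (zeros kept).
    ``samples`` carries per-sample metadata (``sample, replicate, bin``).
    ``unassigned`` tallies reads that could not be counted, by reason.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts.reset_index(drop=True)[
            ["sample", "gene", "sgrna", "count", "fraction"]
        ].copy()
        if (df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = df

    @classmethod
    def from_matrix(
        cls,
        matrix: pd.DataFrame,
        library: SgRNALibrary,
        samples: pd.DataFrame | None = None,
        unassigned: dict[str, int] | None = None,
    ) -> "CountTable":
        """Build from a (sgRNA id x sample) count matrix, adding zeros for
        library guides absent from the matrix."""
        matrix = matrix.reindex(library.entries["sgrna"]).fillna(0)
        gene_of = library.gene_of()
        long = (
            matrix.rename_axis("sgrna")
            .reset_index()
            .melt(id_vars="sgrna", var_name="sample", value_name="count")
        )
        long["gene"] = long["sgrna"].map(gene_of)
        totals = long.groupby("sample")["count"].transform("sum")
        long["fraction"] = np.where(totals > 0, long["count"] / totals, 0.0)
        long["count"] = long["count"].astype(np.int64)
        if samples is None:
            samples = _infer_sample_meta(matrix.columns)
        return cls(
            long[["sample", "gene", "sgrna", "count", "fraction"]],
            samples,
            unassigned or {},
        )

    def to_matrix(self) -> pd.DataFrame:
        """(sgRNA id x sample) wide count matrix."""
        return self.counts.pivot_table(
            index="sgrna", columns="sample", values="count", aggfunc="sum"
        ).astype(np.int64)

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples["sample"])

    def total(self, sample: str) -> int:
        return int(self.counts.loc[self.counts["sample"] == sample, "count"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, samples: pd.DataFrame | None = None
    ) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        if samples is None:
            samples = _infer_sample_meta(df["sample"].unique())
        return cls(df, samples)


def _infer_sample_meta(names: Iterable[str]) -> pd.DataFrame:
    """Parse 'repK_low' / 'repK_high' style names; otherwise leave blank."""
    rows = []
    for name in names:
        rep, bin_ = "", ""
        parts = str(name).rsplit("_", 1)
        if len(parts) == 2 and parts[1] in ("low", "high"):
            rep, bin_ = parts
        rows.append({"sample": name, "replicate": rep, "bin": bin_})
    return pd.DataFrame(rows, columns=["sample", "replicate", "bin"])


# ---------------------------------------------------------------------------
# reference


@dataclass
class ReferenceIndex:
    """Full amplicon reference: one record per (primer, sgRNA).

    Record names follow ``primer|gene|sgRNA``.
    """

    records: pd.DataFrame  # columns: name, primer, gene, sgrna, sequence
    library: SgRNALibrary
    primers: PrimerSet

    def __len__(self) -> int:
        return len(self.records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.records["name"], self.records["sequence"]):
                fh.write(f">{name}\n{seq}\n")


def build_reference(
    library: SgRNALibrary, primers: PrimerSet | None = None
) -> ReferenceIndex:
    """Construct the artificial amplicon reference.

    For each guide and each primer the record sequence is
    ``stagger + index + Template1 + sgRNA + Template2``; a 77,441-guide
    library with 12 primers yields 929,292 records.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    primers = primers or default_primers()
    entries = library.entries
    frames = []
    for p in primers:
        prefix = p.prefix + primers.template1
        df = pd.DataFrame(
            {
                "name": p.name + "|" + entries["gene"] + "|" + entries["sgrna"],
                "primer": p.name,
                "gene": entries["gene"].to_numpy(),
                "sgrna": entries["sgrna"].to_numpy(),
                "sequence": prefix + entries["sequence"] + primers.template2,
            }
        )
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    return ReferenceIndex(records, library, primers)


# ---------------------------------------------------------------------------
# counting


def _encode(seqs: Iterable[str], length: int) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(-1, length)


class _GuideMatcher:
    """Unique-best Hamming matcher over 20-nt guide sequences."""

    def __init__(self, library: SgRNALibrary):
        seqs = library.entries["sequence"].tolist()
        self.ids = library.entries["sgrna"].to_numpy()
        self.exact = {s: i for i, s in enumerate(seqs)}
        self.matrix = _encode(seqs, 20)

    def match(self, guide: str, max_mismatch: int) -> int | None:
        """Return library row index of the unique best match, or None."""
        idx = self.exact.get(guide)
        if idx is not None:
            return idx  # 0 mismatches; uniqueness guaranteed by library
        if max_mismatch == 0:
            return None
        query = np.frombuffer(guide.encode(), dtype=np.uint8)
        mm = (self.matrix != query).sum(axis=1)
        best = int(mm.min())
        if best > max_mismatch:
            return None
        hits = np.flatnonzero(mm == best)
        if len(hits) != 1:
            return None  # ambiguous best match: discard
        return int(hits[0])


def _iter_fastq(source) -> Iterator[str]:
    """Yield read sequences from a FASTQ path / handle / sequence iterable."""
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
    else:
        for item in source:
            yield str(getattr(item, "seq", item))


def count_reads(
    reads,
    reference: ReferenceIndex,
    max_mismatch: int = 2,
    layout: dict[str, str] | None = None,
) -> CountTable:
    """Demultiplex reads and count per-sample sgRNA hits.

    A read is assigned iff its stagger+index prefix matches exactly one
    primer exactly, its Template1 region has at most ``max_mismatch``
    substitutions, and its guide region has a unique best library match
    with at most ``max_mismatch`` substitutions.  Unassigned reads are
    tallied under reason codes in ``CountTable.unassigned``.

    ``layout`` maps primer name to sample name (default: primer names as
    sample names, or the standard rep/bin layout if it covers all primers).
    """
    primers = reference.primers
    template1 = primers.template1.upper()
    t1_len = len(template1)
    t1_arr = np.frombuffer(template1.encode(), dtype=np.uint8)
    matcher = _GuideMatcher(reference.library)
    prefixes = [(p, p.prefix.upper()) for p in primers]

    names = primers.names if layout is None else list(layout)
    sample_of = {n: n for n in primers.names} if layout is None else dict(layout)

    lib_ids = reference.library.entries["sgrna"]
    counts = {p.name: Counter() for p in primers}
    unassigned: Counter = Counter()

    for seq in _iter_fastq(reads):
        seq = seq.upper()
        matches = [(p, pref) for p, pref in prefixes if seq.startswith(pref)]
        if len(matches) != 1:
            unassigned["unknown_index" if not matches else "ambiguous_index"] += 1
            continue
        primer, pref = matches[0]
        off = len(pref)
        if len(seq) < off + t1_len + 20:
            unassigned["too_short"] += 1
            continue
        t1 = np.frombuffer(seq[off : off + t1_len].encode(), dtype=np.uint8)
        if int((t1 != t1_arr).sum()) > max_mismatch:
            unassigned["template_mismatch"] += 1
            continue
        guide = seq[off + t1_len : off + t1_len + 20]
        hit = matcher.match(guide, max_mismatch)
        if hit is None:
            unassigned["guide_unmatched"] += 1
            continue
        counts[primer.name][matcher.ids[hit]] += 1

    matrix = pd.DataFrame(
        {sample_of.get(p, p): pd.Series(c, dtype=np.int64) for p, c in counts.items()},
        index=pd.Index(lib_ids, name="sgrna"),
    ).fillna(0)
    # keep only samples named by the layout (drop primers absent from it)
    if layout is not None:
        matrix = matrix[[sample_of[n] for n in names]]
    return CountTable.from_matrix(
        matrix, reference.library, unassigned=dict(unassigned)
    )


def count_qc(table: CountTable) -> dict:
    """Deterministic summary of a count table for logs and reports."""
    df = table.counts
    per_guide = df.groupby("sgrna")["count"].sum()
    per_sample = df.groupby("sample")["count"].sum().to_dict()
    control = df[df["gene"] == "CONTROL"]["count"].sum()
    total = df["count"].sum()
    return {
        "zero_count_sgrnas": sorted(per_guide.index[per_guide == 0]),
        "n_zero_count_sgrnas": int((per_guide == 0).sum()),
        "per_sample_totals": {k: int(v) for k, v in sorted(per_sample.items())},
        "control_fraction": float(control / total) if total > 0 else 0.0,
        "unassigned": dict(table.unassigned),
    }
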