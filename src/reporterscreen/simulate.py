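"""Synthetic reporter-screen generator.

Emulates the experimental design of a FACS-sorted reporter CRISPR
screen: cells carry one guide each (low-MOI infection), the reporter is
log-normally distributed with a multiplicative knockout effect per
targeted gene, the bottom and top tails are sorted, and each sorted bin
is sequenced to a fixed read depth (multinomial sampling).  A
centromere-proximal reporter-loss artifact is modelled as complete loss
of reporter signal in a fraction of cells carrying guides against genes
located between the centromere and the reporter locus.

Effect-size convention: ``effect`` is the log2 fold-change of reporter
expression when the regulator is knocked out.  An *activator* therefore
has ``effect < 0`` (its loss lowers the reporter, enriching its guides
in the low bin) and a *repressor* has ``effect > 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .counting import CountTable
from .library import CONTROL, SgRNALibrary
from .primers import PrimerSet, default_primers, default_sample_layout

__all__ = [
    "TrueNetwork",
    "ScreenConfig",
    "SimulatedScreen",
    "ReadSet",
    "genes_in_artifact_span",
    "make_genome",
    "make_library",
    "plant_truth",
    "simulate_screen",
    "emit_reads",
]


# ---------------------------------------------------------------------------
# genome


def make_genome(
    n_chromosomes: int,
    genes_per_chromosome: int,
    seed: int,
    slot_bp: int = 10_000,
    chrom_length: int | None = None,
    zero_inflation: float = 0.15,
) -> GenomeAnnotation:
    """Generate a toy genome annotation.

    Each chromosome carries ``genes_per_chromosome`` non-overlapping
    genes laid out in fixed-width slots, one centromere interval near
    the middle, and per-gene rpkm drawn from a mixture with a
    zero-inflated low tail (``zero_inflation`` fraction below rpkm 0.1),
    so that the transcriptional-inactivity filter has work to do.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    length = chrom_length or genes_per_chromosome * slot_bp
    if length // genes_per_chromosome < 2_000:
        raise ValueError(
            f"cannot pack {genes_per_chromosome} genes into {length} bp"
        )
    slot = length // genes_per_chromosome
    chrom_rows, gene_rows = [], []
    for c in range(1, n_chromosomes + 1):
        chrom = f"chr{c}"
        cen_mid = int(length * rng.uniform(0.35, 0.65))
        cen_half = max(1, int(length * 0.01))
        chrom_rows.append(
            {
                "chrom": chrom,
                "length": length,
                "cen_start": cen_mid - cen_half,
                "cen_end": cen_mid + cen_half,
            }
        )
        for g in range(genes_per_chromosome):
            lo = g * slot
            span = int(rng.integers(1_000, max(1_001, slot // 2)))
            start = lo + int(rng.integers(0, slot - span))
            if rng.random() < zero_inflation:
                rpkm = float(10 ** rng.uniform(-3.0, -1.0))  # below 0.1
            else:
                rpkm = float(2 ** rng.normal(4.0, 2.0))
            gene_rows.append(
                {
                    "gene": f"G{c:02d}_{g:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + span,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "rpkm": rpkm,
                }
            )
    return GenomeAnnotation(pd.DataFrame(chrom_rows), pd.DataFrame(gene_rows))


# ---------------------------------------------------------------------------
# library


def make_library(
    annotation: GenomeAnnotation,
    guides_per_gene: int = 4,
    n_controls: int = 100,
    seed: int = 0,
) -> SgRNALibrary:
    """Generate a Brunello-like library: ``guides_per_gene`` random 20-nt
    guides per annotated gene plus ``n_controls`` non-targeting controls,
    all sequences distinct."""
    if n_controls < 0:
        raise ValueError("n_controls must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(annotation.genes["gene"])
    n_seqs = len(genes) * guides_per_gene + n_controls
    seqs = _distinct_sequences(n_seqs, rng)
    rows = []
    k = 0
    for gene in genes:
        for j in range(1, guides_per_gene + 1):
            rows.append({"sgrna": f"{gene}_sg{j}", "sequence": seqs[k], "gene": gene})
            k += 1
    for j in range(1, n_controls + 1):
        rows.append({"sgrna": f"CTRL_{j:05d}", "sequence": seqs[k], "gene": CONTROL})
        k += 1
    return SgRNALibrary(pd.DataFrame(rows, columns=["sgrna", "sequence", "gene"]))


def _distinct_sequences(n: int, rng: np.random.Generator) -> list[str]:
    if n > 4**20 // 2:
        raise ValueError("sequence space exhausted")
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = alphabet[rng.integers(0, 4, size=((n - len(out)) + 16, 20))]
        for row in batch:
            s = row.tobytes().decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


# ---------------------------------------------------------------------------
# ground-truth regulatory effects


@dataclass
class TrueNetwork:
    """Planted regulator effects and artifact flags for one or more reporters.

    ``effects``: columns ``gene, reporter, effect`` — log2 fold-change of
    the reporter upon knockout (activator < 0 < repressor; absent = 0).
    ``artifacts``: columns ``gene, reporter, penetrance`` — fraction of
    cells with complete reporter loss when the gene is targeted.
    """

    effects: pd.DataFrame
    artifacts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "reporter", "penetrance"])
    )

    def effects_for(self, reporter: str) -> pd.Series:
        df = self.effects[self.effects["reporter"] == reporter]
        return df.set_index("gene")["effect"]

    def artifacts_for(self, reporter: str) -> pd.Series:
        df = self.artifacts[self.artifacts["reporter"] == reporter]
        return df.set_index("gene")["penetrance"]

    def labels_for(self, reporter: str) -> pd.Series:
        """Per-gene truth label: activator / repressor / artifact / null."""
        eff = self.effects_for(reporter)
        lab = pd.Series(
            np.where(eff < 0, "activator", np.where(eff > 0, "repressor", "null")),
            index=eff.index,
        )
        for g in self.artifacts_for(reporter).index:
            lab.loc[g] = "artifact"
        return lab

    def to_tsv(self, path: str | Path) -> None:
        eff = self.effects.assign(penetrance=np.nan, kind="effect")
        art = self.artifacts.assign(effect=np.nan, kind="artifact")
        pd.concat([eff, art], ignore_index=True)[
            ["kind", "gene", "reporter", "effect", "penetrance"]
        ].to_csv(path, sep="\t", index=False)


def plant_truth(
    annotation: GenomeAnnotation,
    reporter_gene: str,
    n_activators: int,
    n_repressors: int,
    effect_size: float = 2.0,
    n_artifacts: int = 0,
    artifact_penetrance: float = 0.6,
    seed: int = 0,
) -> TrueNetwork:
    """Plant regulators for one reporter, avoiding the artifact span.

    True activators/repressors are drawn only from genes *outside* the
    centromere-to-reporter span on the reporter chromosome; artifact
    genes are drawn from inside it.
    """
    rng = np.random.default_rng(seed)
    target = annotation.gene(reporter_gene)
    cen_start, cen_end = annotation.centromere(target["chrom"])
    span_lo, span_hi = _artifact_span(
        cen_start, cen_end, int(target["start"]), int(target["end"])
    )
    genes = annotation.genes
    on_chrom = genes["chrom"] == target["chrom"]
    in_span = on_chrom & (genes["start"] < span_hi) & (genes["end"] > span_lo)
    outside = genes.loc[~in_span & (genes["gene"] != reporter_gene), "gene"].to_numpy()
    inside = genes.loc[in_span & (genes["gene"] != reporter_gene), "gene"].to_numpy()

    n_reg = n_activators + n_repressors
    if n_reg > len(outside):
        raise ValueError("not enough out-of-span genes to plant regulators")
    if n_artifacts > len(inside):
        raise ValueError("not enough in-span genes to plant artifacts")
    regs = rng.choice(outside, size=n_reg, replace=False)
    effects = pd.DataFrame(
        {
            "gene": regs,
            "reporter": reporter_gene,
            "effect": [-effect_size] * n_activators + [effect_size] * n_repressors,
        }
    )
    arts = rng.choice(inside, size=n_artifacts, replace=False) if n_artifacts else []
    artifacts = pd.DataFrame(
        {
            "gene": list(arts),
            "reporter": [reporter_gene] * len(arts),
            "penetrance": [artifact_penetrance] * len(arts),
        }
    )
    return TrueNetwork(effects, artifacts)


def genes_in_artifact_span(
    annotation: GenomeAnnotation, reporter_gene: str
) -> list[str]:
    """Genes overlapping the centromere-to-reporter span (reporter excluded)."""
    target = annotation.gene(reporter_gene)
    cen_start, cen_end = annotation.centromere(target["chrom"])
    lo, hi = _artifact_span(cen_start, cen_end, int(target["start"]), int(target["end"]))
    genes = annotation.genes
    mask = (
        (genes["chrom"] == target["chrom"])
        & (genes["start"] < hi)
        & (genes["end"] > lo)
        & (genes["gene"] != reporter_gene)
    )
    return list(genes.loc[mask, "gene"])


def _artifact_span(cen_start, cen_end, gene_start, gene_end) -> tuple[int, int]:
    """Closed genomic span from the centromere edge nearest the target
    through the far end of the target gene."""
    if gene_start >= cen_end:  # target downstream of the centromere
        return cen_end, gene_end
    return gene_start, cen_start


# ---------------------------------------------------------------------------
# screen simulation


@dataclass
class ScreenConfig:
    """Simulation parameters for one screen.

    Defaults mirror the experimental design (six replicates, MOI 0.3,
    5% tails) at desk scale for sequencing depth and cell numbers.
    """

    replicates: int = 6
    moi: float = 0.3
    sort_fraction: float = 0.05
    cells_per_replicate: int = 1_000_000
    reads_per_bin: int = 200_000
    reporter_mu: float = 7.0  # natural-log scale of the log-normal baseline
    reporter_sigma: float = 0.6
    dirichlet_concentration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sort_fraction < 0.5:
            raise ValueError("sort_fraction must be in (0, 0.5)")
        if self.moi <= 0:
            raise ValueError("MOI must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class SimulatedScreen:
    """A simulated screen: per-(replicate, bin) counts plus ground truth."""

    counts: CountTable
    truth: TrueNetwork
    reporter_gene: str
    config: ScreenConfig
    guide_frequencies: pd.Series | None = None

    @property
    def truth_labels(self) -> pd.Series:
        return self.truth.labels_for(self.reporter_gene)


def simulate_screen(
    library: SgRNALibrary,
    truth: TrueNetwork,
    reporter_gene: str,
    config: ScreenConfig,
) -> SimulatedScreen:
    """Simulate sorted-bin sgRNA counts for one reporter screen.

    Cell model: each cell carries exactly one guide (low MOI makes
    multi-infection rare enough to neglect), drawn from
    Dirichlet-perturbed library frequencies shared across replicates.
    The reporter value is log-normal times ``2**effect`` of the guide's
    gene; artifact-gene cells lose the reporter entirely with the
    configured penetrance.  Per replicate the bottom and top
    ``sort_fraction`` tails are selected and each bin is sequenced as a
    multinomial draw of ``reads_per_bin`` reads over the sorted cells'
    guide composition.
    """
    rng = np.random.default_rng(config.seed)
    entries = library.entries
    n_guides = len(entries)

    eff = truth.effects_for(reporter_gene)
    if not np.isfinite(eff.to_numpy(dtype=float)).all():
        raise ValueError("effect sizes must be finite")
    guide_eff = entries["gene"].map(eff).fillna(0.0).to_numpy()
    pen = truth.artifacts_for(reporter_gene)
    guide_pen = entries["gene"].map(pen).fillna(0.0).to_numpy()

    # library representation: Dirichlet-perturbed frequencies, one draw per
    # screen (the plasmid pool is shared by all replicates)
    alpha = config.dirichlet_concentration * rng.uniform(0.0, 1.0, size=n_guides)
    alpha = np.clip(alpha, 1e-3, None)
    freqs = rng.dirichlet(alpha)

    n_cells = config.cells_per_replicate
    k = int(np.floor(config.sort_fraction * n_cells))
    if 2 * k < 10 * n_guides:
        warnings.warn(
            f"sorted cells per replicate ({2 * k}) below 10x library size "
            f"({10 * n_guides}): expect representation loss",
            stacklevel=2,
        )

    matrix = {}
    for rep in range(1, config.replicates + 1):
        cells_per_guide = rng.multinomial(n_cells, freqs)
        guide_idx = np.repeat(np.arange(n_guides), cells_per_guide)
        log_rep = rng.normal(config.reporter_mu, config.reporter_sigma, size=n_cells)
        reporter = np.exp(log_rep) * np.exp2(guide_eff[guide_idx])
        lost = rng.random(n_cells) < guide_pen[guide_idx]
        reporter[lost] = 0.0
        # random tie-break among artifact zeros, far below any real signal
        reporter = reporter + rng.random(n_cells) * 1e-9

        order = np.argsort(reporter, kind="stable")
        low_cells, high_cells = guide_idx[order[:k]], guide_idx[order[-k:]]
        for bin_name, cells in (("low", low_cells), ("high", high_cells)):
            comp = np.bincount(cells, minlength=n_guides).astype(float)
            comp /= comp.sum()
            matrix[f"rep{rep}_{bin_name}"] = rng.multinomial(
                config.reads_per_bin, comp
            )

    wide = pd.DataFrame(matrix, index=pd.Index(entries["sgrna"], name="sgrna"))
    counts = CountTable.from_matrix(wide, library)
    return SimulatedScreen(
        counts,
        truth,
        reporter_gene,
        config,
        guide_frequencies=pd.Series(freqs, index=entries["sgrna"]),
    )


# ---------------------------------------------------------------------------
# read emission


@dataclass
class ReadSet:
    """Synthetic single-end reads as (name, sequence) pairs."""

    reads: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.reads)

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        from Bio import SeqIO

        reads = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]
        return cls(reads)


def emit_reads(
    screen: SimulatedScreen | CountTable,
    library: SgRNALibrary,
    primers: PrimerSet | None = None,
    seed: int = 0,
    read_length: int = 75,
    layout: dict[str, str] | None = None,
) -> ReadSet:
    """Turn a count table into the FASTQ reads that would produce it.

    Each read is ``stagger + index + Template1 + sgRNA + Template2``
    truncated to ``read_length``; read counts match the count table
    exactly.  ``layout`` maps primer name -> sample name (default: the
    standard six-replicate low/high pooling scheme, falling back to
    primer-named samples).
    """
    primers = primers or default_primers()
    counts = screen.counts if isinstance(screen, SimulatedScreen) else screen
    matrix = counts.to_matrix()
    samples = list(matrix.columns)
    if layout is None:
        std = default_sample_layout(6)
        if set(samples) <= set(std.values()):
            layout = {p: s for p, s in std.items() if s in samples}
        else:
            layout = {s: s for s in samples if s in primers.names}
    if set(samples) - set(layout.values()):
        missing = sorted(set(samples) - set(layout.values()))
        raise ValueError(f"no primer assigned for samples: {missing}")

    seq_of = library.entries.set_index("sgrna")["sequence"]
    t1 = primers.template1
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for primer_name, sample in layout.items():
        primer = primers.get(primer_name)
        if read_length < len(primer.stagger) + 8 + len(t1) + 20:
            raise ValueError(
                f"read length {read_length} too short for primer {primer_name}"
            )
        prefix = primer.prefix + t1
        col = matrix[sample]
        i = 0
        for sgrna, n in col[col > 0].items():
            full = (prefix + seq_of[sgrna] + primers.template2)[:read_length]
            for _ in range(int(n)):
                reads.append((f"{sample}:{sgrna}:{i}", full))
                i += 1
    # shuffle to mimic a lane
    order = rng.permutation(len(reads))
    return ReadSet([reads[i] for i in order])
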