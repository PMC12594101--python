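"""End-to-end orchestration: config-driven pipeline and synthetic fixtures.

``run_pipeline`` executes count -> score -> filter per screen, then
assembles the cross-screen network and co-regulation outputs, writing a
manifest of input/output hashes so a rerun with the same config is
bit-identical.  ``make_fixture`` writes a self-contained synthetic
dataset (annotation, library, truth, per-screen counts, config) that
the pipeline can run directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .annotation import GenomeAnnotation
from .counting import CountTable, build_reference, count_reads
from .coregulation import cluster_screens, overlap_matrices
from .filtering import (
    FilterConfig,
    HitTable,
    apply_rra_cutoff,
    filter_centromere_interval,
    filter_inactive,
)
from .library import SgRNALibrary
from .network import build_network, classify_regulators, export_network
from .primers import default_primers, default_sample_layout
from .scoring import RraConfig, default_design, export_scores, gene_rra, normalize, sgrna_scores
from .simulate import (
    ScreenConfig,
    emit_reads,
    genes_in_artifact_span,
    make_genome,
    make_library,
    plant_truth,
    simulate_screen,
)

__all__ = ["ScreenInput", "PipelineConfig", "run_pipeline", "make_fixture"]


@dataclass
class ScreenInput:
    name: str
    target_gene: str
    counts: str | None = None  # TSV count table
    reads: str | None = None  # FASTQ (counted at run time)
    max_mismatch: int = 2


@dataclass
class PipelineConfig:
    library: str
    chromosomes: str
    genes: str
    outdir: str
    screens: list[ScreenInput]
    expression: str | None = None  # TSV gene/rpkm; defaults to annotation rpkm
    rra: RraConfig = field(default_factory=RraConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p):
            return str(base / p) if p and not Path(p).is_absolute() else p

        screens = [
            ScreenInput(
                name=s["name"],
                target_gene=s["target_gene"],
                counts=resolve(s.get("counts")),
                reads=resolve(s.get("reads")),
                max_mismatch=int(s.get("max_mismatch", 2)),
            )
            for s in raw["screens"]
        ]
        return cls(
            library=resolve(raw["library"]),
            chromosomes=resolve(raw["chromosomes"]),
            genes=resolve(raw["genes"]),
            expression=resolve(raw.get("expression")),
            outdir=resolve(raw["outdir"]),
            screens=screens,
            rra=RraConfig(seed=raw.get("seed", 0), **raw.get("rra", {})),
            filter=FilterConfig(**raw.get("filter", {})),
            seed=int(raw.get("seed", 0)),
        )

    def validate_paths(self) -> None:
        missing = []
        for p in [self.library, self.chromosomes, self.genes, self.expression]:
            if p and not Path(p).exists():
                missing.append(p)
        for s in self.screens:
            src = s.counts or s.reads
            if src is None:
                missing.append(f"{s.name}: no counts or reads")
            elif not Path(src).exists():
                missing.append(src)
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a manifest of stage outputs.

    Raises with the failing stage's name on error; validates every input
    path before any compute.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load_inputs"
    try:
        library = SgRNALibrary.from_tsv(config.library)
        annotation = GenomeAnnotation.from_tsv(config.chromosomes, config.genes)
        if config.expression:
            expression = pd.read_csv(config.expression, sep="\t").set_index("gene")["rpkm"]
        else:
            expression = annotation.rpkm

        hit_tables: dict[str, HitTable] = {}
        outputs: dict[str, str] = {}
        for screen in config.screens:
            stage = f"count[{screen.name}]"
            if screen.counts:
                table = CountTable.from_tsv(screen.counts)
            else:
                reference = build_reference(library, default_primers())
                table = count_reads(
                    screen.reads,
                    reference,
                    max_mismatch=screen.max_mismatch,
                    layout=default_sample_layout(),
                )
                counts_path = outdir / f"{screen.name}.counts.tsv"
                table.to_tsv(counts_path)
                outputs[f"{screen.name}.counts"] = str(counts_path)

            stage = f"score[{screen.name}]"
            norm = normalize(table)
            guides = sgrna_scores(norm, default_design(table))
            genes = gene_rra(guides, library, config.rra)
            scores_path = outdir / f"{screen.name}.gene_scores.tsv"
            export_scores(genes, scores_path)
            outputs[f"{screen.name}.gene_scores"] = str(scores_path)

            stage = f"filter[{screen.name}]"
            hits = apply_rra_cutoff(genes, config.filter, screen=screen.name)
            hits = filter_centromere_interval(hits, annotation, screen.target_gene)
            hits = filter_inactive(hits, expression, config.filter.min_rpkm)
            hits_path = outdir / f"{screen.name}.hits.tsv"
            removed_path = outdir / f"{screen.name}.removed.tsv"
            hits.to_tsv(hits_path, removed_path)
            outputs[f"{screen.name}.hits"] = str(hits_path)
            outputs[f"{screen.name}.removed"] = str(removed_path)
            hit_tables[screen.name] = hits

        stage = "network"
        network = build_network(hit_tables)
        export_network(network, outdir / "network.tsv", "tsv")
        export_network(network, outdir / "network.sif", "sif")
        outputs["network"] = str(outdir / "network.tsv")
        classes = classify_regulators(network)
        classes.to_csv(outdir / "regulator_classes.tsv", sep="\t", index=False)
        outputs["regulator_classes"] = str(outdir / "regulator_classes.tsv")
        summary = network.summary()
        summary["regulator_classes"] = (
            classes["class"].value_counts().to_dict() if len(classes) else {}
        )

        stage = "coregulation"
        if len(hit_tables) >= 2:
            matrices = overlap_matrices(hit_tables)
            matrices.to_tsv(outdir / "overlap")
            outputs["overlap"] = str(outdir / "overlap.activator_overlap.tsv")
            if len(hit_tables) >= 3:
                assignment = cluster_screens(matrices)
                assignment.to_tsv(outdir / "screen_groups.tsv")
                outputs["screen_groups"] = str(outdir / "screen_groups.tsv")
                sil = assignment.silhouette
                summary["silhouette"] = None if sil != sil else sil

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "inputs": {
                p: _sha256(p)
                for p in [config.library, config.chromosomes, config.genes]
                + ([config.expression] if config.expression else [])
                + [s.counts or s.reads for s in config.screens]
            },
            "outputs": {k: _sha256(v) for k, v in outputs.items()},
            "summary": summary,
            "rra": asdict(config.rra),
            "filter": asdict(config.filter),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


_FIXTURE_SIZES = {
    "tiny": dict(
        n_chromosomes=2, genes_per_chromosome=25, guides_per_gene=4,
        n_controls=20, replicates=3, cells_per_replicate=40_000,
        reads_per_bin=40_000, n_permutations=1000,
    ),
    "desk": dict(
        n_chromosomes=4, genes_per_chromosome=500, guides_per_gene=4,
        n_controls=100, replicates=6, cells_per_replicate=1_000_000,
        reads_per_bin=200_000, n_permutations=10_000,
    ),
}


def make_fixture(
    size: str,
    seed: int,
    outdir: str | Path,
    n_screens: int = 3,
    with_reads: bool = False,
) -> PipelineConfig:
    """Write a synthetic dataset plus a ready-to-run pipeline config.

    ``tiny`` is a 50-gene, 3-replicate dataset for fast smoke tests;
    ``desk`` is a 2,000-gene, 6-replicate dataset matching the
    simulator's default study conditions.  Each screen's reporter gene
    is drawn from the annotation and planted with true activators,
    repressors and centromere-proximal artifact genes; the truth table
    is written alongside.
    """
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size: {size}")
    params = _FIXTURE_SIZES[size]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotation = make_genome(
        params["n_chromosomes"], params["genes_per_chromosome"], seed=seed
    )
    library = make_library(
        annotation, params["guides_per_gene"], params["n_controls"], seed=seed + 1
    )
    annotation.to_tsv(outdir / "chromosomes.tsv", outdir / "genes.tsv")
    library.to_tsv(outdir / "library.tsv")

    n_genes = len(annotation.genes)
    n_reg = max(2, n_genes // 50)
    screens = []
    truth_frames = []
    genes_by_rpkm = annotation.genes.sort_values("rpkm", ascending=False)
    reporters = list(genes_by_rpkm["gene"].iloc[:n_screens])
    for i, reporter in enumerate(reporters):
        truth = plant_truth(
            annotation,
            reporter,
            n_activators=n_reg,
            n_repressors=n_reg,
            effect_size=2.0,
            n_artifacts=min(
                2, n_genes // 25, len(genes_in_artifact_span(annotation, reporter))
            ),
            seed=seed + 10 + i,
        )
        cfg = ScreenConfig(
            replicates=params["replicates"],
            cells_per_replicate=params["cells_per_replicate"],
            reads_per_bin=params["reads_per_bin"],
            seed=seed + 100 + i,
        )
        sim = simulate_screen(library, truth, reporter, cfg)
        counts_path = outdir / f"{reporter}.counts.tsv"
        sim.counts.to_tsv(counts_path)
        truth_frames.append(
            truth.effects.assign(kind="effect").merge(
                truth.artifacts.assign(kind="artifact"), how="outer"
            )
        )
        entry = {"name": reporter, "target_gene": reporter, "counts": counts_path.name}
        if with_reads:
            reads = emit_reads(sim, library, default_primers(), seed=seed + 200 + i)
            reads_path = outdir / f"{reporter}.reads.fastq"
            reads.to_fastq(reads_path)
            entry["reads"] = reads_path.name
        screens.append(entry)

    pd.concat(truth_frames, ignore_index=True).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    config_raw = {
        "library": "library.tsv",
        "chromosomes": "chromosomes.tsv",
        "genes": "genes.tsv",
        "outdir": "out",
        "seed": seed,
        "rra": {"n_permutations": params["n_permutations"]},
        "screens": screens,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config_raw, fh, sort_keys=False)
    return PipelineConfig.from_yaml(outdir / "config.yaml")
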