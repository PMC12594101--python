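import numpy as np
import pandas as pd
import pytest

import reporterscreen as rs


@pytest.fixture(scope="session")
def annotation():
    return rs.make_genome(2, 50, seed=11)


@pytest.fixture(scope="session")
def library(annotation):
    return rs.make_library(annotation, guides_per_gene=4, n_controls=20, seed=12)


@pytest.fixture(scope="session")
def reporter(annotation):
    # a well-expressed gene downstream of the chr1 centromere
    genes = annotation.genes
    cen_start, cen_end = annotation.centromere("chr1")
    cand = genes[(genes["chrom"] == "chr1") & (genes["start"] >= cen_end)]
    cand = cand[cand["rpkm"] >= 1.0]
    return cand.iloc[len(cand) // 2]["gene"]


@pytest.fixture(scope="session")
def truth(annotation, reporter):
    return rs.plant_truth(
        annotation,
        reporter,
        n_activators=4,
        n_repressors=4,
        effect_size=2.0,
        n_artifacts=2,
        artifact_penetrance=0.6,
        seed=13,
    )


@pytest.fixture(scope="session")
def screen(library, truth, reporter):
    cfg = rs.ScreenConfig(
        replicates=3, cells_per_replicate=60_000, reads_per_bin=60_000, seed=14
    )
    return rs.simulate_screen(library, truth, reporter, cfg)


@pytest.fixture(scope="session")
def guide_scores(screen):
    norm = rs.normalize(screen.counts)
    return rs.sgrna_scores(norm, rs.default_design(screen.counts))


@pytest.fixture(scope="session")
def gene_scores(guide_scores, library):
    return rs.gene_rra(
        guide_scores, library, rs.RraConfig(n_permutations=1000, seed=15)
    )


def make_hit_table(screen_name, activators=(), repressors=(), score=1e-4):
    """Hand-built hit table for network / co-regulation tests."""
    rows = [
        {"screen": screen_name, "gene": g, "sense": "activator", "score": score, "fdr": 0.01}
        for g in activators
    ] + [
        {"screen": screen_name, "gene": g, "sense": "repressor", "score": score, "fdr": 0.01}
        for g in repressors
    ]
    return rs.HitTable(
        pd.DataFrame(rows, columns=["screen", "gene", "sense", "score", "fdr"])
    )


@pytest.fixture
def hit_table_factory():
    return make_hit_table
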