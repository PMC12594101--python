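"""Normalization, per-guide statistics and alpha-RRA gene scoring."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import reporterscreen as rs
from reporterscreen.library import CONTROL
from reporterscreen.scoring import _rho


def table_from(matrix, genes):
    lib = rs.SgRNALibrary(
        pd.DataFrame(
            {
                "sgrna": matrix.index,
                "sequence": _seqs(len(matrix)),
                "gene": genes,
            }
        )
    )
    return rs.CountTable.from_matrix(matrix, lib), lib


def _seqs(n):
    rng = np.random.default_rng(0)
    out = set()
    while len(out) < n:
        out.add("".join(rng.choice(list("ACGT"), 20)))
    return sorted(out)


class TestNormalize:
    def test_identical_samples_equal_factors(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 100, 200)
        matrix = pd.DataFrame(
            {"a": counts, "b": counts},
            index=pd.Index([f"g{i}" for i in range(200)], name="sgrna"),
        )
        table, _ = table_from(matrix, ["X"] * 200)
        norm = rs.normalize(table)
        assert norm.size_factors["a"] == pytest.approx(norm.size_factors["b"])
        assert np.allclose(norm.matrix["a"], norm.matrix["b"])

    def test_doubled_sample_scale_equivariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 100, 200)
        matrix = pd.DataFrame(
            {"a": counts, "b": 2 * counts},
            index=pd.Index([f"g{i}" for i in range(200)], name="sgrna"),
        )
        table, _ = table_from(matrix, ["X"] * 200)
        norm = rs.normalize(table)
        ratio = norm.size_factors["b"] / norm.size_factors["a"]
        assert ratio == pytest.approx(2.0)
        assert np.allclose(norm.matrix["a"], norm.matrix["b"])

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(
            rng.integers(1, 500, (150, 4)),
            index=pd.Index([f"g{i}" for i in range(150)], name="sgrna"),
            columns=["s1", "s2", "s3", "s4"],
        )
        table, _ = table_from(matrix, ["X"] * 150)
        norm = rs.normalize(table)
        # independent oracle: plain python median-of-ratios
        arr = matrix.to_numpy(dtype=float)
        geo = np.array([float(np.prod(row)) ** (1 / 4) for row in arr])
        for j, col in enumerate(matrix.columns):
            ratios = sorted(arr[i, j] / geo[i] for i in range(len(arr)))
            n = len(ratios)
            med = (ratios[n // 2] if n % 2 else (ratios[n // 2 - 1] + ratios[n // 2]) / 2)
            assert norm.size_factors[col] == pytest.approx(med)
        assert norm.method == "median_ratio"

    def test_fallback_to_totals_when_few_common_guides(self):
        matrix = pd.DataFrame(
            {"a": [10, 0, 5], "b": [0, 10, 5]},
            index=pd.Index(["g0", "g1", "g2"], name="sgrna"),
        )
        table, _ = table_from(matrix, ["X"] * 3)
        norm = rs.normalize(table)
        assert norm.method == "total"

    def test_zero_total_sample_rejected(self):
        matrix = pd.DataFrame(
            {"a": [10, 10], "b": [0, 0]},
            index=pd.Index(["g0", "g1"], name="sgrna"),
        )
        table, _ = table_from(matrix, ["X"] * 2)
        with pytest.raises(ValueError, match="zero total"):
            rs.normalize(table)


def scores_table(scores, genes, n_controls=0):
    """Build a guide-score frame directly for rank/p tests."""
    n = len(scores)
    matrix = pd.DataFrame(
        {"low": np.ones(n), "high": np.ones(n)},
        index=pd.Index([f"g{i}" for i in range(n)], name="sgrna"),
    )
    table, lib = table_from(matrix, genes)
    return table, lib


class TestSgrnaScores:
    def _norm(self, low, high, genes):
        n = len(low)
        matrix = pd.DataFrame(
            {"rep1_low": low, "rep1_high": high},
            index=pd.Index([f"g{i}" for i in range(n)], name="sgrna"),
        )
        table, lib = table_from(matrix, genes)
        norm = rs.normalize(table, min_common=10**9)  # force total scaling
        return table, norm

    def test_identical_low_high_score_zero(self):
        genes = ["X", "Y", CONTROL, CONTROL]
        table, norm = self._norm([10, 20, 30, 40], [10, 20, 30, 40], genes)
        scores = rs.sgrna_scores(norm, rs.default_design(table))
        assert np.allclose(scores["score"], 0.0)

    def test_top_low_enriched_guide_has_rank_one_over_n(self):
        genes = ["X", "Y", CONTROL, CONTROL]
        table, norm = self._norm([100, 20, 30, 40], [10, 20, 30, 40], genes)
        scores = rs.sgrna_scores(norm, rs.default_design(table)).set_index("sgrna")
        assert scores.loc["g0", "pos_rank"] == pytest.approx(1 / 4)
        assert scores.loc["g0", "neg_rank"] == pytest.approx(1.0)

    def test_control_at_median_has_empirical_p_half(self):
        # 1,001 controls with strictly increasing scores
        n = 1001
        low = np.linspace(1, 2, n) * 1000
        high = np.full(n, 1000.0)
        table, norm = self._norm(low, high, [CONTROL] * n)
        scores = rs.sgrna_scores(norm, rs.default_design(table))
        median_guide = scores.sort_values("score").iloc[n // 2]
        # (1 + #{controls >= median}) / (1 + n) with 501 controls >= median
        assert median_guide["pos_p"] == pytest.approx((1 + 501) / (1 + 1001))

    def test_no_controls_rejected(self):
        table, norm = self._norm([1, 2], [1, 2], ["X", "Y"])
        with pytest.raises(ValueError, match="control"):
            rs.sgrna_scores(norm, rs.default_design(table))


def toy_guide_frame(ranks, pvals, genes):
    """Direct guide-score frame bypassing count simulation."""
    n = len(ranks)
    return pd.DataFrame(
        {
            "sgrna": [f"g{i}" for i in range(n)],
            "gene": genes,
            "score": -np.asarray(ranks),
            "pos_p": pvals,
            "neg_p": 1.0 - np.asarray(pvals) + 1e-9,
            "pos_rank": ranks,
            "neg_rank": 1.0 - np.asarray(ranks) + min(ranks),
        }
    )


def oracle_rho_two_guides(r1, r2, n_selected):
    """Closed-form rho for m=2: Beta(1,2) and Beta(2,1) order statistics."""
    lo, hi = min(r1, r2), max(r1, r2)
    cdf1 = 1 - (1 - lo) ** 2  # P(min of 2 uniforms <= lo)
    cdf2 = hi**2  # P(max of 2 uniforms <= hi)
    if n_selected == 0:
        return 1.0
    if n_selected == 1:
        return min(1.0, cdf1)
    return min(1.0, cdf1, cdf2)


class TestGeneRra:
    def test_single_selected_guide_rho_equals_rank(self):
        frame = toy_guide_frame([0.2, 0.9], [0.01, 0.9], ["X", "Y"])
        lib = None
        out = rs.gene_rra(frame, lib, rs.RraConfig(n_permutations=100, seed=1))
        row = out.set_index("gene").loc["X"]
        assert row["pos_score"] == pytest.approx(0.2)  # Beta(1,1) CDF identity
        assert row["pos_good"] == 1

    def test_no_selected_guides_gives_rho_one_p_one(self):
        frame = toy_guide_frame([0.5, 0.6], [0.5, 0.6], ["X", "X"])
        out = rs.gene_rra(frame, None, rs.RraConfig(n_permutations=100, seed=1))
        row = out.set_index("gene").loc["X"]
        assert row["pos_score"] == 1.0
        assert row["pos_p"] == 1.0

    def test_exhaustive_matches_brute_force_enumeration(self):
        """3 genes x 2 guides: rho and exhaustive-permutation p vs an
        independent itertools enumeration with closed-form beta CDFs."""
        ranks = np.array([1, 2, 3, 4, 5, 6]) / 6
        pvals = np.array([0.01, 0.02, 0.04, 0.3, 0.6, 0.9])
        genes = ["A", "A", "B", "B", "C", "C"]
        frame = toy_guide_frame(ranks, pvals, genes)
        out = rs.gene_rra(
            frame, None, rs.RraConfig(alpha=0.05, n_permutations=100, seed=1),
            exhaustive=True,
        ).set_index("gene")

        # oracle: enumerate all C(6,2) guide pairs once
        null = []
        for i, j in combinations(range(6), 2):
            s = int(pvals[i] < 0.05) + int(pvals[j] < 0.05)
            null.append(oracle_rho_two_guides(ranks[i], ranks[j], s))
        for gene, idx in (("A", (0, 1)), ("B", (2, 3)), ("C", (4, 5))):
            s = int(pvals[idx[0]] < 0.05) + int(pvals[idx[1]] < 0.05)
            rho = oracle_rho_two_guides(ranks[idx[0]], ranks[idx[1]], s)
            p = sum(x <= rho for x in null) / len(null)
            assert out.loc[gene, "pos_score"] == pytest.approx(rho)
            assert out.loc[gene, "pos_p"] == pytest.approx(p)

    def test_permutation_p_lower_bound(self):
        frame = toy_guide_frame(
            [0.001, 0.002, 0.9, 0.95], [0.001, 0.002, 0.9, 0.95],
            ["X", "X", "Y", "Y"],
        )
        cfg = rs.RraConfig(n_permutations=200, seed=3)
        out = rs.gene_rra(frame, None, cfg)
        assert (out["pos_p"] >= 1 / (cfg.n_permutations + 1) - 1e-12).all()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ranks=st.lists(
            st.floats(0.01, 1.0), min_size=3, max_size=6, unique=True
        ),
        improve=st.integers(0, 5),
    )
    def test_rho_monotone_in_selected_rank(self, ranks, improve):
        """Improving any selected guide's rank never increases rho."""
        m = len(ranks)
        r = np.sort(ranks)
        sel = m  # all selected
        rho_before = _rho(r[None, :], np.array([sel]))[0]
        i = improve % m
        r2 = r.copy()
        r2[i] = r2[i] / 2
        r2 = np.sort(r2)
        rho_after = _rho(r2[None, :], np.array([sel]))[0]
        assert rho_after <= rho_before + 1e-12

    def test_empty_scores_give_empty_output(self):
        frame = toy_guide_frame([0.5], [0.5], [CONTROL])
        out = rs.gene_rra(frame, None, rs.RraConfig(n_permutations=100, seed=1))
        assert len(out) == 0


class TestNullCalibration:
    def test_null_gene_p_values_conservative(self, library):
        """All-null screen: the empirical CDF of gene p-values never
        exceeds the nominal level by more than sampling noise (the
        alpha-selection step makes the null conservative, not uniform)."""
        truth = rs.TrueNetwork(pd.DataFrame(columns=["gene", "reporter", "effect"]))
        cfg = rs.ScreenConfig(
            replicates=3, cells_per_replicate=60_000, reads_per_bin=60_000, seed=42
        )
        sim = rs.simulate_screen(library, truth, "G01_0000", cfg)
        norm = rs.normalize(sim.counts)
        gs = rs.gene_rra(
            rs.sgrna_scores(norm, rs.default_design(sim.counts)),
            library,
            rs.RraConfig(n_permutations=1000, seed=7),
        )
        n = len(gs)
        for level in (0.001, 0.01, 0.05, 0.1):
            for col in ("pos_p", "neg_p"):
                frac = float((gs[col] < level).mean())
                # binomial slack: 3 sigma above the nominal level
                slack = 3 * np.sqrt(level * (1 - level) / n)
                assert frac <= level + slack + 1e-9


class TestExport:
    def test_round_trip_and_column_order(self, gene_scores, tmp_path):
        path = tmp_path / "scores.tsv"
        rs.export_scores(gene_scores, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == [
            "gene", "pos.score", "neg.score", "pos.fdr", "neg.fdr",
            "pos.goodsgrna", "neg.goodsgrna",
        ]
        back = rs.read_scores(path)
        merged = back.merge(gene_scores, on="gene", suffixes=("_rt", ""))
        assert np.allclose(merged["pos_score_rt"], merged["pos_score"])
        # sorted by min(pos, neg)
        mins = np.minimum(back["pos_score"], back["neg_score"])
        assert (np.diff(mins) >= -1e-12).all()

    def test_empty_table_writes_header_only(self, tmp_path):
        empty = rs.gene_rra(
            toy_guide_frame([0.5], [0.5], [CONTROL]), None,
            rs.RraConfig(n_permutations=100, seed=1),
        )
        path = tmp_path / "empty.tsv"
        rs.export_scores(empty, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
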