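"""Cross-screen overlap matrices, group clustering, co-regulation queries."""

import numpy as np
import pandas as pd
import pytest

import reporterscreen as rs


def planted_two_block(
    n_per_block=6, shared=40, private=15, noise=0.0, seed=0
):
    """Two screen blocks: block A shares a pool of activators, block B a
    pool of repressors.  ``noise`` swaps that fraction of each screen's
    shared hits for random private genes."""
    rng = np.random.default_rng(seed)
    shared_act = [f"SA{i}" for i in range(shared * 2)]
    shared_rep = [f"SR{i}" for i in range(shared * 2)]
    tables = {}
    for block, pool, sense_shared in (("A", shared_act, "activator"),
                                      ("B", shared_rep, "repressor")):
        other = "repressor" if sense_shared == "activator" else "activator"
        for k in range(n_per_block):
            name = f"{block}{k}"
            core = list(rng.choice(pool, shared, replace=False))
            n_swap = int(noise * shared)
            if n_swap:
                keep = core[:-n_swap]
                swapped = [f"{name}_noise{i}" for i in range(n_swap)]
                core = keep + swapped
            rows = [
                {"screen": name, "gene": g, "sense": sense_shared,
                 "score": 1e-4, "fdr": 0.01}
                for g in core
            ] + [
                {"screen": name, "gene": f"{name}_priv{i}", "sense": other,
                 "score": 1e-4, "fdr": 0.01}
                for i in range(private)
            ]
            tables[name] = rs.HitTable(pd.DataFrame(rows))
    return tables


class TestOverlapMatrices:
    def test_identical_screens(self, hit_table_factory):
        t1 = hit_table_factory("S1", activators=["A", "B", "C"])
        t2 = hit_table_factory("S2", activators=["A", "B", "C"])
        m = rs.overlap_matrices({"S1": t1, "S2": t2})
        assert m.activator.loc["S1", "S2"] == 3
        assert m.activator.loc["S1", "S1"] == 3
        assert m.activator_jaccard.loc["S1", "S2"] == 1.0

    def test_disjoint_screens(self, hit_table_factory):
        t1 = hit_table_factory("S1", activators=["A"])
        t2 = hit_table_factory("S2", activators=["B"])
        m = rs.overlap_matrices({"S1": t1, "S2": t2})
        assert m.activator.loc["S1", "S2"] == 0
        assert m.activator_jaccard.loc["S1", "S2"] == 0.0

    def test_symmetry_and_bounds(self):
        tables = planted_two_block(seed=3)
        m = rs.overlap_matrices(tables)
        for mat in (m.activator, m.repressor):
            arr = mat.to_numpy()
            assert (arr == arr.T).all()
            diag = np.diag(arr)
            off = arr - np.diag(diag)
            assert (off <= np.minimum.outer(diag, diag)).all()
        assert ((m.activator_jaccard.to_numpy() >= 0)
                & (m.activator_jaccard.to_numpy() <= 1)).all()

    def test_matches_incidence_matrix_product(self):
        """Overlap via set intersection equals the incidence-matrix product."""
        tables = planted_two_block(seed=4)
        m = rs.overlap_matrices(tables)
        genes = sorted(
            {g for t in tables.values() for g in t.genes("activator")}
        )
        screens = list(tables)
        incidence = np.array(
            [[g in tables[s].genes("activator") for g in genes] for s in screens],
            dtype=int,
        )
        product = incidence @ incidence.T
        assert (m.activator.loc[screens, screens].to_numpy() == product).all()

    def test_single_screen_rejected(self, hit_table_factory):
        with pytest.raises(ValueError):
            rs.overlap_matrices({"S1": hit_table_factory("S1", activators=["A"])})


class TestClusterScreens:
    def test_planted_partition_recovered_exactly(self):
        tables = planted_two_block(seed=5)
        m = rs.overlap_matrices(tables)
        assignment = rs.cluster_screens(m)
        groups = assignment.groups
        # block A shares activators -> group 1; block B -> group 2
        assert all(groups[f"A{k}"] == 1 for k in range(6))
        assert all(groups[f"B{k}"] == 2 for k in range(6))
        assert assignment.silhouette > 0.0

    def test_robust_to_ten_percent_label_noise(self):
        tables = planted_two_block(noise=0.1, seed=6)
        m = rs.overlap_matrices(tables)
        groups = rs.cluster_screens(m).groups
        truth = pd.Series(
            {f"A{k}": 1 for k in range(6)} | {f"B{k}": 2 for k in range(6)}
        )
        agreement = (groups[truth.index] == truth).mean()
        assert max(agreement, 1 - agreement) >= 0.9

    def test_permutation_invariance(self):
        tables = planted_two_block(seed=7)
        m1 = rs.overlap_matrices(tables)
        shuffled = dict(reversed(list(tables.items())))
        m2 = rs.overlap_matrices(shuffled)
        g1 = rs.cluster_screens(m1).groups.sort_index()
        g2 = rs.cluster_screens(m2).groups.sort_index()
        # same partition, up to group-label semantics which are fixed
        assert g1.equals(g2)

    def test_identical_screens_unassigned(self, hit_table_factory):
        tables = {
            f"S{i}": hit_table_factory(f"S{i}", activators=["A", "B"])
            for i in range(4)
        }
        assignment = rs.cluster_screens(rs.overlap_matrices(tables))
        assert (assignment.groups == "unassigned").all()

    def test_too_few_screens_rejected(self, hit_table_factory):
        tables = {
            "S1": hit_table_factory("S1", activators=["A"]),
            "S2": hit_table_factory("S2", activators=["B"]),
        }
        with pytest.raises(ValueError):
            rs.cluster_screens(rs.overlap_matrices(tables))


class TestHeatmap:
    def test_writes_figure_in_cluster_order(self, tmp_path):
        tables = planted_two_block(seed=12)
        m = rs.overlap_matrices(tables)
        assignment = rs.cluster_screens(m)
        path = tmp_path / "overlap.png"
        rs.plot_overlap_heatmap(m, path, assignment)
        assert path.stat().st_size > 0


class TestSharedRegulators:
    def test_identical_sets(self, hit_table_factory):
        genes = ["A", "B", "C", "D", "E"]
        tables = {
            "S1": hit_table_factory("S1", repressors=genes),
            "S2": hit_table_factory("S2", repressors=genes),
        }
        common, regions = rs.shared_regulators(tables, ["S1", "S2"], "repressor")
        assert len(common) == 5
        assert regions[frozenset({"S1", "S2"})] == 5

    def test_one_empty_screen_empties_intersection(self, hit_table_factory):
        tables = {
            "S1": hit_table_factory("S1", activators=["A"]),
            "S2": hit_table_factory("S2", activators=["A"]),
            "S3": hit_table_factory("S3", activators=["A"]),
            "S4": hit_table_factory("S4"),
        }
        common, _ = rs.shared_regulators(tables, ["S1", "S2", "S3", "S4"], "activator")
        assert common == set()

    def test_region_counts_sum_to_union(self, hit_table_factory):
        tables = {
            "S1": hit_table_factory("S1", activators=["A", "B", "C"]),
            "S2": hit_table_factory("S2", activators=["B", "C", "D"]),
            "S3": hit_table_factory("S3", activators=["C", "D", "E"]),
        }
        _, regions = rs.shared_regulators(tables, ["S1", "S2", "S3"], "activator")
        union = {"A", "B", "C", "D", "E"}
        assert sum(regions.values()) == len(union)

    def test_unknown_screen_rejected(self, hit_table_factory):
        tables = {"S1": hit_table_factory("S1", activators=["A"])}
        with pytest.raises(KeyError):
            rs.shared_regulators(tables, ["S1", "S9"], "activator")

    def test_screen_count_bounds(self, hit_table_factory):
        tables = {f"S{i}": hit_table_factory(f"S{i}") for i in range(6)}
        with pytest.raises(ValueError):
            rs.shared_regulators(tables, ["S0"], "activator")
        with pytest.raises(ValueError):
            rs.shared_regulators(tables, [f"S{i}" for i in range(5)], "activator")


class TestConditionSpecific:
    def test_same_hits_give_empty_specific_set(self, hit_table_factory):
        t = hit_table_factory("S1", activators=["A", "B"])
        common, specific = rs.condition_specific_regulators({"S1": t}, {"S1u": t})
        assert common == {"A", "B"} and specific == set()

    def test_treated_only_regulator_detected(self, hit_table_factory):
        treated = {
            f"T{i}": hit_table_factory(f"T{i}", activators=["RAPA", f"X{i}"])
            for i in range(3)
        }
        untreated = {
            f"U{i}": hit_table_factory(f"U{i}", activators=[f"X{i}", "BASE"])
            for i in range(3)
        }
        common, specific = rs.condition_specific_regulators(treated, untreated)
        assert common == {"RAPA"}
        assert specific == {"RAPA"}

    def test_common_regulator_present_everywhere_not_specific(self, hit_table_factory):
        treated = {"T1": hit_table_factory("T1", activators=["FK", "G1"])}
        untreated = {"U1": hit_table_factory("U1", activators=["FK"])}
        common, specific = rs.condition_specific_regulators(treated, untreated)
        assert "FK" in common and "FK" not in specific


class TestClassDistribution:
    def test_single_class_map_gives_fraction_one(self, hit_table_factory):
        tables = {"S1": hit_table_factory("S1", activators=["A", "B"], repressors=["C"])}
        cmap = {"A": "ribo", "B": "ribo", "C": "ribo"}
        out = rs.class_distribution(tables, cmap)
        assert (out["fraction"] == 1.0).all()

    def test_empty_map_gives_zero_fractions(self, hit_table_factory):
        tables = {"S1": hit_table_factory("S1", activators=["A"])}
        out = rs.class_distribution(tables, {})
        assert out.empty or (out["fraction"] == 0.0).all()

    def test_counts_sum_to_classified_hits(self, hit_table_factory):
        tables = {
            "S1": hit_table_factory("S1", activators=["A", "B", "C"], repressors=["D"])
        }
        cmap = {"A": "ribo", "B": "cycle", "D": "ribo"}
        out = rs.class_distribution(tables, cmap)
        act = out[(out["sense"] == "activator")]
        assert act["count"].sum() == 2
        assert ((out["fraction"] >= 0) & (out["fraction"] <= 1)).all()
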