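import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from karyoasym import indices
from karyoasym.cluster import (
    CategoryBinning,
    categorize,
    distance_matrix,
    majority_consensus,
    root_on_outgroup,
    run_cluster_analysis,
    upgma,
)
from karyoasym.ideals import ideal_series
from karyoasym.model import Chromosome, HomologPair, Karyotype


def clades_of(tree):
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        c = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(c) < len(leaves):
            out.add(c)
    return out


class TestCategorize:
    def test_half_open_bins_with_closed_top(self):
        binning = CategoryBinning(edges=(0.0, 0.5, 1.0))
        vals = pd.Series({"x": 0.1, "y": 0.5, "z": 0.9})
        assert categorize(vals, binning).tolist() == [1, 2, 2]
        assert binning.assign(1.0) == 2  # top edge closed

    def test_equal_values_share_a_bin(self):
        binning = CategoryBinning.equal_width([3.0, 3.0, 3.0], n_bins=4)
        assert binning.assign(3.0) in range(1, 5)

    def test_edges_map_monotonically(self):
        binning = CategoryBinning(edges=(0.0, 1.0, 2.0, 3.0))
        codes = [binning.assign(v) for v in (0.0, 1.0, 2.0, 3.0)]
        assert codes == [1, 2, 3, 3]
        assert codes == sorted(codes)

    def test_strict_mode_rejects_out_of_range(self):
        binning = CategoryBinning(edges=(0.0, 1.0))
        with pytest.raises(ValueError):
            binning.assign(2.0, strict=True)
        assert binning.assign(2.0) == 1  # clamps when not strict

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            CategoryBinning(edges=(1.0, 1.0, 2.0))


class TestDistanceMatrix:
    def test_absolute_differences(self):
        d = distance_matrix([1, 2, 4])
        assert np.array_equal(d, [[0, 1, 3], [1, 0, 2], [3, 2, 0]])

    def test_identical_codes_give_zero(self):
        assert np.array_equal(distance_matrix([1, 1]), [[0, 0], [0, 0]])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix([1.0, np.nan])


class TestUPGMA:
    def test_two_leaves_join_at_half_distance(self):
        res = upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        root = res.tree.seed_node
        assert [ch.edge.length for ch in root.child_nodes()] == [2.0, 2.0]
        assert res.cophenetic.loc["A", "B"] == 4.0

    def test_three_leaf_hand_agglomeration(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        res = upgma(d, ["A", "B", "C"])
        assert clades_of(res.tree) == {frozenset({"A", "B"})}
        # heights 1 and 3 -> cophenetic distances 2 and 6
        assert res.cophenetic.loc["A", "B"] == pytest.approx(2.0)
        assert res.cophenetic.loc["A", "C"] == pytest.approx(6.0)

    def test_ultrametric_output(self, rng):
        n = 7
        x = rng.uniform(0, 10, size=(n, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        res = upgma(d, [f"L{i}" for i in range(n)])
        depths = {}
        def walk(node, depth):
            if node.is_leaf():
                depths[node.taxon.label] = depth
            for ch in node.child_nodes():
                walk(ch, depth + ch.edge.length)
        walk(res.tree.seed_node, 0.0)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_matches_scipy_average_linkage(self, rng):
        """Cophenetic distances agree with an independent average-linkage
        implementation on random tie-free matrices up to 6 leaves."""
        for _ in range(50):
            n = int(rng.integers(3, 7))
            x = rng.normal(size=(n, 4))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            labels = [f"L{i}" for i in range(n)]
            res = upgma(d, labels)
            ref = squareform(cophenet(average(squareform(d))))
            assert np.allclose(res.cophenetic.to_numpy(), ref, atol=1e-9)

    def test_cophenetic_reproduces_ultrametric_input(self):
        # an already-ultrametric matrix is recovered exactly
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
        )
        res = upgma(d, list("ABCD"))
        assert np.allclose(res.cophenetic.to_numpy(), d)

    def test_tied_matrix_has_equal_cophenetics_regardless_of_seed(self):
        d = np.ones((4, 4)) - np.eye(4)
        cophs = []
        for seed in range(5):
            res = upgma(d, list("ABCD"), rng=np.random.default_rng(seed))
            cophs.append(res.cophenetic.loc[list("ABCD"), list("ABCD")].to_numpy())
        for c in cophs:
            assert np.allclose(c, d)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0.0]]), ["A"])
        with pytest.raises(ValueError):
            upgma(np.array([[0, 1], [2, 0]], float), ["A", "B"])


class TestConsensus:
    def make_trees(self, d, labels, n):
        return [upgma(d, labels).tree for _ in range(n)]

    def test_identical_trees_full_support(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        trees = self.make_trees(d, ["A", "B", "C"], 10)
        cons = majority_consensus(trees)
        assert clades_of(cons) == {frozenset({"A", "B"})}
        node = [
            nd for nd in cons.preorder_node_iter()
            if not nd.is_leaf() and nd is not cons.seed_node
        ][0]
        assert node.label == "100"

    def test_sixty_percent_majority(self):
        d_ab = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        d_ac = np.array([[0, 6, 2], [6, 0, 6], [2, 6, 0]], float)
        trees = self.make_trees(d_ab, ["A", "B", "C"], 6) + self.make_trees(
            d_ac, ["A", "B", "C"], 4
        )
        cons = majority_consensus(trees)
        assert clades_of(cons) == {frozenset({"A", "B"})}

    def test_even_split_collapses_to_star(self):
        d_ab = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        d_ac = np.array([[0, 6, 2], [6, 0, 6], [2, 6, 0]], float)
        trees = self.make_trees(d_ab, ["A", "B", "C"], 5) + self.make_trees(
            d_ac, ["A", "B", "C"], 5
        )
        assert clades_of(majority_consensus(trees)) == set()

    def test_idempotent_and_order_invariant(self):
        d = np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float)
        t = upgma(d, list("ABCD")).tree
        assert clades_of(majority_consensus([t])) == clades_of(t)
        d2 = np.array([[0, 8, 2, 8], [8, 0, 8, 4], [2, 8, 0, 8], [8, 4, 8, 0]], float)
        t2 = upgma(d2, list("ABCD")).tree
        fwd = majority_consensus([t, t, t2])
        rev = majority_consensus([t2, t, t])
        assert clades_of(fwd) == clades_of(rev)

    def test_leaf_set_mismatch_rejected(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        t1 = upgma(d, ["A", "B"]).tree
        t2 = upgma(d, ["A", "C"]).tree
        with pytest.raises(ValueError):
            majority_consensus([t1, t2])


class TestRooting:
    def test_root_on_c(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        t = upgma(d, ["A", "B", "C"]).tree
        rooted = root_on_outgroup(t, "C")
        assert clades_of(rooted) == {frozenset({"A", "B"})}

    def test_root_on_a_reorients(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        t = upgma(d, ["A", "B", "C"]).tree  # ((A,B),C)
        rooted = root_on_outgroup(t, "A")
        assert clades_of(rooted) == {frozenset({"B", "C"})}

    def test_idempotent_on_current_outgroup(self):
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float)
        t = root_on_outgroup(upgma(d, ["A", "B", "C"]).tree, "C")
        again = root_on_outgroup(t, "C")
        assert clades_of(again) == clades_of(t)

    def test_bipartitions_preserved(self, rng):
        for _ in range(20):
            n = 6
            x = rng.normal(size=(n, 3))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            labels = [f"L{i}" for i in range(n)]
            t = upgma(d, labels).tree
            all_set = frozenset(labels)
            og = labels[int(rng.integers(n))]
            rooted = root_on_outgroup(t, og)

            def biparts(tree):
                # non-trivial bipartitions only: both sides of size >= 2
                return {
                    frozenset({c, all_set - c})
                    for c in clades_of(tree)
                    if 2 <= len(c) <= n - 2
                }

            # rooting may add or drop only the trivial outgroup bipartition
            trivial = frozenset({frozenset({og}), all_set - {og}})
            assert biparts(t) - {trivial} == biparts(rooted) - {trivial}

    def test_missing_outgroup_rejected(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        t = upgma(d, ["A", "B"]).tree
        with pytest.raises(ValueError):
            root_on_outgroup(t, "Z")


class TestRunClusterAnalysis:
    def ideal_values(self, index_name):
        return pd.Series(
            {
                f"ideal_{ik.label}": getattr(
                    indices.index_set(ik.karyotype), index_name
                )
                for ik in ideal_series()
            }
        )

    def test_ideals_alone_form_ordered_chain(self):
        """Clustering the six ideals alone respects the A..F asymmetry
        ladder: every consensus clade is a contiguous block of the ladder
        and the fully symmetric ideal A is the outgroup."""
        vals = self.ideal_values("a1")
        res = run_cluster_analysis(
            vals, index_name="a1", ideal_labels=list(vals.index), seed=1
        )
        order = [f"ideal_{c}" for c in "ABCDEF"]
        for clade in clades_of(res.consensus):
            ranks = sorted(order.index(lab) for lab in clade)
            assert ranks == list(range(ranks[0], ranks[-1] + 1)), clade
            assert "ideal_A" not in clade
        root_children = res.consensus.seed_node.child_nodes()
        leaf_children = [c.taxon.label for c in root_children if c.is_leaf()]
        assert "ideal_A" in leaf_children

    def test_pure_metacentric_taxon_nearest_ideal_a(self):
        # all arms equal: arm ratio 1 throughout, so a1 = 0 like ideal A
        k = Karyotype(
            taxon="sym",
            pairs=tuple(
                HomologPair(
                    pair_id=str(i),
                    members=(Chromosome(1.0, 1.0), Chromosome(1.0, 1.0)),
                )
                for i in range(10)
            ),
        )
        vals = self.ideal_values("a1")
        vals["sym_taxon"] = indices.a1(k)
        res = run_cluster_analysis(vals, index_name="a1", seed=2)
        row = res.nearest_ideal.set_index("taxon").loc["sym_taxon"]
        assert row["nearest_ideal"] == "A"
        assert row["mean_cophenetic"] == 0.0

    def test_deterministic_under_fixed_seed(self):
        vals = self.ideal_values("ask")
        vals["t1"], vals["t2"] = 0.55, 0.62
        r1 = run_cluster_analysis(vals, index_name="ask", seed=7)
        r2 = run_cluster_analysis(vals, index_name="ask", seed=7)
        assert r1.newick == r2.newick
        assert r1.nearest_ideal.equals(r2.nearest_ideal)
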