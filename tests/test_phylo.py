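"""Distances, neighbor joining, Fitch parsimony, bootstrap, overlay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aprphylo.phylo import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_supports,
    distance_matrix,
    neighbor_joining,
    overlay_supports,
    pairwise_distance,
    parsimony_score,
    support_dict,
)
from conftest import (
    fitch_oracle,
    internal_bipartitions,
    mutate,
    random_protein,
    random_unrooted_tree,
    tree_path_distances,
)


def related_family(rng, n, length=60, k=6):
    """Sequences a few substitutions from a common ancestor (p well below 1)."""
    base = random_protein(rng, length)
    return {f"t{i}": mutate(base, k, rng) for i in range(n)}


class TestPairwiseDistance:
    def test_identical_rows_distance_zero(self):
        assert pairwise_distance("ACDE", "ACDE") == (0.0, 4)

    def test_quarter_difference_closed_form(self):
        p, n = pairwise_distance("ACDE", "ACDF", model="p")
        assert (p, n) == (0.25, 4)
        d, _ = pairwise_distance("ACDE", "ACDF", model="poisson")
        assert d == pytest.approx(-math.log(0.75), rel=1e-12)
        assert d == pytest.approx(0.2877, abs=1e-4)

    def test_two_diffs_over_119_positions_below_otu_cutoff(self):
        # the scale of near-identical amplicon fragments: 2 differences over
        # 119 comparable residues stays below the 0.02 clustering cutoff
        base = random_protein(np.random.default_rng(7), 119)
        other = base[:2].swapcase()  # not used; build explicit 2-diff pair
        other = ("W" if base[0] != "W" else "Y") + ("W" if base[1] != "W" else "Y") + base[2:]
        p, n = pairwise_distance(base, other, model="p")
        assert n == 119 and p == pytest.approx(2 / 119)
        d, _ = pairwise_distance(base, other, model="poisson")
        assert d == pytest.approx(0.01695, abs=1e-5)
        assert d < 0.02

    def test_ambiguous_positions_not_comparable(self):
        d, n = pairwise_distance("AXDE", "AC-E", model="p")
        assert n == 2 and d == 0.0

    def test_zero_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance("XX", "AA")

    def test_saturated_pair_needs_cap(self):
        with pytest.raises(ValueError, match="Poisson"):
            pairwise_distance("AAAA", "CCCC", model="poisson")
        d, _ = pairwise_distance("AAAA", "CCCC", model="poisson", cap=5.0)
        assert d == 5.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_poisson_dominates_p_distance(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, 60)
        b = random_protein(rng, 60)
        p, _ = pairwise_distance(a, b, model="p")
        if p < 1.0:
            d, _ = pairwise_distance(a, b, model="poisson")
            assert d >= p
            # first-order agreement as p -> 0
            if p < 0.05:
                assert d == pytest.approx(p, rel=0.05)


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        dm = distance_matrix({"a": "MKV", "b": "MKV"})
        assert np.all(dm.values == 0)

    def test_matrix_matches_per_pair_calls(self, rng):
        rows = {f"s{i}": random_protein(rng, 30) for i in range(3)}
        dm = distance_matrix(rows, model="p", deletion="pairwise")
        ids = dm.ids
        for i in range(3):
            for j in range(i + 1, 3):
                d, n = pairwise_distance(rows[ids[i]], rows[ids[j]], model="p")
                assert dm.values[i, j] == pytest.approx(d)
                assert dm.comparable_sites[i, j] == n

    def test_pairwise_deletion_keeps_at_least_complete_sites(self, rng):
        rows = {}
        for i in range(4):
            seq = list(random_protein(rng, 40))
            for pos in rng.choice(40, size=6, replace=False):
                seq[int(pos)] = "-"
            rows[f"s{i}"] = "".join(seq)
        comp = distance_matrix(rows, model="p", deletion="complete").comparable_sites
        pair = distance_matrix(rows, model="p", deletion="pairwise").comparable_sites
        assert np.all(pair >= comp)


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        dm = DistanceMatrix(list("ABC"), np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float), "p", "complete")
        tree = neighbor_joining(dm)
        assert sorted(tree.leaf_names) == ["A", "B", "C"]
        assert len(tree.root.children) == 3
        assert internal_bipartitions(tree) == set()

    def test_recovers_split_from_additive_matrix(self):
        vals = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 4], [4, 4, 4, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), vals, "p", "complete"))
        assert internal_bipartitions(tree) == {frozenset({"C", "D"})}

    def test_fewer_than_three_taxa_is_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float), "p", "complete"))

    @pytest.mark.parametrize("n_leaves", [4, 6, 9, 12])
    def test_exact_recovery_on_additive_input(self, n_leaves, rng):
        # NJ is consistent: additive distances return the generating topology
        for _ in range(10):
            true_tree = random_unrooted_tree(rng, n_leaves)
            dm = tree_path_distances(true_tree)
            est = neighbor_joining(dm)
            assert internal_bipartitions(est) == internal_bipartitions(true_tree)
            assert len(internal_bipartitions(est)) == n_leaves - 3

    def test_branch_lengths_recovered_on_additive_input(self, rng):
        true_tree = random_unrooted_tree(rng, 8)
        est = neighbor_joining(tree_path_distances(true_tree))
        d_true = tree_path_distances(true_tree)
        d_est = tree_path_distances(est)
        order = [d_est.ids.index(i) for i in d_true.ids]
        assert np.allclose(d_true.values, d_est.values[np.ix_(order, order)], atol=1e-9)


class TestFitchParsimony:
    def test_identical_leaves_score_zero(self):
        tree = PhyloTree.from_newick("((A,B),C,D);")
        assert parsimony_score(tree, {x: "MMM" for x in "ABCD"}) == 0

    def test_one_column_two_state_topology_dependence(self):
        rows = {"A": "A", "B": "A", "C": "C", "D": "C"}
        assert parsimony_score(PhyloTree.from_newick("((A,B),C,D);"), rows) == 1
        assert parsimony_score(PhyloTree.from_newick("((A,C),B,D);"), rows) == 2

    def test_additive_over_disjoint_column_sets(self, rng):
        tree = random_unrooted_tree(rng, 6)
        rows = {name: random_protein(rng, 10) for name in tree.leaf_names}
        full = parsimony_score(tree, rows)
        left = parsimony_score(tree, rows, columns=range(0, 5))
        right = parsimony_score(tree, rows, columns=range(5, 10))
        assert full == left + right

    def test_missing_leaf_row_is_error(self):
        tree = PhyloTree.from_newick("((A,B),C,D);")
        with pytest.raises(ValueError, match="no alignment row"):
            parsimony_score(tree, {"A": "A", "B": "A", "C": "C"})

    @pytest.mark.parametrize("n_leaves,n_cols", [(4, 3), (5, 4), (6, 5)])
    def test_matches_exhaustive_labeling_oracle(self, n_leaves, n_cols, rng):
        for rep in range(5):
            tree = random_unrooted_tree(rng, n_leaves)
            rows = {}
            for name in tree.leaf_names:
                # few states + occasional missing data to stress wildcards
                chars = [
                    "-" if rng.random() < 0.15 else "ACD"[int(rng.integers(0, 3))]
                    for _ in range(n_cols)
                ]
                rows[name] = "".join(chars)
            assert parsimony_score(tree, rows) == fitch_oracle(tree, rows)


class TestBootstrap:
    def test_same_seed_reproduces_supports(self, rng):
        rows = related_family(rng, 6)
        r1 = bootstrap_supports(rows, n_reps=20, seed=5)
        r2 = bootstrap_supports(rows, n_reps=20, seed=5)
        assert r1.supports == r2.supports

    def test_unanimous_columns_give_full_support(self):
        # every column individually separates AB from CD
        rows = {"A": "AAAA", "B": "AAAA", "C": "CCCC", "D": "CCCC"}
        result = bootstrap_supports(rows, model="p", n_reps=30, seed=1)
        assert result.supports == {frozenset({"C", "D"}): 100.0}

    def test_default_replicate_count_is_100(self):
        import inspect

        assert inspect.signature(bootstrap_supports).parameters["n_reps"].default == 100


class TestOverlay:
    def test_self_overlay_matches_primary(self, rng):
        rows = related_family(rng, 6, length=50)
        result = bootstrap_supports(rows, n_reps=20, seed=3)
        overlaid = overlay_supports(result.tree, result.supports)
        for key, node in overlaid.bipartitions().items():
            assert node.primary_support == node.overlay_support

    def test_disjoint_topologies_overlay_absent(self):
        # caterpillar trees on 5 taxa with no shared internal bipartition
        primary = PhyloTree.from_newick("(((A,B),(C,D)),E,F);")
        secondary = PhyloTree.from_newick("(((A,C),(B,E)),D,F);")
        fake = {key: 77.0 for key in secondary.bipartitions()}
        overlaid = overlay_supports(primary, fake)
        assert all(
            node.overlay_support is None for node in overlaid.bipartitions().values()
        )

    def test_newick_encodes_dual_supports(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        node = tree.bipartitions()[frozenset({"C", "D"})]
        node.primary_support, node.overlay_support = 85.0, 72.0
        newick = tree.to_newick(supports=True)
        assert "85/72" in newick
        back = PhyloTree.from_newick(newick)
        annotated = back.bipartitions()[frozenset({"C", "D"})]
        assert (annotated.primary_support, annotated.overlay_support) == (85.0, 72.0)

    def test_foreign_leaf_in_supports_is_error(self):
        tree = PhyloTree.from_newick("((A,B),C,D);")
        with pytest.raises(ValueError, match="unknown leaves"):
            overlay_supports(tree, {frozenset({"Z", "Q"}): 50.0})

    def test_support_dict_roundtrip(self, rng):
        rows = related_family(rng, 5, length=50)
        result = bootstrap_supports(rows, n_reps=10, seed=2)
        assert support_dict(result.tree) == result.supports
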