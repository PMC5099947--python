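"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: Fitch scores
come from exhaustive enumeration of ancestral labelings, additive distance
matrices from explicit path lengths on a generating tree, primer mismatch
counts from minimum Hamming distance over the degenerate expansion, and OTU
partitions from scipy's hierarchical clustering.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from aprphylo._alphabet import AA_LETTERS
from aprphylo.phylo import Clade, DistanceMatrix, PhyloTree, bipartition_key


# ---------------------------------------------------------------------------
# random trees and additive matrices


def random_unrooted_tree(rng: np.random.Generator, n_leaves: int,
                         min_bl: float = 0.1, mean_bl: float = 0.5) -> PhyloTree:
    """Random unrooted binary tree with strictly positive branch lengths.

    Grown by attaching each new leaf to a uniformly chosen existing edge.
    """
    def bl() -> float:
        return min_bl + float(rng.exponential(mean_bl))

    assert n_leaves >= 3
    root = Clade(children=[Clade(name="L1", length=bl()),
                           Clade(name="L2", length=bl()),
                           Clade(name="L3", length=bl())])
    tree = PhyloTree(root)
    for k in range(4, n_leaves + 1):
        parents = tree.parent_map()
        edges = [node for node in tree.preorder() if node is not tree.root]
        target = edges[int(rng.integers(0, len(edges)))]
        parent = parents[target]
        half = target.length / 2
        new_leaf = Clade(name=f"L{k}", length=bl())
        joint = Clade(length=half, children=[target, new_leaf])
        target.length = half
        parent.children[parent.children.index(target)] = joint
    return tree


def tree_path_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (additive) distance matrix."""
    parents = tree.parent_map()
    adjacency: dict[Clade, list[tuple[Clade, float]]] = {}
    for child, parent in parents.items():
        adjacency.setdefault(parent, []).append((child, child.length or 0.0))
        adjacency.setdefault(child, []).append((parent, child.length or 0.0))
    leaves = tree.leaves()
    ids = [leaf.name for leaf in leaves]
    values = np.zeros((len(ids), len(ids)))
    for i, leaf in enumerate(leaves):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for neighbor, w in adjacency.get(node, []):
                if neighbor not in dist:
                    dist[neighbor] = dist[node] + w
                    stack.append(neighbor)
        for j, other in enumerate(leaves):
            values[i, j] = dist[other]
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2
    return DistanceMatrix(ids, values, "p", "complete")


def internal_bipartitions(tree: PhyloTree) -> set[frozenset]:
    return set(tree.bipartitions())


# ---------------------------------------------------------------------------
# Fitch oracle: exhaustive ancestral labeling


def fitch_oracle(tree: PhyloTree, rows: dict[str, str],
                 columns=None, alphabet: str = AA_LETTERS) -> int:
    """Minimum number of state changes over all ancestral labelings.

    Leaves with gaps/ambiguity are free variables too (wildcard). Optimal
    labelings only need states observed in the column (plus one arbitrary
    state when a column has none), which keeps enumeration tractable.
    """
    leaves = tree.leaves()
    internals = [n for n in tree.postorder() if not n.is_leaf]
    parents = tree.parent_map()
    ncols = len(next(iter(rows.values())))
    cols = range(ncols) if columns is None else columns
    total = 0
    for col in cols:
        fixed: dict[Clade, str] = {}
        free: list[Clade] = []
        observed = set()
        for leaf in leaves:
            char = rows[leaf.name][col].upper()
            if char in AA_LETTERS:
                fixed[leaf] = char
                observed.add(char)
            else:
                free.append(leaf)
        states = sorted(observed) or [alphabet[0]]
        best = None
        for assignment in itertools.product(states, repeat=len(internals) + len(free)):
            labels = dict(fixed)
            for node, s in zip(internals + free, assignment):
                labels[node] = s
            changes = sum(
                1 for child, parent in parents.items() if labels[child] != labels[parent]
            )
            if best is None or changes < best:
                best = changes
        total += best
    return total


# ---------------------------------------------------------------------------
# primer oracle: degenerate expansion membership


def expansion_mismatch_oracle(primer, window: str) -> int:
    """min over all concrete expansions of the Hamming distance to window."""
    return min(
        sum(1 for a, b in zip(exp, window) if a != b) for exp in primer.expansions()
    )


# ---------------------------------------------------------------------------
# OTU oracle: scipy hierarchical clustering


def scipy_otu_oracle(dm: DistanceMatrix, cutoff: float, linkage: str) -> set[frozenset]:
    from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
    from scipy.spatial.distance import squareform

    method = {"furthest": "complete", "average": "average", "nearest": "single"}[linkage]
    z = scipy_linkage(squareform(dm.values, checks=False), method=method)
    labels = fcluster(z, t=cutoff, criterion="distance")
    clusters: dict[int, set[str]] = {}
    for rid, lab in zip(dm.ids, labels):
        clusters.setdefault(int(lab), set()).add(rid)
    return {frozenset(c) for c in clusters.values()}


def partition_as_sets(partition) -> set[frozenset]:
    return {frozenset(members) for members in partition.clusters.values()}


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20160907)


@pytest.fixture
def four_leaf_case():
    """Reference AB|CD with A='AA', B='AA', C='CC', D='CC'."""
    from aprphylo.refset import ReferenceAlignment

    tree = PhyloTree.from_newick("((A:1,B:1):1,C:2,D:2);")
    ref = ReferenceAlignment(
        [("A", "AA"), ("B", "AA"), ("C", "CC"), ("D", "CC")],
        2,
        frozenset({0, 1}),
        "A",
    )
    return tree, ref


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_LETTERS[int(i)] for i in rng.integers(0, 20, size=length))


def mutate(seq: str, k: int, rng: np.random.Generator) -> str:
    """Exactly k substitutions at k distinct positions."""
    out = list(seq)
    sites = rng.choice(len(seq), size=k, replace=False)
    for pos in sites:
        choices = [a for a in AA_LETTERS if a != out[pos]]
        out[int(pos)] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)
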