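"""Distance, tree building, parsimony scoring and support overlay.

The phylogenetic core of the pipeline:

* p-distance and Poisson-corrected amino-acid distances (d = -ln(1 - p))
  under complete or pairwise deletion of non-comparable sites;
* Saitou-Nei neighbor joining with deterministic tie-breaking;
* Fitch small-parsimony scoring (unordered states, missing data as
  wildcard), vectorized over alignment columns;
* nonparametric bootstrap supports for the bipartitions of a point-estimate
  tree;
* the dual-support "consensus tree" construct: a primary topology whose
  internal edges additionally carry supports from a second analysis,
  rendered in Newick as ``primary/overlay`` internal labels.

Trees are unrooted; internally they are stored rooted at an arbitrary
trifurcating node, which leaves Fitch scores, bipartitions and NJ output
invariant.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._alphabet import AA_INDEX, encode_residues

__all__ = [
    "Clade",
    "PhyloTree",
    "DistanceMatrix",
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "parsimony_score",
    "bootstrap_supports",
    "BootstrapResult",
    "overlay_supports",
    "bipartition_key",
]


# ---------------------------------------------------------------------------
# tree structure


class Clade:
    """Tree node; a non-root node also represents the edge to its parent."""

    __slots__ = ("name", "length", "children", "primary_support", "overlay_support")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        children: list["Clade"] | None = None,
        primary_support: float | None = None,
        overlay_support: float | None = None,
    ):
        self.name = name
        self.length = length
        self.children = children if children is not None else []
        self.primary_support = primary_support
        self.overlay_support = overlay_support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Clade":
        return Clade(
            self.name,
            self.length,
            [c.copy() for c in self.children],
            self.primary_support,
            self.overlay_support,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)} children"
        return f"<Clade {self.name!r} ({kind})>"


_SUPPORT_LABEL = re.compile(r"^(?P<p>\d+(?:\.\d+)?|NA)/(?P<o>\d+(?:\.\d+)?|NA)$")


class PhyloTree:
    """Unrooted leaf-labeled tree, stored with an arbitrary internal root."""

    def __init__(self, root: Clade):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[Clade]:
        order: list[Clade] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(node.children)
        order.reverse()
        return order

    def preorder(self) -> list[Clade]:
        order: list[Clade] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(node.children))
        return order

    def leaves(self) -> list[Clade]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def parent_map(self) -> dict[Clade, Clade]:
        parents: dict[Clade, Clade] = {}
        for node in self.preorder():
            for child in node.children:
                parents[child] = node
        return parents

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    # -- bipartitions ------------------------------------------------------

    def leafsets(self) -> dict[Clade, frozenset[str]]:
        """Leaf-name set below each node (below = away from the root)."""
        below: dict[Clade, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.name])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= below[c]
                below[node] = frozenset(acc)
        return below

    def edges(self) -> list[tuple[Clade, frozenset[str]]]:
        """All edges in preorder as (child node, leaf set below the edge)."""
        below = self.leafsets()
        return [(n, below[n]) for n in self.preorder() if n is not self.root]

    def bipartitions(self, include_trivial: bool = False) -> dict[frozenset[str], Clade]:
        """Canonical bipartition key -> child node of that edge.

        By default only internal (non-trivial) bipartitions are returned;
        an unrooted binary tree has exactly n_leaves - 3 of them.
        """
        all_leaves = frozenset(self.leaf_names)
        out: dict[frozenset[str], Clade] = {}
        for node, leafset in self.edges():
            if not include_trivial and (
                len(leafset) <= 1 or len(leafset) >= len(all_leaves) - 1
            ):
                continue
            out[bipartition_key(leafset, all_leaves)] = node
        return out

    # -- newick ------------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str | Path) -> "PhyloTree":
        from skbio import TreeNode

        text = newick if isinstance(newick, str) and newick.strip().startswith("(") else Path(newick).read_text()
        sk = TreeNode.read(io.StringIO(text), convert_underscores=False)

        def convert(node) -> Clade:
            clade = Clade(name=node.name, length=node.length)
            clade.children = [convert(c) for c in node.children]
            if clade.children and clade.name:
                m = _SUPPORT_LABEL.match(clade.name)
                if m:
                    clade.primary_support = None if m["p"] == "NA" else float(m["p"])
                    clade.overlay_support = None if m["o"] == "NA" else float(m["o"])
                    clade.name = None
            return clade

        return cls(convert(sk))

    def to_newick(self, supports: bool = False) -> str:
        def fmt_support(v: float | None) -> str:
            return "NA" if v is None else f"{v:g}"

        def render(node: Clade) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(render(c) for c in node.children)
                if supports and node is not self.root and (
                    node.primary_support is not None or node.overlay_support is not None
                ):
                    label = f"({inner}){fmt_support(node.primary_support)}/{fmt_support(node.overlay_support)}"
                else:
                    label = f"({inner}){node.name or ''}"
            if node.length is not None and node is not self.root:
                label += f":{node.length:g}"
            return label

        return render(self.root) + ";"

    def write(self, path: str | Path, supports: bool = False) -> None:
        Path(path).write_text(self.to_newick(supports=supports) + "\n")


def bipartition_key(leafset: Iterable[str], all_leaves: frozenset[str]) -> frozenset[str]:
    """Rooting-independent identifier of the edge splitting *leafset* off.

    The canonical key is the side of the bipartition that does not contain
    the lexicographically smallest leaf name.
    """
    leafset = frozenset(leafset)
    anchor = min(all_leaves)
    return frozenset(all_leaves - leafset) if anchor in leafset else leafset


def reroot_on_edge(tree: PhyloTree, target: Clade) -> PhyloTree:
    """Return a copy rooted at the midpoint of the edge above *target*.

    Support annotations are not carried over; rerooted trees serve clade
    (MRCA) semantics only.
    """
    parents = tree.parent_map()
    if target not in parents:
        raise ValueError("cannot reroot on the root node")

    def seen_from(node: Clade, coming_from: Clade) -> Clade:
        kids = [c.copy() for c in node.children if c is not coming_from]
        parent = parents.get(node)
        if parent is not None:
            up = seen_from(parent, node)
            up.length = node.length
            kids.append(up)
        return Clade(name=node.name if node.is_leaf else None, children=kids)

    half = (target.length or 0.0) / 2.0
    down = target.copy()
    down.length = half
    up = seen_from(parents[target], target)
    up.length = half
    return PhyloTree(Clade(children=[down, up]))


def root_on_longest_edge(tree: PhyloTree) -> PhyloTree:
    """Canonical rooting: midpoint of the longest edge (preorder tie-break)."""
    best, best_len = None, -1.0
    for node, _ in tree.edges():
        ln = node.length if node.length is not None else 0.0
        if ln > best_len:
            best, best_len = node, ln
    if best is None:
        raise ValueError("tree has no edges")
    return reroot_on_edge(tree, best)


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric matrix of per-site amino-acid distances."""

    ids: list[str]
    values: np.ndarray
    model: str  # 'p' | 'poisson'
    deletion: str  # 'complete' | 'pairwise'
    comparable_sites: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        if self.comparable_sites is None:
            self.comparable_sites = np.zeros((n, n), dtype=int)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="record_id")


def _codes(seq: str) -> np.ndarray:
    """Residue string -> int8 codes, -1 for gaps/ambiguity (non-comparable)."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        out[i] = AA_INDEX.get(c, -1)
    return out


def pairwise_distance(
    row_i: str,
    row_j: str,
    model: str = "poisson",
    cap: float | None = None,
) -> tuple[float, int]:
    """Distance between two equal-length residue rows.

    Comparable sites are positions where both rows carry an unambiguous
    residue. p = differences / comparable sites; under the Poisson model the
    corrected distance is d = -ln(1 - p). Returns (distance, n_comparable).
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    ci, cj = _codes(row_i), _codes(row_j)
    comparable = (ci >= 0) & (cj >= 0)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable sites between rows")
    p = float(((ci != cj) & comparable).sum()) / n_comp
    if model == "p":
        return p, n_comp
    if p >= 1.0:
        if cap is None:
            raise ValueError("p-distance >= 1: Poisson correction undefined (set cap)")
        return cap, n_comp
    return -np.log1p(-p), n_comp


def distance_matrix(
    rows: Mapping[str, str] | "object",
    model: str = "poisson",
    deletion: str = "complete",
    cap: float | None = None,
) -> DistanceMatrix:
    """All-pairs distances for an alignment (ReferenceAlignment or id->row).

    Complete deletion first drops every column that is not unambiguous in
    all rows (so every pair shares the same comparable set); pairwise
    deletion keeps, per pair, the columns comparable for that pair.
    """
    if hasattr(rows, "masked_rows"):
        rows = rows.masked_rows()
    ids = list(rows)
    if len(ids) < 2:
        raise ValueError("need at least 2 rows")
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    mat = np.stack([_codes(rows[i]) for i in ids])
    if deletion == "complete":
        keep = np.all(mat >= 0, axis=0)
        mat = mat[:, keep]
        if mat.shape[1] == 0:
            raise ValueError("complete deletion removed all columns")
    n = len(ids)
    values = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    np.fill_diagonal(comp, mat.shape[1])
    for i in range(n):
        for j in range(i + 1, n):
            comparable = (mat[i] >= 0) & (mat[j] >= 0)
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(f"no comparable sites for pair ({ids[i]}, {ids[j]})")
            p = float(((mat[i] != mat[j]) & comparable).sum()) / n_comp
            if model == "p":
                d = p
            elif p >= 1.0:
                if cap is None:
                    raise ValueError(
                        f"p >= 1 for pair ({ids[i]}, {ids[j]}): Poisson undefined"
                    )
                d = cap
            else:
                d = -np.log1p(-p)
            values[i, j] = values[j, i] = d
            comp[i, j] = comp[j, i] = n_comp
    return DistanceMatrix(ids, values, model, deletion, comp)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Q criterion.

    Deterministic: the pair minimizing Q is chosen as the smallest (i, j)
    index pair in the current working matrix (row-major scan). Negative
    branch lengths are clamped to zero with a warning.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[Clade] = [Clade(name=i) for i in dm.ids]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first flattened argmin = smallest (i, j) in row-major order
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = Clade(children=[child_i, child_j])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    if clamped:
        warnings.warn(f"{clamped} negative branch length(s) clamped to 0")
    return PhyloTree(Clade(children=[a, b, c]))


# ---------------------------------------------------------------------------
# Fitch parsimony


def _leaf_states(
    rows: Mapping[str, str], columns: Sequence[int] | None
) -> dict[str, np.ndarray]:
    states = {}
    for rid, seq in rows.items():
        enc = encode_residues(seq)
        states[rid] = enc if columns is None else enc[np.asarray(columns, dtype=int)]
    return states


def _fitch_down(
    tree: PhyloTree, leaf_states: Mapping[str, np.ndarray]
) -> tuple[dict[Clade, np.ndarray], np.ndarray]:
    """Postorder Fitch state sets and per-column cost (vectorized bitmasks)."""
    down: dict[Clade, np.ndarray] = {}
    cost: np.ndarray | None = None
    for node in tree.postorder():
        if node.is_leaf:
            try:
                down[node] = leaf_states[node.name]
            except KeyError:
                raise ValueError(f"leaf {node.name!r} has no alignment row") from None
            if cost is None:
                cost = np.zeros(len(down[node]), dtype=np.int64)
        else:
            state = down[node.children[0]]
            for child in node.children[1:]:
                inter = state & down[child]
                union = state | down[child]
                empty = inter == 0
                cost += empty
                state = np.where(empty, union, inter)
            down[node] = state
    assert cost is not None
    return down, cost


def parsimony_score(
    tree: PhyloTree,
    rows: Mapping[str, str],
    columns: Sequence[int] | None = None,
) -> int:
    """Fitch small-parsimony score of *tree* over the given columns.

    States are unordered amino acids; a gap or ambiguity character at a leaf
    is missing data and contributes the full wildcard state set. With the
    stored trifurcating root, sequential pairwise union/intersection at the
    root is exact (it equals rooting on the edge to the last child).
    """
    _, cost = _fitch_down(tree, _leaf_states(rows, columns))
    return int(cost.sum())


# ---------------------------------------------------------------------------
# bootstrap and overlay


@dataclass
class BootstrapResult:
    """Point-estimate tree plus per-bipartition bootstrap percentages."""

    tree: PhyloTree
    supports: dict[frozenset[str], float]
    n_reps: int
    n_skipped: int


def bootstrap_supports(
    alignment,
    model: str = "poisson",
    n_reps: int = 100,
    seed: int = 0,
    deletion: str = "complete",
    cap: float | None = None,
) -> BootstrapResult:
    """NJ bootstrap: resample columns, rebuild, count recovered bipartitions.

    *alignment* is a ReferenceAlignment or an id -> masked-row mapping. The
    point-estimate tree is built on all columns; each replicate resamples
    columns with replacement and rebuilds an NJ tree. Support for each
    internal bipartition of the point tree is the percentage of successful
    replicates containing it. Replicates whose resampled matrix is
    degenerate (a pair with no comparable sites, or p >= 1 without a cap)
    are skipped, counted, and reported with a warning.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if hasattr(alignment, "masked_rows"):
        rows = alignment.masked_rows()
    else:
        rows = dict(alignment)
    ids = list(rows)
    length = len(next(iter(rows.values())))
    point = neighbor_joining(distance_matrix(rows, model, deletion, cap))
    targets = point.bipartitions()
    counts = {key: 0 for key in targets}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        sample = {rid: "".join(rows[rid][c] for c in cols) for rid in ids}
        try:
            rep_tree = neighbor_joining(distance_matrix(sample, model, deletion, cap))
        except ValueError:
            skipped += 1
            continue
        rep_biparts = set(rep_tree.bipartitions())
        for key in counts:
            if key in rep_biparts:
                counts[key] += 1
    effective = n_reps - skipped
    if skipped:
        warnings.warn(f"{skipped}/{n_reps} bootstrap replicates skipped (degenerate)")
    if effective == 0:
        raise ValueError("all bootstrap replicates were degenerate")
    supports = {key: 100.0 * c / effective for key, c in counts.items()}
    for key, node in targets.items():
        node.primary_support = supports[key]
    return BootstrapResult(point, supports, n_reps, skipped)


def overlay_supports(
    primary_tree: PhyloTree,
    secondary_supports: Mapping[frozenset[str], float],
) -> PhyloTree:
    """Annotate the primary tree's edges with supports from a second analysis.

    Returns a copy with unchanged topology in which every internal edge
    carries (primary_support, overlay_support); bipartitions absent from the
    secondary set get overlay None (rendered "NA"). This realizes the
    dual-support consensus-tree construct: one method's topology, a second
    method's supports overlaid edge by edge.
    """
    leaves = frozenset(primary_tree.leaf_names)
    foreign = set().union(*secondary_supports.keys()) - leaves if secondary_supports else set()
    if foreign:
        raise ValueError(f"secondary supports mention unknown leaves: {sorted(foreign)}")
    out = primary_tree.copy()
    for key, node in out.bipartitions().items():
        node.overlay_support = secondary_supports.get(key)
    return out


def support_dict(tree: PhyloTree) -> dict[frozenset[str], float]:
    """Primary supports of a tree keyed by canonical bipartition."""
    return {
        key: node.primary_support
        for key, node in tree.bipartitions().items()
        if node.primary_support is not None
    }
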