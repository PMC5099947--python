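"""Parsimony placement of partial query sequences on a fixed reference tree.

Environmental amplicon fragments cover only a window of the reference
alignment (~110 comparable residues for aprA amplicons versus 585 in the
concatenated AprBA reference), which makes de-novo trees from fragments
unreliable. Instead, each fragment is (1) mapped into reference alignment
coordinates by semi-global alignment against the column-wise consensus of
the reference, and (2) attached as a new leaf to the edge of the reference
tree that minimizes the increase in Fitch parsimony score over the columns
the fragment actually covers. The reference topology is never altered.

The per-edge score increase is computed with directional Fitch state sets:
for the edge above node v, with D(v) the Fitch set of the subtree below and
U(v) the Fitch set of the rest of the tree seen from that edge, the edge set
F = D & U if non-empty else D | U, and attaching a query with state q adds
exactly [q ∩ F = ∅] changes in that column. Both directions are computed in
one postorder plus one preorder sweep, so scoring all 2n-3 edges costs the
same as two full-tree Fitch passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from ._alphabet import AA_INDEX, encode_residues
from .phylo import Clade, PhyloTree, bipartition_key, _fitch_down, _leaf_states
from .refset import ReferenceAlignment

__all__ = [
    "QueryAlignment",
    "PlacementResult",
    "consensus_row",
    "align_query_to_reference",
    "place_query",
    "place_batch",
    "attach_query",
]


@dataclass
class QueryAlignment:
    """A query in reference alignment coordinates."""

    query_id: str
    residues: str  # length = reference n_columns, '-' where uncovered
    covered_columns: frozenset[int]  # masked columns carrying a residue
    source: str = "mapped"  # 'provided_aligned' | 'mapped'
    pct_identity: float | None = None  # identity to consensus over covered cols


@dataclass
class PlacementResult:
    """Best parsimony attachment of one query."""

    query_id: str
    best_edge: frozenset[str]  # canonical bipartition of the attachment edge
    delta_score: int
    tie_edges: list[frozenset[str]] = field(default_factory=list)
    covered_columns_count: int = 0
    assigned_group: str = "unclassified"

    @property
    def pendant_length(self) -> float:
        """Display-only pendant length: changes per covered column."""
        if not self.covered_columns_count:
            return 0.0
        return self.delta_score / self.covered_columns_count


def consensus_row(reference: ReferenceAlignment) -> str:
    """Column-wise modal unambiguous residue over the masked columns.

    Ties go to the alphabetically smallest residue. The returned string has
    one character per masked column, in mask order.
    """
    rows = [seq for _, seq in reference.rows]
    out = []
    for col in reference.mask_order:
        counts: dict[str, int] = {}
        for seq in rows:
            c = seq[col].upper()
            if c in AA_INDEX:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            raise ValueError(f"masked column {col} has no unambiguous residues")
        best = min(counts, key=lambda c: (-counts[c], c))
        out.append(best)
    return "".join(out)


def _semi_global_aligner(
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on both sequences: overhangs of the full-length
    # reference consensus beyond a partial fragment are not penalized
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def align_query_to_reference(
    query_seq: str,
    reference: ReferenceAlignment,
    query_id: str = "query",
    min_overlap: int = 50,
    scoring: tuple[float, float, float, float] = (1.0, 0.0, -5.0, -1.0),
) -> QueryAlignment:
    """Map an unaligned fragment into reference coordinates.

    The fragment is aligned semi-globally (no end penalties) against the
    reference consensus row over masked columns; each aligned fragment
    residue is written into the corresponding reference column. Fails with
    "insufficient overlap" when fewer than *min_overlap* masked columns are
    covered.
    """
    query_seq = query_seq.upper().replace("-", "").replace(".", "")
    if not query_seq:
        raise ValueError(f"query {query_id!r}: empty sequence")
    mask_order = reference.mask_order
    consensus = consensus_row(reference)
    aligner = _semi_global_aligner(*scoring)
    aln = aligner.align(consensus, query_seq)[0]
    row = ["-"] * reference.n_columns
    covered: set[int] = set()
    matches = 0
    target_blocks, query_blocks = aln.aligned
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        for ti, qi in zip(range(t0, t1), range(q0, q1)):
            col = mask_order[ti]
            row[col] = query_seq[qi]
            covered.add(col)
            if query_seq[qi] == consensus[ti]:
                matches += 1
    if len(covered) < min_overlap:
        raise ValueError(
            f"query {query_id!r}: insufficient overlap "
            f"({len(covered)} < {min_overlap} masked columns)"
        )
    return QueryAlignment(
        query_id=query_id,
        residues="".join(row),
        covered_columns=frozenset(covered),
        source="mapped",
        pct_identity=100.0 * matches / len(covered),
    )


def query_from_aligned(
    query_id: str, aligned_residues: str, reference: ReferenceAlignment
) -> QueryAlignment:
    """Wrap a query already provided in reference coordinates."""
    if len(aligned_residues) != reference.n_columns:
        raise ValueError(
            f"aligned query {query_id!r} has {len(aligned_residues)} columns, "
            f"reference has {reference.n_columns}"
        )
    covered = frozenset(
        c for c in reference.mask for aa in [aligned_residues[c].upper()] if aa in AA_INDEX
    )
    return QueryAlignment(query_id, aligned_residues.upper(), covered, "provided_aligned")


def _edge_state_sets(
    tree: PhyloTree, leaf_states: Mapping[str, np.ndarray]
) -> dict[Clade, np.ndarray]:
    """Per-edge Fitch sets F(edge) used by the attachment delta formula."""
    down, _ = _fitch_down(tree, leaf_states)
    up: dict[Clade, np.ndarray] = {}
    edge_sets: dict[Clade, np.ndarray] = {}
    for node in tree.preorder():
        parts_base = [] if node is tree.root else [up[node]]
        for child in node.children:
            parts = parts_base + [down[c] for c in node.children if c is not child]
            state = parts[0]
            for s in parts[1:]:
                inter = state & s
                state = np.where(inter == 0, state | s, inter)
            up[child] = state
    for node in tree.preorder():
        if node is tree.root:
            continue
        inter = down[node] & up[node]
        edge_sets[node] = np.where(inter == 0, down[node] | up[node], inter)
    return edge_sets


def place_query(
    reference_tree: PhyloTree,
    reference_alignment: ReferenceAlignment,
    query_alignment: QueryAlignment,
    extra_rows: Mapping[str, str] | None = None,
) -> PlacementResult:
    """Attach one query to the minimal-parsimony edge of the reference tree.

    Scoring is restricted to the query's covered masked columns. Ties share
    the minimal delta; the reported best edge is the first tie in preorder
    (deterministic). *extra_rows* supplies alignment rows for leaves not in
    the reference alignment (sequential-mode insertions).
    """
    covered = sorted(query_alignment.covered_columns)
    if not covered:
        raise ValueError(f"query {query_alignment.query_id!r}: no covered columns")
    if not query_alignment.covered_columns <= reference_alignment.mask:
        raise ValueError("covered columns outside the reference mask")
    rows = {rid: seq for rid, seq in reference_alignment.rows}
    if extra_rows:
        rows.update(extra_rows)
    missing = set(reference_tree.leaf_names) - set(rows)
    if missing:
        raise ValueError(f"tree leaves without alignment rows: {sorted(missing)}")
    leaf_states = _leaf_states(rows, covered)
    q_state = encode_residues(query_alignment.residues)[np.asarray(covered)]
    edge_sets = _edge_state_sets(reference_tree, leaf_states)

    all_leaves = frozenset(reference_tree.leaf_names)
    below = reference_tree.leafsets()
    deltas: list[tuple[frozenset[str], int]] = []
    for node in reference_tree.preorder():
        if node is reference_tree.root:
            continue
        delta = int(((q_state & edge_sets[node]) == 0).sum())
        deltas.append((bipartition_key(below[node], all_leaves), delta))
    best_delta = min(d for _, d in deltas)
    ties = [key for key, d in deltas if d == best_delta]
    return PlacementResult(
        query_id=query_alignment.query_id,
        best_edge=ties[0],
        delta_score=best_delta,
        tie_edges=ties,
        covered_columns_count=len(covered),
    )


def attach_query(
    tree: PhyloTree,
    edge: frozenset[str],
    query_id: str,
    pendant_length: float = 0.0,
    restrict_to: frozenset[str] | None = None,
) -> PhyloTree:
    """Return a copy of *tree* with a new leaf attached on *edge*.

    The edge is split at its midpoint by a new internal node carrying the
    query leaf; every bipartition of the input tree is preserved. When the
    tree already contains extra leaves (earlier insertions), *restrict_to*
    names the leaf universe on which *edge* was defined; the first preorder
    edge whose bipartition restricted to that universe matches is used.
    """
    out = tree.copy()
    universe = restrict_to or frozenset(out.leaf_names)
    below = out.leafsets()
    parents = out.parent_map()
    target = None
    for node in out.preorder():
        if node is out.root:
            continue
        side = below[node] & universe
        if not side or side == universe:
            continue
        if bipartition_key(side, universe) == edge:
            target = node
            break
    if target is None:
        raise ValueError(f"edge {sorted(edge)} not found in tree")
    parent = parents[target]
    half = (target.length or 0.0) / 2.0
    leaf = Clade(name=query_id, length=pendant_length)
    joint = Clade(length=half, children=[target, leaf])
    target.length = half
    parent.children[parent.children.index(target)] = joint
    return out


def place_batch(
    reference_tree: PhyloTree,
    reference_alignment: ReferenceAlignment,
    queries: Sequence[QueryAlignment],
    mode: str = "independent",
) -> tuple[list[PlacementResult], PhyloTree, list[tuple[str, str]]]:
    """Place many queries; returns (results, extended tree, failures).

    ``independent`` (default): every query is scored against the pristine
    reference, so results are order-invariant; the returned tree has all
    successfully placed queries attached at their reference edges for
    display. ``sequential``: each accepted query is attached before the next
    is scored, mimicking interactive insertion tools; results then depend on
    input order. Failures are collected as (query_id, reason) and do not
    abort the batch.
    """
    if mode not in ("independent", "sequential"):
        raise ValueError(f"unknown placement mode {mode!r}")
    results: list[PlacementResult] = []
    failures: list[tuple[str, str]] = []
    tree = reference_tree.copy()
    ref_leaves = frozenset(reference_tree.leaf_names)
    extra_rows: dict[str, str] = {}
    for query in queries:
        try:
            if mode == "independent":
                res = place_query(reference_tree, reference_alignment, query)
                tree = attach_query(
                    tree, res.best_edge, query.query_id, res.pendant_length,
                    restrict_to=ref_leaves,
                )
            else:
                res = place_query(tree, reference_alignment, query, extra_rows=extra_rows)
                tree = attach_query(tree, res.best_edge, query.query_id, res.pendant_length)
                extra_rows[query.query_id] = query.residues
            results.append(res)
        except ValueError as exc:
            failures.append((query.query_id, str(exc)))
    return results, tree, failures
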