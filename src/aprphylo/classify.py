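"""Named reference groups, OTU assignment, and clone-count tables.

Curators partition reference leaves into named phylogenetic groups (for
aprA: reductive groups Re1, Re2, ... and oxidative groups Ox1, Ox2, ...).
Each group is realized on the reference tree as the clade spanned by its
members under a canonical rooting (midpoint of the longest edge); a query
placed on any edge inside that clade — including the clade's stem edge — is
assigned to the group, while attachments on edges separating groups or
outside every clade stay "unclassified". Assignments are aggregated
clone-wise into a groups x libraries count table with per-library
reductive/oxidative fractions, and two classification strategies can be
compared OTU-by-OTU for concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .otu import OtuPartition
from .phylo import PhyloTree, bipartition_key, root_on_longest_edge
from .placement import PlacementResult

__all__ = [
    "GroupDefinition",
    "define_groups",
    "assign_group",
    "group_count_table",
    "classification_concordance",
    "assign_by_membership",
]


@dataclass
class GroupDefinition:
    """A named group realized as an edge set on the reference tree."""

    group_name: str
    member_leaves: frozenset[str]
    role: str  # 'reductive' | 'oxidative'
    clade_leaves: frozenset[str]  # leaves under the MRCA (may exceed members)
    edges: frozenset[frozenset[str]]  # canonical bipartition keys incl. stem
    monophyletic: bool = True


def roles_from_group_names(group_names: Sequence[str]) -> dict[str, str]:
    """Re* -> reductive, Ox* -> oxidative (the aprA naming convention)."""
    return {
        g: "reductive" if g.startswith("Re") else "oxidative" for g in group_names
    }


def define_groups(
    reference_tree: PhyloTree,
    leaf_to_group: Mapping[str, str],
    roles: Mapping[str, str] | None = None,
) -> list[GroupDefinition]:
    """Realize named groups as MRCA clades on the canonically rooted tree.

    The tree is rooted at the midpoint of its longest edge; each group's
    clade is the subtree under the MRCA of its member leaves, and its edge
    set contains every edge inside that subtree plus the stem edge. A group
    whose MRCA clade contains leaves of another group (or ungrouped leaves)
    is kept but flagged non-monophyletic with a warning.
    """
    if not leaf_to_group:
        raise ValueError("empty group map")
    tree_leaves = set(reference_tree.leaf_names)
    unknown = set(leaf_to_group) - tree_leaves
    if unknown:
        raise ValueError(f"group map mentions non-tree leaves: {sorted(unknown)}")
    groups: dict[str, set[str]] = {}
    for leaf, group in leaf_to_group.items():
        groups.setdefault(group, set()).add(leaf)
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
    roles = roles or roles_from_group_names(list(groups))
    rooted = root_on_longest_edge(reference_tree)
    below = rooted.leafsets()
    all_leaves = frozenset(rooted.leaf_names)

    definitions = []
    for name in sorted(groups):
        members = frozenset(groups[name])
        # MRCA: deepest node whose leafset contains all members
        mrca = rooted.root
        changed = True
        while changed:
            changed = False
            for child in mrca.children:
                if members <= below[child]:
                    mrca, changed = child, True
                    break
        clade_leaves = below[mrca]
        foreign = clade_leaves - members
        monophyletic = not foreign
        if foreign:
            warnings.warn(
                f"group {name!r} is not monophyletic: MRCA clade also contains "
                f"{sorted(foreign)}"
            )
        edges = set()
        if mrca is not rooted.root:
            edges.add(bipartition_key(clade_leaves, all_leaves))  # stem edge
        stack = list(mrca.children)
        while stack:
            node = stack.pop()
            edges.add(bipartition_key(below[node], all_leaves))
            stack.extend(node.children)
        definitions.append(
            GroupDefinition(
                group_name=name,
                member_leaves=members,
                role=roles.get(name, "unknown"),
                clade_leaves=clade_leaves,
                edges=frozenset(edges),
                monophyletic=monophyletic,
            )
        )
    return definitions


def assign_group(
    placement_result: PlacementResult,
    group_definitions: Sequence[GroupDefinition],
) -> str:
    """Group of the attachment edge, or "unclassified".

    The query belongs to a group iff its attachment edge lies within exactly
    one group's clade edge set (stem edge included). When a non-monophyletic
    outer group's MRCA clade swallows an inner group, edges of the inner
    clade hit both definitions; the most specific (innermost) clade wins
    provided the hits form a nested chain. Edges separating groups, inside
    none, or hitting incomparable clades give "unclassified". Depends only
    on the edge and the definitions, so group order is irrelevant.
    """
    edge = placement_result.best_edge
    hits = [g for g in group_definitions if edge in g.edges]
    if not hits:
        return "unclassified"
    if len(hits) == 1:
        return hits[0].group_name
    hits.sort(key=lambda g: (len(g.clade_leaves), g.group_name))
    innermost = hits[0]
    if all(innermost.clade_leaves < g.clade_leaves for g in hits[1:]):
        return innermost.group_name
    return "unclassified"


def assign_by_membership(
    tree: PhyloTree,
    query_id: str,
    group_definitions: Sequence[GroupDefinition],
    reference_leaves: frozenset[str],
) -> str:
    """Classify a query leaf of a de-novo tree by its smallest reference clade.

    Walking from the query leaf toward the root, the first ancestor whose
    subtree contains reference leaves decides: if all of them belong to one
    group, that group; otherwise "unclassified". Used for the comparison
    tree built directly from partial sequences.
    """
    member_of = {
        leaf: g.group_name for g in group_definitions for leaf in g.member_leaves
    }
    parents = tree.parent_map()
    below = tree.leafsets()
    node = next((n for n in tree.leaves() if n.name == query_id), None)
    if node is None:
        raise ValueError(f"query {query_id!r} not in tree")
    while node in parents:
        node = parents[node]
        refs = below[node] & reference_leaves
        if refs:
            labels = {member_of.get(leaf) for leaf in refs}
            if len(labels) == 1 and None not in labels:
                return labels.pop()
            return "unclassified"
    return "unclassified"


def group_count_table(
    assignments: Mapping[str, str],
    otu_partition: OtuPartition,
    clone_library: Mapping[str, str],
    group_definitions: Sequence[GroupDefinition] | None = None,
) -> pd.DataFrame:
    """Clone counts per (group, library) with reductive/oxidative fractions.

    *assignments* maps OTU_id -> group name; *clone_library* maps clone_id
    -> library name. Counts are aggregated clone-wise (an OTU of 5 clones
    contributes 5 to its group's cell). Clones without a library are counted
    under "unknown_library" with a warning. The returned frame has groups
    (plus "unclassified") as rows, libraries as columns, and appends
    fraction rows computed from group roles when definitions are given.
    """
    counts: dict[tuple[str, str], int] = {}
    for otu_id, members in otu_partition.clusters.items():
        group = assignments.get(otu_id, "unclassified")
        for clone in members:
            library = clone_library.get(clone)
            if library is None:
                warnings.warn(f"clone {clone!r} has no library of origin")
                library = "unknown_library"
            counts[(group, library)] = counts.get((group, library), 0) + 1
    table = (
        pd.Series(counts, dtype=int)
        .rename_axis(["group", "library"])
        .unstack(fill_value=0)
        .sort_index()
    )
    if group_definitions is not None:
        role_of = {g.group_name: g.role for g in group_definitions}
        classified = table.loc[[g for g in table.index if g in role_of]]
        totals = classified.sum(axis=0)
        for role in ("reductive", "oxidative"):
            members = [g for g in classified.index if role_of[g] == role]
            frac = classified.loc[members].sum(axis=0) / totals.replace(0, pd.NA)
            table.loc[f"fraction_{role}"] = frac
    return table


def classification_concordance(
    assignments_a: Mapping[str, str],
    assignments_b: Mapping[str, str],
) -> tuple[float, pd.DataFrame]:
    """Fraction of OTUs labeled identically by two strategies, plus diffs."""
    if set(assignments_a) != set(assignments_b):
        raise ValueError("OTU id sets differ between assignments")
    if not assignments_a:
        raise ValueError("empty assignments")
    diffs = [
        {"OTU_id": otu, "assignment_a": assignments_a[otu], "assignment_b": assignments_b[otu]}
        for otu in sorted(assignments_a)
        if assignments_a[otu] != assignments_b[otu]
    ]
    fraction = 1.0 - len(diffs) / len(assignments_a)
    return fraction, pd.DataFrame(diffs, columns=["OTU_id", "assignment_a", "assignment_b"])
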