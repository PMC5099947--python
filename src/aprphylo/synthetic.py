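"""Seeded synthetic data with the statistical structure the pipeline assumes.

Four generators, all fully deterministic given a seed:

* a labeled reference tree with protein sequences evolved along it under a
  uniform-replacement (Poisson) substitution model, with named monophyletic
  Re*/Ox* groups planted as clades;
* partial query fragments cut from reference leaves with a controlled
  substitution rate, emulating environmental amplicon fragments;
* nucleotide clone libraries back-translated from well-separated amino-acid
  centers with controlled intra-center divergence (planted OTU structure);
* primer binding sites planted with an exact number of mismatching bases.

Every generator also emits a truth table sufficient to score the downstream
stage without external data. Defaults are desk-scale versions of a curated
reference set (tens of taxa, 82 + 503 = 585 columns mirroring the two
subunit widths, ~110-column fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from ._alphabet import AA_LETTERS
from .otu import CloneLibrary
from .phylo import Clade, PhyloTree, pairwise_distance
from .primer import IUPAC_SETS, PrimerSpec, best_site_mismatches
from .refset import ReferenceAlignment

__all__ = [
    "SimulationConfig",
    "simulate_reference_set",
    "evolve_queries",
    "synthesize_clone_library",
    "random_centers",
    "plant_primer_site",
    "back_translate",
]

#: amino acid -> codons, deterministic order
CODONS_FOR: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    CODONS_FOR.setdefault(_aa, ())
    CODONS_FOR[_aa] = CODONS_FOR[_aa] + (_codon,)


@dataclass
class LibrarySpec:
    """Plan for one synthetic clone library."""

    library_name: str
    n_clones: int = 40
    intra_otu_divergence: float = 0.005
    n_centers: int = 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic reference set and libraries."""

    seed: int = 0
    n_taxa: int = 32
    branch_length_mean: float = 0.08  # substitutions per site per edge
    n_groups: int = 6
    n_sites_b: int = 82  # comparable AprB columns
    n_sites_a: int = 503  # comparable AprA columns
    fragment_length: int = 110  # masked columns per query fragment
    clone_library_spec: list[LibrarySpec] = field(
        default_factory=lambda: [
            LibrarySpec("libA", 40, 0.005, 5),
            LibrarySpec("libB", 40, 0.005, 5),
            LibrarySpec("libC", 40, 0.005, 5),
        ]
    )
    primer_plant_spec: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_groups < 1 or self.n_groups > self.n_taxa // 2:
            raise ValueError("n_groups must leave >= 2 taxa per group")
        for spec in self.clone_library_spec:
            if spec.n_clones < 1 or spec.n_centers < 1:
                raise ValueError("library spec counts must be positive")
            if not 0 <= spec.intra_otu_divergence < 1:
                raise ValueError("divergence must be in [0, 1)")

    @property
    def n_sites(self) -> int:
        return self.n_sites_b + self.n_sites_a


def _random_rooted_subtree(
    leaf_names: Sequence[str], rng: np.random.Generator, bl_mean: float
) -> Clade:
    nodes = [Clade(name=n, length=float(rng.exponential(bl_mean))) for n in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = Clade(
            length=float(rng.exponential(bl_mean)), children=[nodes[i], nodes[j]]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    return nodes[0]


def _unroot(root: Clade) -> Clade:
    """Collapse a degree-2 root into a trifurcating root (unrooted binary)."""
    a, b = root.children
    inner = b if b.children else a
    outer = a if inner is b else b
    if not inner.children:
        raise ValueError("cannot unroot a 2-leaf tree")
    outer.length = (outer.length or 0.0) + (inner.length or 0.0)
    return Clade(children=[outer] + inner.children)


def _evolve(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for _ in range(n_sub):
        site = int(rng.integers(0, len(out)))
        out[site] = (out[site] + 1 + int(rng.integers(0, 19))) % 20
    return out


def simulate_reference_set(
    config: SimulationConfig,
) -> tuple[PhyloTree, ReferenceAlignment, dict[str, str]]:
    """Reference tree + alignment + leaf -> group map, all from one seed.

    The topology is built by random pairwise joining within each group and
    along a backbone connecting group subtrees, so the n_groups Re*/Ox*
    groups (alternating reductive/oxidative labels) are monophyletic by
    construction. Backbone edges are drawn three times longer than
    within-group edges so the separation between groups dominates. Sequences
    evolve from a random ancestral protein with Poisson(branch length x
    sites) substitutions per edge, each to a uniformly chosen different
    residue.
    """
    rng = np.random.default_rng(config.seed)
    sizes = [
        config.n_taxa // config.n_groups
        + (1 if g < config.n_taxa % config.n_groups else 0)
        for g in range(config.n_groups)
    ]
    group_map: dict[str, str] = {}
    subtrees = []
    for g, size in enumerate(sizes):
        name = f"{'Re' if g % 2 == 0 else 'Ox'}{g // 2 + 1}"
        leaves = [f"{name}_L{j + 1:02d}" for j in range(size)]
        for leaf in leaves:
            group_map[leaf] = name
        subtrees.append(_random_rooted_subtree(leaves, rng, config.branch_length_mean))
    backbone_mean = 3.0 * config.branch_length_mean
    nodes = list(subtrees)
    for node in nodes:
        node.length = float(rng.exponential(backbone_mean))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = Clade(
            length=float(rng.exponential(backbone_mean)), children=[nodes[i], nodes[j]]
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    tree = PhyloTree(_unroot(nodes[0]) if len(nodes[0].children) == 2 else nodes[0])

    letters = np.frombuffer(AA_LETTERS.encode(), dtype=np.uint8)
    ancestral = rng.integers(0, 20, size=config.n_sites)
    seqs: dict[str, str] = {}

    def descend(node: Clade, seq: np.ndarray) -> None:
        for child in node.children:
            n_sub = int(rng.poisson((child.length or 0.0) * config.n_sites))
            child_seq = _evolve(seq, n_sub, rng)
            if child.is_leaf:
                seqs[child.name] = letters[child_seq].tobytes().decode()
            else:
                descend(child, child_seq)

    descend(tree.root, ancestral)
    rows = [(name, seqs[name]) for name in tree.leaf_names]
    alignment = ReferenceAlignment(
        rows,
        config.n_sites,
        frozenset(range(config.n_sites)),
        "concatenated",
        boundary=config.n_sites_b,
    )
    return tree, alignment, group_map


def evolve_queries(
    reference: ReferenceAlignment,
    fragment_length: int,
    divergence: float,
    n_queries: int,
    seed: int,
    group_map: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Partial fragments cut from reference leaves with planted substitutions.

    Each query is a contiguous window of *fragment_length* masked columns
    from a uniformly chosen leaf, with each residue substituted (to a
    uniformly chosen different one) with probability *divergence*. Returns
    (queries, truth table with source leaf, group, window and substitution
    count).
    """
    if divergence >= 0.5:
        raise ValueError("divergence >= 0.5 breaks the placement-recovery regime")
    masked = reference.masked_rows()
    n_masked = len(next(iter(masked.values())))
    if fragment_length > n_masked:
        raise ValueError("fragment_length exceeds masked columns")
    rng = np.random.default_rng(seed)
    ids = list(masked)
    queries: list[tuple[str, str]] = []
    truth_rows = []
    for i in range(n_queries):
        leaf = ids[int(rng.integers(0, len(ids)))]
        start = int(rng.integers(0, n_masked - fragment_length + 1))
        frag = list(masked[leaf][start : start + fragment_length])
        n_sub = 0
        for pos in range(fragment_length):
            if rng.random() < divergence:
                choices = [a for a in AA_LETTERS if a != frag[pos]]
                frag[pos] = choices[int(rng.integers(0, len(choices)))]
                n_sub += 1
        qid = f"q{i + 1:04d}"
        queries.append((qid, "".join(frag)))
        truth_rows.append(
            {
                "query_id": qid,
                "source_leaf": leaf,
                "group": group_map.get(leaf, "") if group_map else "",
                "window_start": start,
                "n_substitutions": n_sub,
            }
        )
    return queries, pd.DataFrame(truth_rows)


def random_centers(
    n_centers: int,
    length: int,
    seed: int,
    divergence: float = 0.15,
    min_separation: float = 0.05,
) -> list[str]:
    """Well-separated amino-acid center sequences.

    Centers are derived from one random base sequence by independent
    substitution at rate *divergence* per site, giving expected pairwise
    p-distance ~ 2 x divergence; generation retries until every pair is
    separated by more than *min_separation*.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        base = "".join(AA_LETTERS[int(i)] for i in rng.integers(0, 20, size=length))
        centers = []
        for _ in range(n_centers):
            seq = list(base)
            for pos in range(length):
                if rng.random() < divergence:
                    choices = [a for a in AA_LETTERS if a != seq[pos]]
                    seq[pos] = choices[int(rng.integers(0, len(choices)))]
            centers.append("".join(seq))
        ok = all(
            pairwise_distance(a, b, model="p")[0] > min_separation
            for i, a in enumerate(centers)
            for b in centers[i + 1 :]
        )
        if ok:
            return centers
    raise RuntimeError("could not generate separated centers")


def back_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly chosen synonymous codons."""
    codons = []
    for aa in aa_seq:
        options = CODONS_FOR[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def synthesize_clone_library(
    aa_centers: Sequence[str],
    n_clones: int,
    intra_divergence: float,
    seed: int,
    library_name: str = "lib",
    min_separation: float = 0.04,
) -> tuple[CloneLibrary, dict[str, int]]:
    """Nucleotide clone library with planted OTU structure.

    Clones are assigned to centers round-robin (every center receives at
    least one clone when n_clones >= n_centers), the center's amino-acid
    sequence is mutated at rate *intra_divergence* per site — with the
    per-clone substitution count capped at floor(2 x rate x length) so that
    intra-center pairwise divergence stays bounded and the planted OTU
    structure is exact — and the result is back-translated with random
    synonymous codons, so translation in the correct frame has no internal
    stops by construction. Returns the library and the truth partition
    clone_id -> center index.
    """
    centers = [c.upper() for c in aa_centers]
    for i, a in enumerate(centers):
        for b in centers[i + 1 :]:
            d, _ = pairwise_distance(a, b, model="p")
            if d <= min_separation:
                raise ValueError(
                    f"centers too close (p={d:.4f} <= {min_separation}); "
                    "planted OTU structure would be ambiguous"
                )
    if 2 * intra_divergence >= min_separation:
        raise ValueError("intra-center divergence unattainable given separation")
    rng = np.random.default_rng(seed)
    clones: list[tuple[str, str]] = []
    truth: dict[str, int] = {}
    length = len(centers[0])
    max_sub = int(2 * intra_divergence * length) if intra_divergence > 0 else 0
    for i in range(n_clones):
        center_idx = i % len(centers)
        aa = list(centers[center_idx])
        n_sub = min(int(rng.binomial(length, intra_divergence)), max_sub)
        for pos in rng.choice(length, size=n_sub, replace=False):
            pos = int(pos)
            choices = [x for x in AA_LETTERS if x != aa[pos]]
            aa[pos] = choices[int(rng.integers(0, len(choices)))]
        cid = f"{library_name}_c{i + 1:03d}"
        clones.append((cid, back_translate("".join(aa), rng)))
        truth[cid] = center_idx
    return CloneLibrary(library_name, clones), truth


#: synthetic 21-nt degenerate primer pair used by the input-bundle generator
DEFAULT_FW_PRIMER = ("syn-fw", "TGGCARGGNTTYCARCCNATG", "forward")
DEFAULT_RV_PRIMER = ("syn-rv", "GCNGTRTANCCRTCNACYTCN", "reverse")

#: masked-column offset of the synthetic amplicon window inside AprA
AMPLICON_OFFSET_IN_A = 150


def write_input_bundle(config: SimulationConfig, out_dir) -> dict:
    """Emit a complete, self-consistent synthetic input set for the pipeline.

    Writes reference subunit FASTAs, metadata and group-map TSVs, per-library
    clone FASTAs wrapped in planted primer sites, a library manifest, truth
    tables, and a ready-to-run ``config.yaml``. Clone centers are amplicon
    windows (fixed offset inside the AprA part of the alignment) cut from
    leaves of distinct groups, so OTU truth and group truth agree. Returns a
    dict of the generated paths plus truth tables.
    """
    import yaml
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, alignment, group_map = simulate_reference_set(config)
    boundary = alignment.boundary
    with open(out / "ref_B.fasta", "w") as fb, open(out / "ref_A.fasta", "w") as fa:
        for rid, seq in alignment.rows:
            fb.write(f">{rid}\n{seq[:boundary]}\n")
            fa.write(f">{rid}\n{seq[boundary:]}\n")
    roles = {"Re": ("reductive", "unknown"), "Ox": ("oxidative", "II")}
    meta_rows = []
    group_rows = []
    for rid, _ in alignment.rows:
        group = group_map[rid]
        role, lineage = roles[group[:2]]
        meta_rows.append(
            {
                "record_id": rid,
                "organism": f"Synthetica sp. {rid}",
                "taxonomy": "Bacteria;Synthetica",
                "role": role,
                "lineage": lineage,
            }
        )
        group_rows.append({"record_id": rid, "group_name": group, "role": role})
    pd.DataFrame(meta_rows).to_csv(out / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(group_rows).to_csv(out / "groups.tsv", sep="\t", index=False)
    tree.write(out / "true_tree.nwk")

    fw = PrimerSpec(*DEFAULT_FW_PRIMER)
    rv = PrimerSpec(*DEFAULT_RV_PRIMER)
    plant_k = dict(config.primer_plant_spec)
    rng = np.random.default_rng(config.seed + 1)
    masked = alignment.masked_rows()
    leaves = list(masked)
    win_start = config.n_sites_b + AMPLICON_OFFSET_IN_A
    if win_start + config.fragment_length > config.n_sites:
        raise ValueError("amplicon window does not fit inside the AprA columns")
    manifest_rows = []
    truth_rows = []
    for li, spec in enumerate(config.clone_library_spec):
        lib = None
        center_leaves: list[str] = []
        for _ in range(20):  # retry until centers are separated enough
            # prefer leaves from distinct groups for well-separated centers
            by_group: dict[str, list[str]] = {}
            for leaf in leaves:
                by_group.setdefault(group_map[leaf], []).append(leaf)
            pool = []
            order = sorted(by_group)
            k = 0
            while len(pool) < spec.n_centers:
                g = order[k % len(order)]
                candidates = [x for x in by_group[g] if x not in pool]
                if candidates:
                    pool.append(candidates[int(rng.integers(0, len(candidates)))])
                k += 1
            centers = [
                masked[leaf][win_start : win_start + config.fragment_length]
                for leaf in pool
            ]
            try:
                lib, truth = synthesize_clone_library(
                    centers,
                    spec.n_clones,
                    spec.intra_otu_divergence,
                    seed=config.seed + 100 + li,
                    library_name=spec.library_name,
                )
                center_leaves = pool
                break
            except ValueError:
                continue
        if lib is None:
            raise RuntimeError(
                f"could not build library {spec.library_name!r} with separated centers"
            )
        wrapped = []
        for ci, (cid, nt) in enumerate(lib.clones):
            template = "A" * len(fw) + nt + "A" * len(rv)
            template = plant_primer_site(
                template, fw, plant_k.get(fw.name, 0), 0, seed=config.seed + 1000 + li * 997 + ci
            )
            template = plant_primer_site(
                template, rv, plant_k.get(rv.name, 0), len(template) - len(rv),
                seed=config.seed + 2000 + li * 997 + ci,
            )
            wrapped.append((cid, template))
            truth_rows.append(
                {
                    "clone_id": cid,
                    "library": spec.library_name,
                    "center_index": truth[cid],
                    "center_leaf": center_leaves[truth[cid]],
                    "group": group_map[center_leaves[truth[cid]]],
                }
            )
        fasta = out / f"{spec.library_name}.fasta"
        with open(fasta, "w") as fh:
            for cid, nt in wrapped:
                fh.write(f">{cid}\n{nt}\n")
        manifest_rows.append(
            {
                "library_name": spec.library_name,
                "fasta_path": fasta.name,
                "site": f"synthetic site {li + 1}",
                "depth": "",
                "date": "",
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(out / "truth_clones.tsv", sep="\t", index=False)

    config_doc = {
        "output_dir": "run",
        "reference": {
            "fasta_b": "ref_B.fasta",
            "fasta_a": "ref_A.fasta",
            "metadata": "metadata.tsv",
            # synthetic sequences are exactly the comparable columns long,
            # so the length gates sit just below those widths
            "thresholds": [config.n_sites_b - 1, config.n_sites_a - 1,
                           max(1, config.n_sites_a // 4)],
        },
        "tree": {
            "model": "poisson",
            "overlay_model": "p",
            "bootstrap_reps": 100,
            "seed": config.seed + 11,
        },
        "placement": {"mode": "independent", "min_overlap": 50},
        "otu": {"cutoff": 0.02, "linkage": "average", "seed": config.seed + 12},
        "primers": {
            "forward": {"name": fw.name, "seq": fw.iupac_seq, "orientation": "forward"},
            "reverse": {"name": rv.name, "seq": rv.iupac_seq, "orientation": "reverse"},
            "max_mismatch": 3,
        },
        "libraries": {"manifest": "manifest.tsv"},
        "groups": {"map": "groups.tsv"},
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config_doc, sort_keys=False))
    return {
        "config": out / "config.yaml",
        "tree": tree,
        "alignment": alignment,
        "group_map": group_map,
        "truth_clones": truth_df,
    }


def plant_primer_site(
    nt_seq: str,
    primer: PrimerSpec,
    k_mismatches: int,
    position: int,
    seed: int,
    max_attempts: int = 100,
) -> str:
    """Overwrite a window of *nt_seq* with a site carrying exactly k mismatches.

    A concrete realization of the primer's degenerate expansion is written
    at *position* (0-based, on the strand the primer anneals to after
    orientation handling), then exactly *k_mismatches* positions are flipped
    to bases outside the corresponding IUPAC set. If a better incidental
    window elsewhere makes the best-site count come out below k, the
    realization is re-drawn; exact equality is verified before returning.
    """
    nt_seq = nt_seq.upper()
    plen = len(primer)
    if not 0 <= k_mismatches <= plen:
        raise ValueError("k_mismatches out of range")
    if not 0 <= position <= len(nt_seq) - plen:
        raise ValueError("position out of range")
    mutable = [
        i for i, code in enumerate(primer.iupac_seq) if len(IUPAC_SETS[code]) < 4
    ]
    if len(mutable) < k_mismatches:
        raise ValueError(
            f"cannot plant {k_mismatches} mismatches: only {len(mutable)} "
            "non-degenerate-N positions"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        site = [
            sorted(IUPAC_SETS[code])[int(rng.integers(0, len(IUPAC_SETS[code])))]
            for code in primer.iupac_seq
        ]
        picked = rng.choice(len(mutable), size=k_mismatches, replace=False)
        for idx in sorted(int(i) for i in picked):
            pos = mutable[idx]
            outside = sorted(set("ACGT") - IUPAC_SETS[primer.iupac_seq[pos]])
            site[pos] = outside[int(rng.integers(0, len(outside)))]
        realized = "".join(site)
        if primer.orientation == "reverse":
            realized = str(Seq(realized).reverse_complement())
        modified = nt_seq[:position] + realized + nt_seq[position + plen :]
        if best_site_mismatches(primer, modified).mismatches == k_mismatches:
            return modified
    raise RuntimeError(
        f"could not plant exactly {k_mismatches} mismatches in {max_attempts} attempts"
    )
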