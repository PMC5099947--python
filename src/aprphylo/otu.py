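"""Clone-library translation and OTU clustering.

Environmental aprA clone libraries arrive as nucleotide FASTA. Clones are
translated in the best reading frame, pairwise Poisson-corrected amino-acid
distances are computed (pairwise deletion over the shared amplicon region),
and the clones are grouped into operational taxonomic units (OTUs) by
agglomerative clustering at a distance cutoff (default 0.02 substitutions
per site). One representative clone per OTU is drawn with a seeded RNG so
downstream placement works on a reproducible subset.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .phylo import DistanceMatrix

__all__ = [
    "CloneLibrary",
    "OtuPartition",
    "translate_best_frame",
    "translate_library",
    "cluster_otus",
    "pick_representatives",
]

FRAMES = (1, 2, 3, -1, -2, -3)
LINKAGES = ("furthest", "average", "nearest")


@dataclass
class CloneLibrary:
    """One clone library: named set of nucleotide sequences plus metadata."""

    library_name: str
    clones: list[tuple[str, str]]
    site: str = ""
    depth: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.clones]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate clone_ids in library {self.library_name!r}")

    @classmethod
    def from_fasta(cls, library_name: str, path: str | Path, **meta) -> "CloneLibrary":
        clones = [(e.id, str(e.seq).upper()) for e in SeqIO.parse(str(path), "fasta")]
        return cls(library_name, clones, **meta)


@dataclass
class OtuPartition:
    """OTU clustering of clones at a distance cutoff."""

    cutoff: float
    linkage: str
    clusters: dict[str, tuple[str, ...]]  # OTU_id -> member clone_ids
    representatives: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        members = list(itertools.chain.from_iterable(self.clusters.values()))
        if len(members) != len(set(members)):
            raise ValueError("clusters overlap: not a partition")
        for otu, rep in self.representatives.items():
            if rep not in self.clusters[otu]:
                raise ValueError(f"representative {rep!r} not a member of {otu}")

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    def otu_of(self) -> dict[str, str]:
        return {cid: otu for otu, cids in self.clusters.items() for cid in cids}

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "OTU_id": otu,
                "size": len(cids),
                "members": ",".join(cids),
                "representative": self.representatives.get(otu, ""),
            }
            for otu, cids in self.clusters.items()
        ]
        return pd.DataFrame(rows, columns=["OTU_id", "size", "members", "representative"])

    def write_list_format(self, path: str | Path) -> None:
        """mothur-style list export: cutoff, n_otus, comma-joined clusters."""
        clusters = "\t".join(",".join(cids) for cids in self.clusters.values())
        Path(path).write_text(f"{self.cutoff:g}\t{self.n_otus}\t{clusters}\n")


def translate_best_frame(nt_seq: str, frame: int | str = "auto") -> tuple[str, int]:
    """Translate with the standard code; returns (protein, frame used).

    Frames are 1..3 on the given strand and -1..-3 on the reverse
    complement; trailing partial codons are dropped. ``auto`` picks the
    frame with the fewest internal stop codons, ties going to the
    lowest-numbered forward frame (+1, +2, +3, -1, -2, -3).
    """
    nt_seq = nt_seq.upper().replace("U", "T")

    def translate(fr: int) -> str:
        seq = nt_seq if fr > 0 else str(Seq(nt_seq).reverse_complement())
        offset = abs(fr) - 1
        trimmed = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
        return str(Seq(trimmed).translate())

    if frame == "auto":
        best_fr, best_stops = None, None
        for fr in FRAMES:
            aa = translate(fr)
            stops = aa[:-1].count("*")  # a stop in the final codon is terminal
            if best_stops is None or stops < best_stops:
                best_fr, best_stops = fr, stops
        return translate(best_fr), best_fr
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame!r}")
    return translate(frame), frame


def translate_library(
    library: CloneLibrary, frame: int | str = "auto"
) -> tuple[dict[str, str], list[str]]:
    """Translate every clone; returns (clone_id -> protein, flagged ids).

    Clones whose best-frame translation still contains an internal stop are
    flagged (and excluded downstream by default) with a warning.
    """
    proteins: dict[str, str] = {}
    flagged: list[str] = []
    for cid, nt in library.clones:
        aa, _ = translate_best_frame(nt, frame)
        if "*" in aa[:-1]:
            flagged.append(cid)
            warnings.warn(
                f"clone {cid!r} ({library.library_name}): internal stop in best frame"
            )
        else:
            proteins[cid] = aa
    return proteins, flagged


def _linkage_distance(
    values: np.ndarray, a: Sequence[int], b: Sequence[int], linkage: str
) -> float:
    block = values[np.ix_(a, b)]
    if linkage == "furthest":
        return float(block.max())
    if linkage == "nearest":
        return float(block.min())
    return float(block.mean())


def cluster_otus(
    dm: DistanceMatrix, cutoff: float = 0.02, linkage: str = "average"
) -> OtuPartition:
    """Agglomerative OTU clustering at a distance cutoff.

    Repeatedly merges the pair of clusters with the smallest inter-cluster
    linkage distance while that distance is <= cutoff. Deterministic: ties
    are broken by the smallest (i, j) pair of each cluster's smallest member
    index. OTU ids are assigned by decreasing size, then by first member.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    clusters: list[list[int]] = [[i] for i in range(dm.n)]
    while len(clusters) > 1:
        best = None  # (dist, min_a, min_b, ia, ib)
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                dist = _linkage_distance(dm.values, clusters[ia], clusters[ib], linkage)
                key = (dist,) + tuple(sorted((min(clusters[ia]), min(clusters[ib]))))
                if best is None or key < best[0]:
                    best = (key, ia, ib)
        (dist, *_), ia, ib = best
        if dist > cutoff:
            break
        clusters[ia] = sorted(clusters[ia] + clusters[ib])
        del clusters[ib]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    width = max(3, len(str(len(clusters))))
    named = {
        f"OTU_{k + 1:0{width}d}": tuple(dm.ids[i] for i in members)
        for k, members in enumerate(clusters)
    }
    return OtuPartition(cutoff=cutoff, linkage=linkage, clusters=named)


def pick_representatives(partition: OtuPartition, seed: int) -> OtuPartition:
    """Draw one uniform random representative per OTU (seeded, reproducible)."""
    rng = np.random.default_rng(seed)
    reps = {}
    for otu in sorted(partition.clusters):
        members = partition.clusters[otu]
        reps[otu] = members[int(rng.integers(0, len(members)))]
    return OtuPartition(
        cutoff=partition.cutoff,
        linkage=partition.linkage,
        clusters=partition.clusters,
        representatives=reps,
        seed=seed,
    )
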