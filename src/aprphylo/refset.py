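"""Curation of the two-subunit AprB/AprA reference sequence set.

The reference set for adenylylsulfate reductase (APS reductase) consists of
aligned amino-acid sequences of the two subunits AprB (iron-sulfur subunit)
and AprA (FAD subunit), plus per-organism metadata: taxonomy, metabolic role
(reductive for sulfate reducers, oxidative for sulfur oxidizers) and Apr
lineage (I or II for oxidative-type sequences). This module reads that set,
partitions it into near-full-length "core" records and "shorter" records by
ungapped length thresholds, concatenates the two subunit alignments, and
masks alignment columns containing gaps or missing data so that downstream
distances and trees use only fully comparable positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._alphabet import AA_INDEX, normalize_gaps, ungapped_length

ROLES = ("reductive", "oxidative", "unknown")
LINEAGES = ("I", "II", "unknown")

#: characters allowed in a reference sequence after gap normalization
_ALLOWED = set(AA_INDEX) | set("XBZJUO*") | {"-"}

#: default ungapped-length thresholds, in residues:
#: (min AprB for core, min AprA for core, min AprA for shorter)
DEFAULT_THRESHOLDS = (101, 554, 118)

_SUBUNIT_SUFFIXES = {"_aprb": "B", "_apra": "A"}


@dataclass
class MarkerRecord:
    """One organism's AprB and/or AprA sequence(s) plus metadata."""

    record_id: str
    organism: str = ""
    taxonomy: tuple[str, ...] = ()
    role: str = "unknown"
    lineage: str = "unknown"
    seq_B: str | None = None
    seq_A: str | None = None
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.seq_B is None and self.seq_A is None:
            raise ValueError(f"record {self.record_id!r} has no sequence")
        if self.role not in ROLES:
            raise ValueError(f"record {self.record_id!r}: invalid role {self.role!r}")
        if self.lineage not in LINEAGES:
            raise ValueError(
                f"record {self.record_id!r}: invalid lineage {self.lineage!r}"
            )
        for attr in ("seq_B", "seq_A"):
            seq = getattr(self, attr)
            if seq is None:
                continue
            seq = normalize_gaps(seq)
            bad = set(seq) - _ALLOWED
            if bad:
                raise ValueError(
                    f"record {self.record_id!r} {attr}: invalid characters {sorted(bad)}"
                )
            setattr(self, attr, seq)

    def subunit_length(self, subunit: str) -> int:
        """Ungapped residue count of one subunit (0 if absent)."""
        seq = self.seq_B if subunit == "B" else self.seq_A
        return 0 if seq is None else ungapped_length(seq)


@dataclass
class ReferenceAlignment:
    """Fixed-coordinate amino-acid alignment with a retained-column mask.

    ``mask`` holds the indices of columns retained for analysis; a fresh
    alignment starts with every column retained. ``boundary`` is the column
    index where AprA starts in a concatenated B+A alignment.
    """

    rows: list[tuple[str, str]]
    n_columns: int
    mask: frozenset[int]
    subunit: str  # 'B' | 'A' | 'concatenated'
    boundary: int | None = None
    excluded_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for rid, seq in self.rows:
            if len(seq) != self.n_columns:
                raise ValueError(
                    f"row {rid!r} has {len(seq)} columns, expected {self.n_columns}"
                )
        if not set(self.mask) <= set(range(self.n_columns)):
            raise ValueError("mask contains out-of-range column indices")
        ids = [rid for rid, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record_id in alignment rows")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def mask_order(self) -> list[int]:
        """Retained column indices in ascending order."""
        return sorted(self.mask)

    def row(self, record_id: str) -> str:
        for rid, seq in self.rows:
            if rid == record_id:
                return seq
        raise KeyError(record_id)

    def masked_rows(self) -> dict[str, str]:
        """Rows restricted to the retained columns, in mask order."""
        cols = self.mask_order
        return {rid: "".join(seq[c] for c in cols) for rid, seq in self.rows}


@dataclass(frozen=True)
class SetPartition:
    """Disjoint, exhaustive split of records into core / shorter / rejected."""

    core: tuple[str, ...]
    shorter: tuple[str, ...]
    rejected: tuple[str, ...]
    thresholds: tuple[int, int, int]

    def table(self, records: Iterable[MarkerRecord]) -> pd.DataFrame:
        """Partition report: record_id, class, per-subunit ungapped lengths."""
        cls = {rid: "core" for rid in self.core}
        cls.update({rid: "shorter" for rid in self.shorter})
        cls.update({rid: "rejected" for rid in self.rejected})
        rows = [
            {
                "record_id": r.record_id,
                "class": cls[r.record_id],
                "len_B": r.subunit_length("B"),
                "len_A": r.subunit_length("A"),
            }
            for r in records
            if r.record_id in cls
        ]
        return pd.DataFrame(rows, columns=["record_id", "class", "len_B", "len_A"])


def _strip_subunit_suffix(fasta_id: str) -> str:
    low = fasta_id.lower()
    for suffix in _SUBUNIT_SUFFIXES:
        if low.endswith(suffix):
            return fasta_id[: -len(suffix)]
    return fasta_id


def read_metadata(path: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read the metadata TSV (record_id, organism, taxonomy, role, lineage)."""
    if isinstance(path, pd.DataFrame):
        meta = path.copy()
    else:
        meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"record_id", "organism", "taxonomy", "role", "lineage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if meta["record_id"].duplicated().any():
        dups = meta.loc[meta["record_id"].duplicated(), "record_id"].tolist()
        raise ValueError(f"duplicate record_id in metadata: {dups}")
    return meta


def read_sequence_set(
    fasta_paths: Mapping[str, str | Path],
    metadata_table: str | Path | pd.DataFrame,
) -> list[MarkerRecord]:
    """Read per-subunit FASTA files plus metadata into MarkerRecords.

    ``fasta_paths`` maps subunit ('B' and/or 'A') to an amino-acid FASTA.
    FASTA ids may carry a ``_aprB`` / ``_aprA`` suffix, which is stripped to
    recover the record_id; subunit sequences are paired by record_id. FASTA
    ids absent from the metadata produce records with unknown role/lineage
    and a warning; metadata rows without any sequence are reported.
    """
    meta = read_metadata(metadata_table)
    seqs: dict[str, dict[str, str]] = {}
    order: list[str] = []
    aligned: dict[str, bool] = {}
    for subunit, path in fasta_paths.items():
        if subunit not in ("B", "A"):
            raise ValueError(f"unknown subunit key {subunit!r}")
        entries = list(SeqIO.parse(str(path), "fasta"))
        lengths = {len(e.seq) for e in entries}
        aligned[subunit] = len(lengths) <= 1
        for entry in entries:
            rid = _strip_subunit_suffix(entry.id)
            slot = seqs.setdefault(rid, {})
            if subunit in slot:
                raise ValueError(f"duplicate {subunit} sequence for record {rid!r}")
            slot[subunit] = str(entry.seq)
            if rid not in order:
                order.append(rid)

    meta_by_id = {row["record_id"]: row for _, row in meta.iterrows()}
    records = []
    for rid in order:
        row = meta_by_id.get(rid)
        if row is None:
            warnings.warn(f"FASTA id {rid!r} missing from metadata; role/lineage unknown")
            organism, taxonomy, role, lineage = "", (), "unknown", "unknown"
        else:
            organism = row["organism"]
            taxonomy = tuple(t for t in str(row["taxonomy"]).split(";") if t)
            role = row["role"] or "unknown"
            lineage = row["lineage"] or "unknown"
        records.append(
            MarkerRecord(
                record_id=rid,
                organism=organism,
                taxonomy=taxonomy,
                role=role,
                lineage=lineage,
                seq_B=seqs[rid].get("B"),
                seq_A=seqs[rid].get("A"),
                aligned=all(aligned.get(s, True) for s in seqs[rid]),
            )
        )
    unpaired = sorted(set(meta_by_id) - set(order))
    if unpaired:
        warnings.warn(f"metadata rows without sequences: {unpaired}")
    return records


def partition_sequence_set(
    records: Sequence[MarkerRecord],
    thresholds: tuple[int, int, int] = DEFAULT_THRESHOLDS,
) -> SetPartition:
    """Partition records into core / shorter / rejected by ungapped length.

    A record is *core* when its AprB length exceeds ``thresholds[0]`` AND its
    AprA length exceeds ``thresholds[1]``; otherwise *shorter* when its AprA
    length exceeds ``thresholds[2]``; otherwise *rejected*. Inequalities are
    strict ("more than N residues").
    """
    min_b, min_a_core, min_a_shorter = thresholds
    if min_b <= 0 or min_a_core <= 0 or min_a_shorter <= 0:
        raise ValueError("thresholds must be positive")
    core, shorter, rejected = [], [], []
    for rec in records:
        len_b = rec.subunit_length("B")
        len_a = rec.subunit_length("A")
        if len_b > min_b and len_a > min_a_core:
            core.append(rec.record_id)
        elif len_a > min_a_shorter:
            shorter.append(rec.record_id)
        else:
            rejected.append(rec.record_id)
    return SetPartition(tuple(core), tuple(shorter), tuple(rejected), thresholds)


def alignment_from_records(
    records: Sequence[MarkerRecord], subunit: str
) -> ReferenceAlignment:
    """Build a per-subunit ReferenceAlignment from aligned MarkerRecords."""
    if subunit not in ("B", "A"):
        raise ValueError("subunit must be 'B' or 'A'")
    rows = []
    for rec in records:
        seq = rec.seq_B if subunit == "B" else rec.seq_A
        if seq is not None:
            rows.append((rec.record_id, seq))
    if not rows:
        raise ValueError(f"no records carry subunit {subunit}")
    n = len(rows[0][1])
    if any(len(s) != n for _, s in rows):
        raise ValueError(f"subunit {subunit} sequences are not aligned (unequal lengths)")
    return ReferenceAlignment(rows, n, frozenset(range(n)), subunit)


def concatenate_subunits(
    align_B: ReferenceAlignment, align_A: ReferenceAlignment
) -> ReferenceAlignment:
    """Concatenate B and A alignments row-wise for records present in both.

    The resulting alignment has ``boundary`` = width of the B alignment, and
    lists records lacking either subunit in ``excluded_ids``.
    """
    rows_b = dict(align_B.rows)
    rows_a = dict(align_A.rows)
    shared = [rid for rid, _ in align_B.rows if rid in rows_a]
    if not shared:
        raise ValueError("no record_ids shared between subunit alignments")
    excluded = tuple(
        sorted((set(rows_b) | set(rows_a)) - set(shared))
    )
    n = align_B.n_columns + align_A.n_columns
    rows = [(rid, rows_b[rid] + rows_a[rid]) for rid in shared]
    return ReferenceAlignment(
        rows,
        n,
        frozenset(range(n)),
        "concatenated",
        boundary=align_B.n_columns,
        excluded_ids=excluded,
    )


def mask_incomplete_columns(
    alignment: ReferenceAlignment, treat_x_as_missing: bool = True
) -> ReferenceAlignment:
    """Retain only columns with an unambiguous residue in every row.

    Columns containing a gap ('-'), missing marker ('.') or — by default —
    any ambiguity character (X, B, Z, J, ...) in any row are removed from the
    mask, leaving only positions comparable across the whole alignment. The
    operation is idempotent and only ever shrinks the existing mask.
    """
    if treat_x_as_missing:
        keep_chars = set(AA_INDEX)
    else:
        keep_chars = set(AA_INDEX) | set("XBZJUO")
    retained = set()
    for col in alignment.mask:
        if all(seq[col] in keep_chars for _, seq in alignment.rows):
            retained.add(col)
    if not retained:
        raise ValueError("no comparable positions remain after masking")
    return replace(alignment, mask=frozenset(retained))


def masked_widths(alignment: ReferenceAlignment) -> tuple[int, int] | int:
    """Retained column count; per subunit (B, A) for concatenated alignments."""
    if alignment.subunit == "concatenated":
        if alignment.boundary is None:
            raise ValueError("concatenated alignment lacks a boundary")
        b = sum(1 for c in alignment.mask if c < alignment.boundary)
        return b, len(alignment.mask) - b
    return len(alignment.mask)


def read_alignment_fasta(path: str | Path, subunit: str) -> ReferenceAlignment:
    """Read an aligned FASTA into a ReferenceAlignment (all columns retained)."""
    rows = [(e.id, normalize_gaps(str(e.seq))) for e in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"empty alignment FASTA: {path}")
    n = len(rows[0][1])
    return ReferenceAlignment(rows, n, frozenset(range(n)), subunit)


def write_masked_fasta(alignment: ReferenceAlignment, path: str | Path) -> None:
    """Write the masked view of an alignment to FASTA."""
    masked = alignment.masked_rows()
    with open(path, "w") as fh:
        for rid, seq in masked.items():
            fh.write(f">{rid}\n{seq}\n")
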