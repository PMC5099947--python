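"""In-silico coverage of degenerate PCR primers.

Given a degenerate primer (IUPAC codes, written 5'->3') and an aprA coding
sequence, the best binding site is the sliding window with the fewest
mismatches: a position mismatches when the template base is not in the
primer base's IUPAC degeneracy set. Forward primers are scanned against the
given strand, reverse primers against the reverse complement. Mismatch
counts per record are binned (default 0 / 1-2 / 3-4 / >=5) to summarize how
well a primer pair covers a set of reference sequences, and the inter-primer
region can be extracted to define the amplified (comparable) region used by
OTU clustering and placement filtering.

Coordinates are 0-based half-open internally; reports are 1-based inclusive
on the input strand. No 3'-anchoring or thermodynamic model is applied —
coverage is pure mismatch counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "PrimerSpec",
    "SiteMatch",
    "AmpliconResult",
    "best_site_mismatches",
    "coverage_table",
    "extract_amplicon_region",
    "DEFAULT_BINS",
]

#: IUPAC degeneracy code -> set of concrete bases
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code in set("ACGTRYSWKMBDHVN")
}

#: default mismatch bins as (label, lower, upper) inclusive ranges
DEFAULT_BINS = (("0", 0, 0), ("1-2", 1, 2), ("3-4", 3, 4), (">=5", 5, None))


@dataclass(frozen=True)
class PrimerSpec:
    """A degenerate primer written 5'->3'."""

    name: str
    iupac_seq: str
    orientation: str  # 'forward' | 'reverse'

    def __post_init__(self) -> None:
        seq = self.iupac_seq.upper()
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name!r}: invalid IUPAC codes {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: invalid orientation")
        object.__setattr__(self, "iupac_seq", seq)

    def __len__(self) -> int:
        return len(self.iupac_seq)

    def expansions(self) -> list[str]:
        """All concrete sequences the degenerate primer represents."""
        out = [""]
        for code in self.iupac_seq:
            out = [prefix + base for prefix in out for base in sorted(IUPAC_SETS[code])]
        return out


@dataclass(frozen=True)
class SiteMatch:
    """Best binding site of one primer on one record."""

    mismatches: int
    position: int  # 1-based start of the site on the input strand
    strand: str  # '+' (as given) or '-' (site read on the reverse complement)


def _window_mismatches(primer_seq: str, window: str) -> int:
    return sum(
        1 for p, b in zip(primer_seq, window) if b not in IUPAC_SETS[p]
    )


def best_site_mismatches(primer: PrimerSpec, nt_seq: str) -> SiteMatch:
    """Minimal-mismatch window of *primer* on *nt_seq*.

    The scan runs over the strand the primer anneals to (reverse primers:
    the reverse complement); ties go to the leftmost window on the scanned
    strand. The reported position is the 1-based start of the binding site
    on the input strand.
    """
    nt_seq = nt_seq.upper().replace("U", "T")
    if len(nt_seq) < len(primer):
        raise ValueError(
            f"sequence shorter than primer {primer.name!r} "
            f"({len(nt_seq)} < {len(primer)})"
        )
    if primer.orientation == "reverse":
        scan_seq = str(Seq(nt_seq).reverse_complement())
        strand = "-"
    else:
        scan_seq = nt_seq
        strand = "+"
    best_mm, best_i = None, None
    p = primer.iupac_seq
    for i in range(len(scan_seq) - len(p) + 1):
        mm = _window_mismatches(p, scan_seq[i : i + len(p)])
        if best_mm is None or mm < best_mm:
            best_mm, best_i = mm, i
            if mm == 0:
                break
    if strand == "-":
        # convert start on the reverse complement to start on input strand
        position = len(nt_seq) - (best_i + len(p)) + 1
    else:
        position = best_i + 1
    return SiteMatch(mismatches=best_mm, position=position, strand=strand)


def assign_bin(
    mismatches: int, bins: Sequence[tuple[str, int, int | None]] = DEFAULT_BINS
) -> str:
    for label, lo, hi in bins:
        if mismatches >= lo and (hi is None or mismatches <= hi):
            return label
    return "unbinned"


def coverage_table(
    primers: tuple[PrimerSpec, PrimerSpec],
    records: Mapping[str, str],
    bins: Sequence[tuple[str, int, int | None]] = DEFAULT_BINS,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-record forward/reverse mismatch counts and coverage bins.

    *primers* is (forward, reverse); *records* maps record_id to an aprA
    coding nucleotide sequence. Records failing the scan (e.g. shorter than
    a primer) are kept in the table with an error note. The overall bin of a
    record is driven by the worse of its two sites. An optional *groups*
    mapping adds a taxon-group column for histogram summaries.
    """
    fw, rv = primers
    rows = []
    for rid, seq in records.items():
        row: dict = {"record_id": rid}
        if groups is not None:
            row["group"] = groups.get(rid, "")
        try:
            fw_site = best_site_mismatches(fw, seq)
            rv_site = best_site_mismatches(rv, seq)
            row.update(
                fw_mismatches=fw_site.mismatches,
                fw_position=fw_site.position,
                rv_mismatches=rv_site.mismatches,
                rv_position=rv_site.position,
                bin=assign_bin(max(fw_site.mismatches, rv_site.mismatches), bins),
                error="",
            )
        except ValueError as exc:
            row.update(
                fw_mismatches=pd.NA, fw_position=pd.NA,
                rv_mismatches=pd.NA, rv_position=pd.NA,
                bin="", error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def coverage_histogram(table: pd.DataFrame) -> pd.DataFrame:
    """Bin counts, overall or per taxon group when a group column exists."""
    ok = table[table["error"] == ""]
    if "group" in ok.columns:
        return ok.groupby(["group", "bin"]).size().rename("count").reset_index()
    return ok.groupby("bin").size().rename("count").reset_index()


@dataclass(frozen=True)
class AmpliconResult:
    """Inter-primer region of a template, or a no-amplicon marker."""

    amplicon: str | None
    start: int | None  # 1-based inclusive, input strand, primer sites excluded
    end: int | None
    fw_site: SiteMatch | None = None
    rv_site: SiteMatch | None = None
    reason: str = ""

    @property
    def amplified(self) -> bool:
        return self.amplicon is not None


def extract_amplicon_region(
    fw_primer: PrimerSpec,
    rv_primer: PrimerSpec,
    nt_seq: str,
    max_mismatch: int = 3,
) -> AmpliconResult:
    """Inter-primer region (primer binding sites excluded).

    Both best sites must be within *max_mismatch* and correctly ordered
    (forward site upstream of the reverse site); otherwise a no-amplicon
    result is returned rather than an exception, mirroring a failed PCR.
    """
    nt_seq = nt_seq.upper().replace("U", "T")
    try:
        fw_site = best_site_mismatches(fw_primer, nt_seq)
        rv_site = best_site_mismatches(rv_primer, nt_seq)
    except ValueError as exc:
        return AmpliconResult(None, None, None, reason=str(exc))
    if fw_site.mismatches > max_mismatch:
        return AmpliconResult(None, None, None, fw_site, rv_site, "forward site exceeds max_mismatch")
    if rv_site.mismatches > max_mismatch:
        return AmpliconResult(None, None, None, fw_site, rv_site, "reverse site exceeds max_mismatch")
    interior_start = fw_site.position - 1 + len(fw_primer)  # 0-based
    interior_end = rv_site.position - 1  # 0-based exclusive
    if interior_end <= interior_start:
        return AmpliconResult(None, None, None, fw_site, rv_site, "primer sites overlap or are misordered")
    return AmpliconResult(
        amplicon=nt_seq[interior_start:interior_end],
        start=interior_start + 1,
        end=interior_end,
        fw_site=fw_site,
        rv_site=rv_site,
    )
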