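"""Amino-acid alphabet helpers and bitmask encodings shared across modules.

Residue states are encoded as bitmasks over the 20 standard amino acids so
that Fitch set operations reduce to integer ``&``/``|``. Anything that is not
one of the 20 unambiguous letters (gaps ``-``/``.``, ambiguity codes such as
``X``/``B``/``Z``/``J``, stop ``*``) is treated as missing data, i.e. the
full state set (wildcard) for parsimony and as a non-comparable site for
distance computation.
"""

from __future__ import annotations

import numpy as np

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_LETTERS)}
FULL_MASK = (1 << len(AA_LETTERS)) - 1

GAP_CHARS = {"-", "."}

# lookup table: byte value of an uppercase character -> bitmask
_ENCODE = np.full(128, FULL_MASK, dtype=np.int64)
for _aa, _i in AA_INDEX.items():
    _ENCODE[ord(_aa)] = 1 << _i


def is_unambiguous(char: str) -> bool:
    """True if *char* is one of the 20 standard amino-acid letters."""
    return char.upper() in AA_INDEX


def encode_residues(seq: str) -> np.ndarray:
    """Encode a residue string as an int64 bitmask array.

    Unambiguous residues map to a single-bit mask; everything else (gaps,
    ambiguity codes) maps to the full 20-state wildcard mask.
    """
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def ungapped_length(seq: str) -> int:
    """Number of residue characters, ignoring gap and missing markers."""
    return sum(1 for c in seq if c not in GAP_CHARS)


def normalize_gaps(seq: str) -> str:
    """Normalize '.' missing markers to '-' and uppercase the sequence."""
    return seq.upper().replace(".", "-")
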