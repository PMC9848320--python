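"""Residue alphabet handling.

The 20 standard amino acids are the working alphabet. An ``X`` in an input
sequence denotes an unknown residue: it is tolerated wherever a motif places
no constraint (wildcard positions) but never satisfies an anchor.
"""

from __future__ import annotations

RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_SET = frozenset(RESIDUES)
UNKNOWN = "X"
GAP = "-"

_VALID_SEQ_CHARS = RESIDUE_SET | {UNKNOWN}


class AlphabetError(ValueError):
    """Raised when a sequence or residue falls outside the amino-acid alphabet."""


def check_residue(letter: str) -> str:
    """Return the upper-cased residue letter, rejecting non-standard symbols."""
    r = letter.upper()
    if r not in RESIDUE_SET:
        raise AlphabetError(f"not a standard amino-acid letter: {letter!r}")
    return r


def check_sequence(seq: str) -> str:
    """Upper-case and validate a residue string (X allowed, gaps are not)."""
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in _VALID_SEQ_CHARS:
            raise AlphabetError(
                f"invalid character {c!r} at position {i} (0-based) in sequence"
            )
    return s
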