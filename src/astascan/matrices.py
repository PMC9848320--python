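"""Substitution-matrix access.

The package ships the standard NCBI BLOSUM62 table as a plain-text file in
the conventional BLOSUM layout and exposes it as a plain ``{(a, b): score}``
lookup over the 20 standard residues. Any matrix in the same text format can
be loaded in its place.
"""

from __future__ import annotations

import functools
from importlib import resources

from .alphabet import RESIDUES, check_residue

ScoreTable = dict[tuple[str, str], int]


def read_matrix(path_or_text) -> ScoreTable:
    """Parse a BLOSUM-format text table into a symmetric score dict.

    Lines starting with ``#`` are comments; the first data line is the column
    alphabet; each subsequent line is a row label followed by integer scores.
    Only entries where both residues are standard amino acids are kept.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = str(path_or_text)
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    columns = lines[0].split()
    table: ScoreTable = {}
    for ln in lines[1:]:
        parts = ln.split()
        row = parts[0]
        for col, val in zip(columns, parts[1:]):
            if row in RESIDUES and col in RESIDUES:
                table[(row, col)] = int(round(float(val)))
    # symmetry check
    for a in RESIDUES:
        for b in RESIDUES:
            if table.get((a, b)) != table.get((b, a)):
                raise ValueError(f"asymmetric matrix entry for {a},{b}")
    return table


@functools.lru_cache(maxsize=1)
def blosum62() -> ScoreTable:
    """The shipped BLOSUM62 table restricted to the 20 standard residues."""
    text = resources.files("astascan.data").joinpath("blosum62.txt").read_text()
    return read_matrix(text)


def score(a: str, b: str, matrix: ScoreTable | None = None) -> int:
    matrix = matrix if matrix is not None else blosum62()
    return matrix[(check_residue(a), check_residue(b))]
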