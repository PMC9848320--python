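"""Readers and writers for the pipeline's on-disk formats.

Internally all coordinates are 0-based half-open; every human-facing on-disk
table (TSV, JSON reports) uses 1-based inclusive coordinates, converted at
this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "SequenceRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_domain_hits_tsv",
    "write_domain_hits_tsv",
    "write_phylip",
    "write_jsonl",
    "read_jsonl",
]

FASTA_WRAP = 60


@dataclass(frozen=True)
class SequenceRecord:
    """One precursor protein: identifier, residue string, optional metadata."""

    id: str
    sequence: str
    taxon: str | None = None
    clade: str | None = None

    def with_metadata(self, taxon=None, clade=None) -> "SequenceRecord":
        return SequenceRecord(self.id, self.sequence, taxon, clade)


class FastaParseError(ValueError):
    """FASTA syntax error, carrying the offending 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_fasta(path) -> list:
    """Strict FASTA reader returning :class:`SequenceRecord` objects.

    Tolerates CRLF endings and blank lines; rejects headerless leading
    sequence data, empty ids and records with no residues.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {header!r} has an empty sequence", header_line)
        records.append(SequenceRecord(id=header, sequence=seq))

    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError("malformed header: empty identifier", lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError("sequence data before any '>' header", lineno)
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records, path, wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# --- tabular metadata -------------------------------------------------------


def read_metadata_tsv(path) -> pd.DataFrame:
    """Per-sequence metadata: columns id, taxon, clade."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"id"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV lacks required columns: {sorted(missing)}")
    for col in ("taxon", "clade"):
        if col not in df.columns:
            df[col] = ""
    return df[["id", "taxon", "clade"]]


def write_metadata_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_domain_hits_tsv(path) -> pd.DataFrame:
    """Externally produced domain hits.

    On disk: columns id, domain, start, end with 1-based inclusive
    coordinates. Returned frame carries 0-based half-open start/end.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "domain": str})
    required = {"id", "domain", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain-hit TSV lacks required columns: {sorted(missing)}")
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    if (out["start"] < 0).any() or (out["start"] >= out["end"]).any():
        raise ValueError("domain-hit TSV has invalid coordinates (expect 1-based inclusive)")
    return out[["id", "domain", "start", "end"]]


def write_domain_hits_tsv(df: pd.DataFrame, path) -> None:
    """Inverse of :func:`read_domain_hits_tsv` (expects 0-based half-open)."""
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# --- matrices and reports ---------------------------------------------------


def write_phylip(ids, matrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    n = len(ids)
    width = max([12] + [len(str(name)) + 2 for name in ids])
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, name in enumerate(ids):
            row = " ".join(f"{matrix[i][j]:.6f}" for j in range(n))
            fh.write(f"{name:<{width}s}{row}\n")


def write_jsonl(objs, path) -> None:
    with open(path, "w") as fh:
        for obj in objs:
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_jsonl(path) -> list:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
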