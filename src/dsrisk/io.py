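"""Sequence and alignment file handling plus tabular report writing.

Unaligned input is plain FASTA; pairwise alignments are accepted as either
aligned FASTA or Clustal. All residues are normalised to uppercase DNA
(``U`` folded to ``T``) so RNA and DNA spellings of the same dsRNA template
compare equal. Reports are written with explicit precision so repeated runs
with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

from .similarity import PairwiseAlignment

#: nucleotide alphabet accepted on input (after uppercasing / U->T folding)
ALPHABET = frozenset("ACGTN")

GAP = "-"


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence: id, free-text description, uppercase residues."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = [(i, c) for i, c in enumerate(self.residues, start=1) if c not in ALPHABET]
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"sequence {self.id!r} has invalid residue {char!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and fold U->T; gap or other foreign characters are left for
    the SequenceRecord validator to reject with coordinates."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned FASTA into SequenceRecords.

    Raises ``ValueError`` on an empty file, a duplicate id, or a residue
    outside the DNA alphabet (gap characters included: aligned rows must go
    through :func:`read_alignment` instead).
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, rec.description, normalize_residues(str(rec.seq)))
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_alignment(path: str | Path, dialect: str = "aligned_fasta") -> PairwiseAlignment:
    """Read a two-row alignment (aligned FASTA or Clustal) into a
    PairwiseAlignment. Row order is preserved."""
    fmt = {"aligned_fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    aln = AlignIO.read(str(path), fmt)
    if len(aln) != 2:
        raise ValueError(
            f"pairwise alignment required: {path} has {len(aln)} rows"
        )
    rowa, rowb = (normalize_residues(str(r.seq)) for r in aln)
    return PairwiseAlignment(aln[0].id, aln[1].id, rowa, rowb)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.description in ("", rec.id) else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_report(
    table: pd.DataFrame | Sequence[dict],
    path: str | Path,
    format: str = "csv",
    float_precision: int = 6,
) -> None:
    """Write a tabular result as CSV/TSV/JSON with fixed numeric precision.

    An empty table yields a header-only file (CSV/TSV) or an empty JSON list.
    """
    if table is None:
        raise ValueError("table is required")
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    ffmt = f"%.{float_precision}g"
    if format == "csv":
        df.to_csv(path, index=False, float_format=ffmt, lineterminator="\n")
    elif format == "tsv":
        df.to_csv(path, index=False, sep="\t", float_format=ffmt, lineterminator="\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2, default=float)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
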