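"""Pairwise global alignment, percent identity, and sliding-window selection
of the most conserved dsRNA target region across species.

The screen asks: which contiguous window of the pest transcript (default
400 nt, the length of the synthesised dsRNA) is most similar, on average or
at worst, across the surrogate non-target species? Windows are anchored in
the *pest* reference coordinates because the designed molecule is a
contiguous fragment of the pest sequence; surrogate gaps inside a window
count as mismatches.

"Identity" here is the identical-column fraction. Two denominators are
offered: ``all_columns`` (every alignment column, the default) and
``exclude_terminal_gaps`` (only columns inside the region where both rows
have begun and not yet ended — appropriate when UTR overhangs from
RACE-derived cDNAs would otherwise dilute ORF-level identity).
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Mapping

import numpy as np
from Bio import Align

if TYPE_CHECKING:  # pragma: no cover
    from .io import SequenceRecord

GAP = "-"

#: NCBI-like nucleotide scoring defaults (match, mismatch, gap open, gap extend)
DEFAULT_SCORING = {"match": 2.0, "mismatch": -3.0, "gap_open": -5.0, "gap_extend": -2.0}


@dataclasses.dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal column count; substrate for identity and
    N-mer scanning."""

    idA: str
    idB: str
    rowA: str
    rowB: str

    def __post_init__(self) -> None:
        if len(self.rowA) != len(self.rowB):
            raise ValueError(
                f"alignment rows differ in length: {len(self.rowA)} vs {len(self.rowB)}"
            )
        if len(self.rowA) == 0:
            raise ValueError("empty alignment")
        for a, b in zip(self.rowA, self.rowB):
            if a == GAP and b == GAP:
                raise ValueError("alignment contains an all-gap column")

    @property
    def n_columns(self) -> int:
        return len(self.rowA)

    def ungapped(self, which: str) -> str:
        row = {"A": self.rowA, "B": self.rowB}[which]
        return row.replace(GAP, "")

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(self.idB, self.idA, self.rowB, self.rowA)


@dataclasses.dataclass(frozen=True)
class IdentityProfile:
    """Identity of every feasible fixed-length window, anchored at 1-based
    start positions in the reference's ungapped coordinates."""

    reference_id: str
    window_length: int
    scores: tuple[tuple[int, float], ...]

    def argmax(self) -> tuple[int, float]:
        """Window start with the highest identity; ties go to the smallest start."""
        best_start, best = self.scores[0]
        for start, ident in self.scores[1:]:
            if ident > best:
                best_start, best = start, ident
        return best_start, best


@dataclasses.dataclass(frozen=True)
class ConservedRegion:
    reference_id: str
    start: int
    end: int
    per_species_identity: dict[str, float]
    aggregate: float


def align_pair(
    a: "SequenceRecord",
    b: "SequenceRecord",
    scoring: Mapping[str, float] | None = None,
) -> PairwiseAlignment:
    """Global pairwise alignment with affine gap penalties.

    Deterministic for fixed inputs and parameters (the first optimal
    alignment in the aligner's canonical order is taken).
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = sc["match"]
    aligner.mismatch_score = sc["mismatch"]
    aligner.open_gap_score = sc["gap_open"]
    aligner.extend_gap_score = sc["gap_extend"]
    aln = aligner.align(a.residues, b.residues)[0]
    rowa, rowb = str(aln[0]), str(aln[1])
    out = PairwiseAlignment(a.id, b.id, rowa, rowb)
    assert out.ungapped("A") == a.residues and out.ungapped("B") == b.residues
    return out


def percent_identity(aln: PairwiseAlignment, mode: str = "all_columns") -> float:
    """Identical-column fraction of a pairwise alignment.

    ``all_columns`` divides by every alignment column; ``exclude_terminal_gaps``
    divides by the columns between the first and last column where both rows
    are non-gap (leading/trailing overhangs of either row are excluded).
    """
    cols = list(zip(aln.rowA, aln.rowB))
    if mode == "all_columns":
        span = cols
    elif mode == "exclude_terminal_gaps":
        both = [i for i, (x, y) in enumerate(cols) if x != GAP and y != GAP]
        if not both:
            return 0.0
        span = cols[both[0] : both[-1] + 1]
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    ident = sum(1 for x, y in span if x != GAP and x == y and x != "N")
    return ident / len(span)


def _column_maps(aln: PairwiseAlignment, reference: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-column match indicator and the alignment column of each 1-based
    reference base."""
    ref_row = aln.rowA if reference == "A" else aln.rowB
    a = np.frombuffer(aln.rowA.encode(), dtype="S1")
    b = np.frombuffer(aln.rowB.encode(), dtype="S1")
    match = (a == b) & (a != b"-") & (a != b"N")
    ref_cols = np.flatnonzero(np.frombuffer(ref_row.encode(), dtype="S1") != b"-")
    return match.astype(np.int64), ref_cols


def window_identity_profile(
    aln: PairwiseAlignment,
    reference: str,
    window_length: int,
) -> IdentityProfile:
    """Identity of every window of ``window_length`` consecutive reference
    bases.

    A window spans the alignment columns from its first to its last reference
    base; identity is matching columns over *all* columns in that span, so
    gaps (in either row) inside the span count as mismatches.
    """
    if reference not in ("A", "B"):
        raise ValueError("reference must be 'A' or 'B'")
    match, ref_cols = _column_maps(aln, reference)
    n_ref = len(ref_cols)
    if n_ref < window_length:
        raise ValueError(
            f"reference has {n_ref} bases, shorter than window {window_length}"
        )
    cum = np.concatenate([[0], np.cumsum(match)])
    starts = np.arange(n_ref - window_length + 1)
    lo = ref_cols[starts]
    hi = ref_cols[starts + window_length - 1]
    ident = (cum[hi + 1] - cum[lo]) / (hi - lo + 1)
    ref_id = aln.idA if reference == "A" else aln.idB
    scores = tuple((int(s) + 1, float(v)) for s, v in zip(starts, ident))
    return IdentityProfile(ref_id, window_length, scores)


def select_conserved_region(
    profiles: Mapping[str, IdentityProfile],
    aggregator: str = "mean",
) -> ConservedRegion:
    """Pick the window start maximising the aggregate identity across species.

    ``mean`` selects the on-average most conserved window; ``min`` selects the
    window whose *worst* surrogate identity is highest (a conservative
    worst-surrogate design). Ties break to the smallest start.
    """
    if not profiles:
        raise ValueError("no identity profiles supplied")
    profs = list(profiles.values())
    ref_id, w = profs[0].reference_id, profs[0].window_length
    starts = [s for s, _ in profs[0].scores]
    for p in profs[1:]:
        if p.reference_id != ref_id or p.window_length != w:
            raise ValueError("profiles must share reference and window length")
        if [s for s, _ in p.scores] != starts:
            raise ValueError("profiles must share window starts")
    agg_fn = {"mean": np.mean, "min": np.min}.get(aggregator)
    if agg_fn is None:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    mat = np.array([[v for _, v in p.scores] for p in profs])
    agg = agg_fn(mat, axis=0)
    idx = int(np.argmax(agg))  # np.argmax returns the first maximum: smallest start
    start = starts[idx]
    return ConservedRegion(
        reference_id=ref_id,
        start=start,
        end=start + w - 1,
        per_species_identity={
            name: float(mat[i, idx]) for i, name in enumerate(profiles)
        },
        aggregate=float(agg[idx]),
    )
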