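"""Enumeration of maximal gap-free identical stretches in a pairwise
alignment, and N-mer counting.

A shared contiguous match of at least ~21 nt between an insecticidal dsRNA
and a non-target transcript is the canonical trigger criterion for
cross-species RNAi activity, so the screen reduces to: list every maximal
run of alignment columns in which both rows are non-gap and identical, then
count how many N-mers those runs contain for N in a range (typically
19..23).

Two counting semantics are provided. ``maximal_runs`` counts runs of length
>= N (one discrete match per run, the convention behind start/end-position
match listings); ``sliding_windows`` counts every distinct N-nt window,
i.e. sum of (L - N + 1) over runs with L >= N. The ambiguity code ``N``
never matches anything, including itself — conservative for risk screening.
"""

from __future__ import annotations

import dataclasses

from .similarity import GAP, PairwiseAlignment

MODES = ("maximal_runs", "sliding_windows")


@dataclasses.dataclass(frozen=True)
class MatchRun:
    """One maximal gap-free identical stretch, with 1-based inclusive
    coordinates in both ungapped sequences."""

    length: int
    sequence: str
    startA: int
    endA: int
    startB: int
    endB: int

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("run length does not match its sequence")
        for s, e in ((self.startA, self.endA), (self.startB, self.endB)):
            if e - s + 1 != self.length:
                raise ValueError("run coordinates inconsistent with length")


@dataclasses.dataclass(frozen=True)
class NmerCountTable:
    mode: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        ns = sorted(self.counts)
        for lo, hi in zip(ns, ns[1:]):
            if self.counts[hi] > self.counts[lo]:
                raise ValueError("N-mer counts must be non-increasing in N")


def enumerate_identity_runs(
    aln: PairwiseAlignment,
    region: tuple[int, int] | None = None,
) -> list[MatchRun]:
    """All maximal runs of consecutive columns where both rows are non-gap
    and identical, ordered by alignment column.

    ``region=(start, end)`` restricts the scan to the 1-based inclusive
    ungapped coordinates of sequence A; a run straddling the region border is
    truncated at it.
    """
    runs: list[MatchRun] = []
    pos_a = pos_b = 0  # ungapped positions consumed so far
    run_chars: list[str] = []
    run_start_a = run_start_b = 0

    def in_region(pa: int) -> bool:
        return region is None or region[0] <= pa <= region[1]

    def flush() -> None:
        if run_chars:
            seq = "".join(run_chars)
            runs.append(
                MatchRun(
                    length=len(seq),
                    sequence=seq,
                    startA=run_start_a,
                    endA=run_start_a + len(seq) - 1,
                    startB=run_start_b,
                    endB=run_start_b + len(seq) - 1,
                )
            )
            run_chars.clear()

    for ca, cb in zip(aln.rowA, aln.rowB):
        if ca != GAP:
            pos_a += 1
        if cb != GAP:
            pos_b += 1
        matched = ca != GAP and cb != GAP and ca == cb and ca != "N" and in_region(pos_a)
        if matched:
            if not run_chars:
                run_start_a, run_start_b = pos_a, pos_b
            run_chars.append(ca)
        else:
            flush()
    flush()
    return runs


def count_nmers(runs: list[MatchRun], n: int, mode: str = "maximal_runs") -> int:
    """Number of N-mers contained in a run list under the chosen semantics."""
    if n < 1:
        raise ValueError("N must be a positive integer")
    if mode == "maximal_runs":
        return sum(1 for r in runs if r.length >= n)
    if mode == "sliding_windows":
        return sum(r.length - n + 1 for r in runs if r.length >= n)
    raise ValueError(f"unknown counting mode {mode!r}")


def nmer_report(
    aln: PairwiseAlignment,
    nmer_range: tuple[int, int] = (19, 23),
    mode: str = "maximal_runs",
    region: tuple[int, int] | None = None,
) -> tuple[NmerCountTable, list[MatchRun]]:
    """Count table for every N in ``nmer_range`` plus the underlying run
    listing (the match-table output)."""
    lo, hi = nmer_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid N-mer range {nmer_range}")
    runs = enumerate_identity_runs(aln, region=region)
    counts = {n: count_nmers(runs, n, mode) for n in range(lo, hi + 1)}
    return NmerCountTable(mode=mode, counts=counts), runs


def screen_minimum_match(
    aln: PairwiseAlignment, threshold: int = 21
) -> tuple[bool, list[MatchRun]]:
    """Does the pair share at least one contiguous match of >= ``threshold``
    nt?  Returns the flag plus the supporting runs as evidence."""
    if threshold < 1:
        raise ValueError("threshold must be a positive integer")
    evidence = [r for r in enumerate_identity_runs(aln) if r.length >= threshold]
    return bool(evidence), evidence
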