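"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own scanning code: they
work column-by-column with plain Python loops so the fast implementations
can be checked against them.
"""

from __future__ import annotations

import numpy as np
import pytest

from dsrisk.similarity import GAP, PairwiseAlignment

BASES = "ACGT"


def random_gapped_alignment(rng: np.random.Generator, n_cols: int,
                            p_gap: float = 0.08, p_match: float = 0.5) -> PairwiseAlignment:
    """Random two-row alignment with gap columns; never an all-gap column."""
    rowa, rowb = [], []
    for _ in range(n_cols):
        r = rng.random()
        if r < p_gap / 2:
            rowa.append(GAP)
            rowb.append(BASES[rng.integers(4)])
        elif r < p_gap:
            rowa.append(BASES[rng.integers(4)])
            rowb.append(GAP)
        else:
            a = BASES[rng.integers(4)]
            if rng.random() < p_match:
                b = a
            else:
                b = BASES[(BASES.index(a) + 1 + rng.integers(3)) % 4]
            rowa.append(a)
            rowb.append(b)
    return PairwiseAlignment("ra", "rb", "".join(rowa), "".join(rowb))


def oracle_match_runs(aln: PairwiseAlignment) -> list[tuple[int, int, int]]:
    """Maximal identical gap-free runs as (length, startA, startB), by a
    plain column scan."""
    runs = []
    pa = pb = 0
    cur = 0
    sa = sb = 0
    for ca, cb in zip(aln.rowA, aln.rowB):
        if ca != GAP:
            pa += 1
        if cb != GAP:
            pb += 1
        if ca != GAP and cb != GAP and ca == cb and ca != "N":
            if cur == 0:
                sa, sb = pa, pb
            cur += 1
        else:
            if cur:
                runs.append((cur, sa, sb))
            cur = 0
    if cur:
        runs.append((cur, sa, sb))
    return runs


def oracle_count_nmers(aln: PairwiseAlignment, n: int, mode: str) -> int:
    """Slide every N-column window over the alignment and count windows whose
    columns all match; maximal runs counted via the run scan."""
    if mode == "sliding_windows":
        match = [
            ca != GAP and cb != GAP and ca == cb and ca != "N"
            for ca, cb in zip(aln.rowA, aln.rowB)
        ]
        return sum(
            1 for i in range(len(match) - n + 1) if all(match[i : i + n])
        )
    return sum(1 for length, _, _ in oracle_match_runs(aln) if length >= n)


def oracle_window_identity(aln: PairwiseAlignment, reference: str, w: int) -> list[tuple[int, float]]:
    """Per-window identity by explicitly locating each window's column span."""
    ref_row = aln.rowA if reference == "A" else aln.rowB
    ref_cols = [i for i, c in enumerate(ref_row) if c != GAP]
    out = []
    for s in range(len(ref_cols) - w + 1):
        lo, hi = ref_cols[s], ref_cols[s + w - 1]
        cols = list(zip(aln.rowA, aln.rowB))[lo : hi + 1]
        ident = sum(1 for a, b in cols if a != GAP and a == b and a != "N")
        out.append((s + 1, ident / (hi - lo + 1)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)
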