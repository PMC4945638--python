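"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its spec plus a seed, producing
inputs with the statistical and combinatorial structure the pipeline
assumes: homolog sequence pairs with planted gap-free identical runs,
replicate-level life-history endpoint tables for a dietary toxicity assay,
qPCR Ct tables, and exponentially decaying gel-band intensity series.

The homolog generator emits substitution-only pairs, so the pair is its own
gapless alignment and planted-run coordinates coincide in both sequences.
The flanking position on each side of a planted run is forced to mismatch,
making the planted lengths exactly the ground-truth maximal run lengths.
An indel mode exists to exercise the aligner but carries no run ground
truth.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord
from .nmer import MatchRun
from .qpcr import CT_COLUMNS
from .similarity import PairwiseAlignment

BASES = np.array(list("ACGT"))

TREATMENTS = ("dsDVV", "dsSC", "dsGUS", "H2O")


@dataclasses.dataclass(frozen=True)
class HomologPairSpec:
    """Homologous ORF pair: length, background per-site identity outside the
    planted runs, and planted gap-free identical runs as (length, 1-based
    start in sequence A)."""

    length: int = 1800
    background_identity: float = 0.75
    planted_runs: tuple[tuple[int, int], ...] = ()
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.background_identity <= 1:
            raise ValueError("background identity must be in (0, 1]")
        spans = sorted((p, p + ln - 1) for ln, p in self.planted_runs)
        for (s, e), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e + 1:  # +1: each run owns its mismatch flanks
                raise ValueError("planted runs overlap or touch")
        for s, e in spans:
            if s < 1 or e > self.length:
                raise ValueError("planted run outside sequence")


def gen_homolog_pair(
    spec: HomologPairSpec, seed: int
) -> tuple[SequenceRecord, SequenceRecord, list[MatchRun]]:
    """Generate a homolog pair (A, B) plus the ground-truth planted runs.

    B derives from A by per-site substitution at rate 1 − background_identity
    outside planted runs (substitutions always differ from A); inside planted
    runs B equals A; run flanks are forced mismatches. With ``indel_rate`` >
    0, B additionally gains insertions/deletions and the ground truth is
    dropped (returned empty).
    """
    rng = np.random.default_rng(seed)
    n = spec.length
    a = rng.choice(BASES, size=n)
    b = a.copy()

    planted = np.zeros(n, dtype=bool)
    flanks = np.zeros(n, dtype=bool)
    for ln, pos in spec.planted_runs:
        planted[pos - 1 : pos - 1 + ln] = True
        if pos - 2 >= 0:
            flanks[pos - 2] = True
        if pos - 1 + ln < n:
            flanks[pos - 1 + ln] = True

    sub = (rng.random(n) < 1 - spec.background_identity) & ~planted
    sub |= flanks
    # substituted base is drawn uniformly from the 3 alternatives
    shift = rng.integers(1, 4, size=n)
    idx = (np.searchsorted(BASES, a) + shift) % 4
    b[sub] = BASES[idx[sub]]

    truth = [
        MatchRun(
            length=ln,
            sequence="".join(a[pos - 1 : pos - 1 + ln]),
            startA=pos, endA=pos + ln - 1, startB=pos, endB=pos + ln - 1,
        )
        for ln, pos in sorted(spec.planted_runs, key=lambda r: r[1])
    ]

    seq_b = b
    if spec.indel_rate > 0:
        out = []
        for base in seq_b:
            r = rng.random()
            if r < spec.indel_rate / 2:
                continue  # deletion
            out.append(base)
            if r > 1 - spec.indel_rate / 2:
                out.append(rng.choice(BASES))  # insertion
        seq_b = np.array(out) if out else seq_b
        truth = []

    rec_a = SequenceRecord("synthA", "synthetic homolog A", "".join(a))
    rec_b = SequenceRecord("synthB", "synthetic homolog B", "".join(seq_b))
    return rec_a, rec_b, truth


def pair_alignment(rec_a: SequenceRecord, rec_b: SequenceRecord) -> PairwiseAlignment:
    """The trivial gapless alignment of an equal-length substitution-only pair."""
    if len(rec_a.residues) != len(rec_b.residues):
        raise ValueError("substitution-only pairs must be equal length")
    return PairwiseAlignment(rec_a.id, rec_b.id, rec_a.residues, rec_b.residues)


@dataclasses.dataclass(frozen=True)
class LifeHistorySpec:
    """Dietary toxicity assay design: 4 dsRNA/control treatments (plus an
    optional arsenate positive control), replicate cohorts of individuals,
    and per-endpoint treatment effects in endpoint units.

    Defaults mirror a 28-day collembolan assay: 14 replicates of 10
    individuals per treatment; dsRNA treatments shift development time
    (faster development), all other endpoints null.
    """

    n_replicates: int = 14
    individuals_per_replicate: int = 10
    survival_p: float = 0.95
    development_mean: float = 20.0       # days to maturity
    development_sd: float = 1.5
    development_effects: dict = dataclasses.field(
        default_factory=lambda: {"dsDVV": -1.5, "dsSC": -1.5}
    )
    body_length_mean: float = 1.6        # mm
    body_length_sd: float = 0.1
    fecundity_mean: float = 100.0        # eggs per replicate cohort in 9 days
    fecundity_dispersion: float = 10.0
    hatch_p: float = 0.85
    include_arsenate: bool = False
    arsenate_death_day: int = 8

    def __post_init__(self) -> None:
        if self.development_sd <= 0 or self.body_length_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        if not 0 < self.survival_p <= 1 or not 0 < self.hatch_p <= 1:
            raise ValueError("probabilities must be in (0, 1]")


def gen_life_history(spec: LifeHistorySpec, seed: int) -> pd.DataFrame:
    """Replicate-level endpoint table (one row per replicate x treatment)."""
    rng = np.random.default_rng(seed)
    treatments = list(TREATMENTS) + (["arsenate"] if spec.include_arsenate else [])
    rows = []
    for trt in treatments:
        for rep in range(1, spec.n_replicates + 1):
            if trt == "arsenate":
                rows.append(
                    {"replicate_id": f"{trt}_{rep}", "treatment": trt,
                     "survival_rate": 0.0,
                     "development_time": float("nan"),
                     "body_length": float("nan"),
                     "fecundity": 0, "hatch_rate": float("nan")}
                )
                continue
            n_ind = spec.individuals_per_replicate
            survived = rng.binomial(n_ind, spec.survival_p)
            dev = rng.normal(
                spec.development_mean + spec.development_effects.get(trt, 0.0),
                spec.development_sd,
            )
            length = rng.normal(spec.body_length_mean, spec.body_length_sd)
            # negative binomial via gamma-Poisson mixture
            k = spec.fecundity_dispersion
            lam = rng.gamma(k, spec.fecundity_mean / k)
            eggs = int(rng.poisson(lam))
            hatched = rng.binomial(eggs, spec.hatch_p) if eggs > 0 else 0
            rows.append(
                {"replicate_id": f"{trt}_{rep}", "treatment": trt,
                 "survival_rate": survived / n_ind,
                 "development_time": float(dev),
                 "body_length": float(length),
                 "fecundity": eggs,
                 "hatch_rate": hatched / eggs if eggs > 0 else float("nan")}
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class CtSpec:
    """qPCR experiment grid: treatments x sampling days plus a calibrator
    condition (untreated at day 0), triplicate technical reps over three
    biological reps; knockdown expressed as a ΔCt shift of the target
    (default 0 — a null experiment)."""

    treatments: tuple[str, ...] = TREATMENTS
    days: tuple[int, ...] = (2, 4, 6)
    calibrator: tuple[str, int] = ("untreated", 0)
    baseline_target_ct: float = 22.0
    baseline_reference_ct: float = 15.0
    knockdown_dct: dict = dataclasses.field(default_factory=dict)
    biological_sd: float = 0.2
    technical_sd: float = 0.1
    n_biological: int = 3
    n_technical: int = 3
    target_gene: str = "vATPaseA"
    reference_gene: str = "28S"

    def __post_init__(self) -> None:
        if self.biological_sd < 0 or self.technical_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def gen_ct_table(spec: CtSpec, seed: int) -> pd.DataFrame:
    """Ct records for the full grid (calibrator condition included).

    The reference gene is stable (i.i.d. around its baseline across all
    conditions); the target's per-condition shift is ``knockdown_dct``,
    keyed by treatment (positive ΔCt = lower expression).
    """
    rng = np.random.default_rng(seed)
    conditions = [spec.calibrator] + [
        (t, d) for t in spec.treatments for d in spec.days
    ]
    rows = []
    for trt, day in conditions:
        shift = spec.knockdown_dct.get(trt, 0.0)
        for bio in range(1, spec.n_biological + 1):
            bio_t = rng.normal(spec.baseline_target_ct + shift, spec.biological_sd)
            bio_r = rng.normal(spec.baseline_reference_ct, spec.biological_sd)
            for gene, centre in ((spec.target_gene, bio_t), (spec.reference_gene, bio_r)):
                for tech in range(1, spec.n_technical + 1):
                    rows.append(
                        {"sample_id": f"{trt}_d{day}_b{bio}",
                         "gene": gene, "treatment": trt, "day": day,
                         "biological_rep": bio, "technical_rep": tech,
                         "ct": float(rng.normal(centre, spec.technical_sd))}
                    )
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def gen_degradation_series(
    initial: float,
    half_life_h: float,
    timepoints: Sequence[float] = (0, 12, 24, 36, 48),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Exponential-decay band-intensity series with Gaussian noise, floored
    at 0. ``half_life_h = inf`` gives the stable (flat) scenario."""
    if half_life_h <= 0:
        raise ValueError("half-life must be > 0")
    rng = np.random.default_rng(seed)
    out = []
    for t in timepoints:
        decay = 1.0 if math.isinf(half_life_h) else 2.0 ** (-t / half_life_h)
        val = initial * decay + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        out.append((float(t), max(val, 0.0)))
    return out
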