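"""Worst-case dietary exposure arithmetic.

Tier-I (worst-case) non-target risk assessment feeds purified dsRNA in
artificial diet and compares the resulting per-individual consumption with
(a) the LC50 of the target pest and (b) the expected environmental
concentration (EEC) of the dsRNA in plant tissue. The fold margin against a
tissue divides an ingested mass (ng per individual) by a tissue
concentration (ng per g fresh weight); its units are grams of tissue
equivalent, carried in the report metadata rather than silently dropped.

All internal arithmetic is in nanograms.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

NG_PER_UG = 1000.0


def round_half_away_from_zero(x: float) -> int:
    """Round to nearest integer with .5 going away from zero (not banker's)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclasses.dataclass(frozen=True)
class FeedingRegimen:
    """Feeding-assay design: dsRNA concentration in the diet (μg dsRNA per
    μg diet), diet mass offered per feeding (μg), number of feedings over the
    assay, and individuals sharing the diet."""

    dsrna_concentration: float = 0.83
    diet_per_feeding: float = 1.65
    n_feedings: int = 14
    n_individuals: int = 10
    assay_days: int = 28
    feeding_interval_days: int | None = 2

    def __post_init__(self) -> None:
        for name in ("dsrna_concentration", "diet_per_feeding", "n_feedings",
                     "n_individuals", "assay_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.feeding_interval_days is not None:
            implied = self.assay_days // self.feeding_interval_days
            if abs(self.n_feedings - implied) > 1:
                raise ValueError(
                    f"n_feedings={self.n_feedings} inconsistent with "
                    f"{self.assay_days} days at {self.feeding_interval_days}-day intervals"
                )


@dataclasses.dataclass(frozen=True)
class TissueEEC:
    """Expected environmental concentration of the dsRNA in one plant
    tissue, ng per g fresh weight."""

    tissue: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(f"EEC for {self.tissue!r} must be > 0")


@dataclasses.dataclass(frozen=True)
class MarginReport:
    consumption_ug: float
    consumption_source: str  # "regimen" | "override"
    tissue_margins: dict[str, int]
    lc50_margin: float | None = None
    units_note: str = (
        "tissue margins are ng ingested per individual divided by ng/g fw "
        "tissue EEC; units are g of tissue equivalent"
    )


def per_capita_consumption(
    regimen: FeedingRegimen, override: float | None = None
) -> tuple[float, str]:
    """Average dsRNA consumption per individual over the assay, in μg.

    Computed as concentration x diet mass per feeding x feedings /
    individuals. An explicit ``override`` (e.g. an independently measured
    consumption) bypasses the regimen arithmetic and is flagged as such in
    the returned provenance tag.
    """
    if override is not None:
        if override <= 0:
            raise ValueError("consumption override must be strictly positive")
        return float(override), "override"
    ug = (
        regimen.dsrna_concentration
        * regimen.diet_per_feeding
        * regimen.n_feedings
        / regimen.n_individuals
    )
    return ug, "regimen"


def margin_vs_tissue(consumption_ug: float, eec: TissueEEC) -> int:
    """Fold margin of the ingested dose over one tissue EEC, rounded
    half-away-from-zero to an integer fold."""
    if consumption_ug <= 0:
        raise ValueError("consumption must be strictly positive")
    return round_half_away_from_zero(consumption_ug * NG_PER_UG / eec.concentration)


def margin_vs_lc50(consumption_ug: float, lc50_ug: float) -> float:
    """Fold margin of the ingested dose over a per-larva LC50, unrounded
    (rounding is a display concern)."""
    if lc50_ug <= 0:
        raise ValueError("LC50 must be strictly positive")
    if consumption_ug <= 0:
        raise ValueError("consumption must be strictly positive")
    return consumption_ug / lc50_ug


def margin_report(
    regimen: FeedingRegimen | None,
    eecs: Mapping[str, float],
    consumption_override: float | None = None,
    lc50_ug: float | None = None,
) -> MarginReport:
    """Full worst-case margin-of-exposure report over a set of tissue EECs."""
    if regimen is None and consumption_override is None:
        raise ValueError("either a feeding regimen or a consumption override is required")
    consumption, source = per_capita_consumption(
        regimen or FeedingRegimen(), override=consumption_override
    )
    margins = {
        tissue: margin_vs_tissue(consumption, TissueEEC(tissue, conc))
        for tissue, conc in eecs.items()
    }
    lc50_fold = margin_vs_lc50(consumption, lc50_ug) if lc50_ug is not None else None
    return MarginReport(consumption, source, margins, lc50_fold)
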