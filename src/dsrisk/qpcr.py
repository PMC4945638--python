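"""RT-qPCR analysis: standard-curve efficiency, reference-gene stability,
and Livak 2^-ΔΔCt relative expression.

The Livak method normalises the target gene's cycle threshold (Ct) to a
reference gene within each biological replicate (ΔCt = Ct_target −
Ct_reference), then to a calibrator condition (ΔΔCt = ΔCt − mean calibrator
ΔCt); fold expression is 2^−ΔΔCt. Technical replicates are averaged
(arithmetic mean of Ct) before any biological-replicate statistics — the
standard Livak convention.

A condition's reported fold is 2^−(mean ΔΔCt), i.e. the geometric mean of
the per-replicate folds, which makes the calibrator's own fold exactly 1;
the SE is computed across the per-replicate folds on the 2^−ΔΔCt scale.
Amplification efficiency from the standard-curve slope is reported for QC
but does not correct the model (plain Livak assumes ~100%).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

CT_COLUMNS = ["sample_id", "gene", "treatment", "day", "biological_rep", "technical_rep", "ct"]


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Ct versus log10 template amount: slope (cycles per 10-fold dilution),
    intercept, fit quality, and amplification efficiency
    (10^(−1/slope) − 1; 1.0 means perfect doubling per cycle)."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclasses.dataclass(frozen=True)
class ExpressionResult:
    treatment: str
    day: int
    relative_expression: float
    se: float
    n: int
    calibrator: str


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of mean Ct on log10 template amount.

    Needs >= 3 dilution points with distinct x values.
    """
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("dilution series is degenerate (all x equal)")
    res = sps.linregress(x, y)
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r
                           for r in records])
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def relative_expression(
    records,
    target_gene: str,
    reference_gene: str,
    calibrator: tuple[str, int],
) -> list[ExpressionResult]:
    """Livak 2^-ΔΔCt fold expression per (treatment, day) condition.

    ``calibrator`` is the (treatment, day) whose fold is defined as 1.
    Every (condition, biological replicate) must carry Ct for both genes;
    missing reference measurements are reported by sample.
    """
    df = _as_frame(records)
    # average technical replicates first
    agg = (
        df.groupby(["treatment", "day", "biological_rep", "gene"], as_index=False)["ct"]
        .mean()
    )
    wide = agg.pivot_table(
        index=["treatment", "day", "biological_rep"], columns="gene", values="ct"
    )
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    incomplete = wide[wide[[target_gene, reference_gene]].isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            "missing target/reference Ct for samples: "
            + ", ".join(map(str, incomplete.index.tolist()))
        )
    dct = wide[target_gene] - wide[reference_gene]
    cal_mask = (
        (dct.index.get_level_values("treatment") == calibrator[0])
        & (dct.index.get_level_values("day") == calibrator[1])
    )
    if not cal_mask.any():
        raise ValueError(f"calibrator condition {calibrator} not present")
    ddct = dct - dct[cal_mask].mean()
    fold = 2.0 ** (-ddct)

    results = []
    for (trt, day), grp in fold.groupby(level=["treatment", "day"]):
        n = len(grp)
        point = 2.0 ** (-ddct.loc[(trt, day)].mean())
        se = float(grp.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        results.append(
            ExpressionResult(
                treatment=str(trt),
                day=int(day),
                relative_expression=float(point),
                se=se,
                n=n,
                calibrator=f"{calibrator[0]}/day{calibrator[1]}",
            )
        )
    return results


def reference_stability(records, gene: str) -> pd.DataFrame:
    """Per-condition mean/SD of a candidate reference gene's Ct plus the
    overall coefficient of variation.

    Produces the summary on which the stability judgement rests; it does not
    accept or reject automatically.
    """
    df = _as_frame(records)
    sub = df[df["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from Ct table")
    counts = sub.groupby(["treatment", "day"])["ct"].size()
    if (counts < 2).any():
        raise ValueError("reference stability needs >= 2 records per condition")
    out = (
        sub.groupby(["treatment", "day"])["ct"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .reset_index()
    )
    out.attrs["overall_cv"] = float(sub["ct"].std(ddof=1) / sub["ct"].mean())
    return out
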