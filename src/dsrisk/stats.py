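"""Endpoint statistics for the dietary toxicity and dsRNA stability assays.

One-way ANOVA (with LSD post hoc on the pooled mean-square error), balanced
two-way ANOVA for expression dynamics over treatment x day, tie-corrected
Kruskal–Wallis for the non-normal gel-band intensity series, the chi-squared
and F upper-tail functions needed to reproduce printed p-values from printed
statistics, and percent-of-baseline normalisation of band intensities.

Proportion endpoints (survival, hatch rate) are analysed untransformed by
default; an arcsine-square-root transform is available but off by default.
LSD p-values are deliberately unadjusted for multiplicity — that is what a
least-significant-difference test is.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    term: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    ms_error: float | None = None  # pooled MSE, carried for LSD post hoc


@dataclasses.dataclass(frozen=True)
class KruskalResult:
    h_statistic: float
    df: int
    p_value: float
    tie_corrected: bool


def arcsine_sqrt(p: Sequence[float]) -> np.ndarray:
    """Variance-stabilising transform for proportions."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(arr))


def chisq_upper_tail(x: float, df: int) -> float:
    """P(X >= x) for X ~ chi-squared with df degrees of freedom."""
    if x < 0:
        raise ValueError("chi-squared statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.chi2.sf(x, df))


def f_upper_tail(x: float, df1: int, df2: int) -> float:
    """P(X >= x) for X ~ F(df1, df2)."""
    if x < 0:
        raise ValueError("F statistic must be non-negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(sps.f.sf(x, df1, df2))


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA via the sum-of-squares
    decomposition SS_total = SS_between + SS_within."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    allv = np.concatenate(list(arrays.values()))
    grand = allv.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_num = len(arrays) - 1
    df_den = len(allv) - len(arrays)
    if ss_within == 0:
        raise ValueError("zero residual variance: all observations identical within groups")
    ms_between = ss_between / df_num
    ms_within = ss_within / df_den
    f = ms_between / ms_within
    return AnovaResult("treatment", float(f), df_num, df_den,
                       f_upper_tail(f, df_num, df_den), ms_error=float(ms_within))


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "treatment",
    factor_b: str = "day",
    interaction: bool = True,
) -> list[AnovaResult]:
    """Two-way fixed-effects ANOVA (treatment x day crossed design).

    Uses the balanced-design decomposition; for unbalanced data Type II sums
    of squares are used. With the interaction term, every factor cell must
    hold >= 2 replicates.
    """
    df = data.copy()
    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from data")
    cells = df.groupby([factor_a, factor_b]).size()
    if interaction and (cells < 2).any():
        raise ValueError("interaction requested but some cells have < 2 replicates")
    op = "*" if interaction else "+"
    formula = f"{response} ~ C({factor_a}) {op} C({factor_b})"
    fit = smf.ols(formula, data=df).fit()
    balanced = cells.nunique() == 1
    table = anova_lm(fit, typ=1 if balanced else 2)
    df_den = int(table.loc["Residual", "df"])
    mse = float(table.loc["Residual", "sum_sq"] / df_den)
    term_names = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    results = []
    for row, label in term_names.items():
        if row not in table.index:
            continue
        results.append(
            AnovaResult(
                term=label,
                f_statistic=float(table.loc[row, "F"]),
                df_num=int(table.loc[row, "df"]),
                df_den=df_den,
                p_value=float(table.loc[row, "PR(>F)"]),
                ms_error=mse,
            )
        )
    return results


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]], tie_correction: bool = True
) -> KruskalResult:
    """Kruskal–Wallis k-group rank test, H referred to chi-squared(k-1).

    H is computed from mid-ranks; with ``tie_correction`` (default, matching
    common statistical-package behaviour) H is divided by
    1 − Σ(t³−t)/(n³−n) over tie groups of size t.
    """
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    sizes = [len(a) for a in arrays]
    n = sum(sizes)
    if n < 3:
        raise ValueError("Kruskal-Wallis needs total n >= 3")
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        raise ValueError("degenerate ranking: all values tied across all groups")
    ranks = sps.rankdata(allv)  # mid-ranks
    h = 0.0
    offset = 0
    for size in sizes:
        r = ranks[offset : offset + size]
        h += r.sum() ** 2 / size
        offset += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    if tie_correction:
        _, counts = np.unique(allv, return_counts=True)
        correction = 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)
        h /= correction
    df = len(groups) - 1
    return KruskalResult(float(h), df, chisq_upper_tail(float(h), df), tie_correction)


def lsd_posthoc(
    groups: Mapping[str, Sequence[float]],
    anova: AnovaResult | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons using the ANOVA pooled MSE.

    p-values are unadjusted two-sided t tail probabilities at the ANOVA
    residual df. Runs the one-way ANOVA itself when not supplied.
    """
    if anova is None:
        anova = one_way_anova(groups)
    if anova.ms_error is None:
        raise ValueError("ANOVA result carries no pooled MSE")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    rows = []
    for (na, a), (nb, b) in itertools.combinations(arrays.items(), 2):
        diff = a.mean() - b.mean()
        se = math.sqrt(anova.ms_error * (1 / len(a) + 1 / len(b)))
        t = diff / se
        p = 2.0 * float(sps.t.sf(abs(t), anova.df_den))
        rows.append(
            {"group_a": na, "group_b": nb, "mean_diff": diff, "t": t,
             "df": anova.df_den, "p_value": p, "significant": p < alpha}
        )
    return pd.DataFrame(rows)


def normalize_band_intensity(
    series: Sequence[tuple[float, float]], baseline_index: int = 0
) -> list[tuple[float, float]]:
    """Express a (timepoint, pixel intensity) series as percent of the
    baseline timepoint (first by default)."""
    series = list(series)
    if not series:
        raise ValueError("empty intensity series")
    baseline = series[baseline_index][1]
    if baseline <= 0:
        raise ValueError("baseline intensity must be > 0")
    return [(t, 100.0 * v / baseline) for t, v in series]

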