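"""Diet composition, prey-length summaries and contingency-table statistics.

Composition percentages are computed over *identified* items only: items
whose taxon could not be determined at all ("unknown") stay in the table
but never enter a composition denominator.  Length summaries likewise use
measured items only and report the exclusion count.

The age-effect contingency analysis builds one 2x2 table per nest
(young vs. old brood x earthworm vs. other, at the item level, or
OnlyE vs. other visits at the visit level), applies a two-sided Fisher
exact test per nest, and pools the per-nest p-values with Fisher's combined
probability test: X = -2 * sum(ln p) ~ chi-square with 2k degrees of
freedom under the global null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AgeClass, FeedingVisit, VisitType

__all__ = [
    "CompositionSummary",
    "LengthSummary",
    "ContingencyResult",
    "composition",
    "visit_type_proportions",
    "length_summary",
    "fisher_exact_2x2",
    "fisher_combined",
    "age_contingency",
]


@dataclass(frozen=True)
class CompositionSummary:
    """Per-taxon counts/percentages over identified prey items."""

    counts: dict
    total_identified: int
    excluded_unknown: int

    @property
    def percentages(self) -> dict:
        return {
            t: 100.0 * n / self.total_identified for t, n in self.counts.items()
        }

    def percentage(self, taxon: str) -> float:
        return round(100.0 * self.counts.get(taxon, 0) / self.total_identified, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: -kv[1])
        return pd.DataFrame(
            [
                {"taxon": t, "count": n, "percent": round(100 * n / self.total_identified, 1)}
                for t, n in rows
            ]
        )


def composition(visits: Sequence[FeedingVisit]) -> CompositionSummary:
    """Tabulate diet composition by taxon over identified items."""
    if len(visits) == 0:
        raise ValueError("cannot summarise an empty visit table")
    counts: dict[str, int] = {}
    unknown = 0
    for v in visits:
        for it in v.items:
            if not it.is_identified:
                unknown += 1
                continue
            counts[it.taxon] = counts.get(it.taxon, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no identified items in the visit table")
    return CompositionSummary(counts=counts, total_identified=total, excluded_unknown=unknown)


def visit_type_proportions(visits: Sequence[FeedingVisit]) -> pd.DataFrame:
    """Counts and shares of NoE / OnlyE / MIX visits, plus YesE = OnlyE + MIX."""
    n = len(visits)
    counts = {t.value: 0 for t in VisitType}
    for v in visits:
        counts[v.visit_type.value] += 1
    counts["YesE"] = counts["OnlyE"] + counts["MIX"]
    rows = [
        {"visit_type": k, "count": c, "percent": round(100.0 * c / n, 1) if n else float("nan")}
        for k, c in counts.items()
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LengthSummary:
    n: int
    mean_cm: float
    sd_cm: float  # sample (n-1) SD; NaN when n < 2
    min_cm: float
    max_cm: float
    n_unmeasured: int


def _summarise(lengths: list[float], n_unmeasured: int) -> LengthSummary:
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        return LengthSummary(0, float("nan"), float("nan"), float("nan"), float("nan"), n_unmeasured)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return LengthSummary(
        n=int(arr.size),
        mean_cm=float(arr.mean()),
        sd_cm=sd,
        min_cm=float(arr.min()),
        max_cm=float(arr.max()),
        n_unmeasured=n_unmeasured,
    )


def length_summary(visits: Sequence[FeedingVisit]) -> dict[str, LengthSummary]:
    """Mean/SD/min/max of measured prey lengths: overall, earthworms, other.

    Unmeasured items are excluded from the statistics; their count is
    carried in each summary.
    """
    overall: list[float] = []
    worms: list[float] = []
    other: list[float] = []
    miss = {"overall": 0, "earthworm": 0, "other": 0}
    for v in visits:
        for it in v.items:
            key = "earthworm" if it.is_earthworm else "other"
            if it.length_cm is None:
                miss["overall"] += 1
                miss[key] += 1
                continue
            overall.append(it.length_cm)
            (worms if it.is_earthworm else other).append(it.length_cm)
    return {
        "overall": _summarise(overall, miss["overall"]),
        "earthworm": _summarise(worms, miss["earthworm"]),
        "other": _summarise(other, miss["other"]),
    }


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 count table.

    Uses the standard two-sided rule: the p-value is the total probability,
    under the fixed-margins hypergeometric null, of all tables whose
    probability does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if t.sum() == 0:
        raise ValueError("all-zero table has no sampling distribution")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0))


@dataclass(frozen=True)
class ContingencyResult:
    """Per-nest exact tests pooled by Fisher's combined probability test."""

    tables: dict = field(default_factory=dict)  # nest_id -> 2x2 np.ndarray
    p_values: dict = field(default_factory=dict)  # nest_id -> exact p
    statistic: float = float("nan")  # -2 * sum(ln p)
    df: int = 0  # 2 * number of pooled nests
    combined_p: float = float("nan")
    skipped_nests: tuple[str, ...] = ()


def fisher_combined(p_values: Iterable[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test over independent p-values.

    Returns ``(statistic, df, combined_p)`` with statistic
    X = -2 * sum(ln p) referred to a chi-square with 2k df.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if ((ps <= 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat, p = stats.combine_pvalues(ps, method="fisher")
    return float(stat), 2 * int(ps.size), float(p)


def age_contingency(
    visits: Sequence[FeedingVisit],
    mode: Literal["items", "visits"] = "items",
) -> ContingencyResult:
    """Test the nestling-age effect on earthworm prevalence, nest by nest.

    ``mode="items"`` crosses age class (young/old) with item identity
    (earthworm vs. other identified prey); ``mode="visits"`` crosses age
    class with visit type (OnlyE vs. all other visits).  Nests where one
    age class is unobserved contribute no information and are skipped with
    a warning, shrinking the combined df accordingly.
    """
    tables: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    nests = sorted({v.nest_id for v in visits})
    for nest in nests:
        nv = [v for v in visits if v.nest_id == nest]
        t = np.zeros((2, 2), dtype=int)
        for v in nv:
            row = 0 if v.age_class is AgeClass.YOUNG else 1
            if mode == "items":
                for it in v.items:
                    if not it.is_identified:
                        continue
                    t[row, 0 if it.is_earthworm else 1] += 1
            else:
                t[row, 0 if v.visit_type is VisitType.ONLYE else 1] += 1
        if t.sum(axis=1).min() == 0:  # one age class absent
            skipped.append(nest)
            warnings.warn(
                f"nest {nest}: one age class unobserved; excluded from the combined test"
            )
            continue
        tables[nest] = t
    if not tables:
        raise ValueError("no nest has both age classes represented")
    p_values = {nest: fisher_exact_2x2(t) for nest, t in tables.items()}
    stat, df, comb = fisher_combined(p_values.values())
    return ContingencyResult(
        tables=tables,
        p_values=p_values,
        statistic=stat,
        df=df,
        combined_p=comb,
        skipped_nests=tuple(skipped),
    )
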