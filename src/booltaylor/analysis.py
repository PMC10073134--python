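"""Group-level statistics for approximability values.

Compares distributions of (linear) approximability across categories of
network models with Welch's unequal-variances t-test (difference of means)
and the F-test of equality of variances, both two-sided.  Raw pairwise
p-values are reported by default; an optional Bonferroni correction is
available for the all-pairs category comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "welch_t_test",
    "f_variance_test",
    "category_report",
    "CategoryReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a two-sample test."""

    labels: tuple[str, str]
    test: str
    statistic: float
    p_value: float
    tails: int = 2
    n: tuple[int, int] = (0, 0)
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _as_arrays(a: Sequence[float], b: Sequence[float], min_n: int):
    av = np.asarray(a, dtype=np.float64)
    bv = np.asarray(b, dtype=np.float64)
    if av.ndim != 1 or bv.ndim != 1:
        raise ValueError("samples must be 1-D")
    if av.size < min_n or bv.size < min_n:
        raise ValueError(f"each sample needs at least {min_n} values")
    return av, bv


def welch_t_test(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Two-sided Welch's unequal-variances t-test with Satterthwaite df.

    Degenerate inputs (both samples with zero variance) are flagged in the
    ``note`` field: identical constants give statistic 0 and p = 1, distinct
    constants give an infinite statistic and p = 0.
    """
    av, bv = _as_arrays(a, b, min_n=2)
    if av.var(ddof=1) == 0.0 and bv.var(ddof=1) == 0.0:
        if av.mean() == bv.mean():
            return GroupComparison(
                labels, "welch_t", 0.0, 1.0, n=(av.size, bv.size),
                note="degenerate: both samples constant and equal",
            )
        return GroupComparison(
            labels, "welch_t", math.inf, 0.0, n=(av.size, bv.size),
            note="degenerate: both samples constant, means differ",
        )
    res = sps.ttest_ind(av, bv, equal_var=False)
    return GroupComparison(
        labels, "welch_t", float(res.statistic), float(res.pvalue),
        n=(av.size, bv.size),
    )


def f_variance_test(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Two-sided F-test of equality of variances.

    ``F = var(a) / var(b)`` (sample variances, ddof 1) referred to an
    F(n_a - 1, n_b - 1) distribution; the two-sided p-value is twice the
    smaller tail.  Zero variance in the denominator raises.
    """
    av, bv = _as_arrays(a, b, min_n=2)
    var_a = av.var(ddof=1)
    var_b = bv.var(ddof=1)
    if var_b == 0.0:
        raise ValueError("zero variance in denominator sample")
    f = float(var_a / var_b)
    dfa, dfb = av.size - 1, bv.size - 1
    cdf = sps.f.cdf(f, dfa, dfb)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return GroupComparison(labels, "f_variance", f, p, n=(av.size, bv.size))


@dataclass(frozen=True)
class CategoryReport:
    """Per-category distributions with all-pairs variance comparisons.

    Categories are ordered by increasing variance; singleton or empty
    categories are excluded (and listed in ``excluded``).
    """

    values: dict[str, tuple[float, ...]]
    order_by_variance: tuple[str, ...]
    comparisons: tuple[GroupComparison, ...]
    excluded: tuple[str, ...] = ()
    bonferroni: bool = False

    def variance(self, category: str) -> float:
        return float(np.var(self.values[category], ddof=1))

    def significant_pairs(self, alpha: float = 0.05) -> list[GroupComparison]:
        return [c for c in self.comparisons if c.p_value < alpha]


def category_report(
    values: Mapping[str, float],
    labels: Mapping[str, str],
    bonferroni: bool = False,
) -> CategoryReport:
    """Group per-model values by category and compare category variances.

    Parameters
    ----------
    values:
        Per-model scalar values, e.g. linear approximability.
    labels:
        Per-model category label.  Models missing from either mapping, or
        with an empty label, are skipped.
    bonferroni:
        Multiply pairwise p-values by the number of comparisons (capped at
        1).  Off by default: raw pairwise p-values.
    """
    groups: dict[str, list[float]] = {}
    for model, value in values.items():
        cat = labels.get(model, "")
        if not cat:
            logger.warning("category_report: model %r has no category label", model)
            continue
        groups.setdefault(cat, []).append(float(value))

    kept: dict[str, tuple[float, ...]] = {}
    excluded: list[str] = []
    for cat, vals in groups.items():
        if len(vals) < 2:
            logger.warning(
                "category_report: category %r has %d model(s); excluded from "
                "variance comparisons", cat, len(vals),
            )
            excluded.append(cat)
        else:
            kept[cat] = tuple(vals)

    ordered = tuple(sorted(kept, key=lambda c: np.var(kept[c], ddof=1)))
    comparisons = []
    for i, ca in enumerate(ordered):
        for cb in ordered[i + 1 :]:
            comparisons.append(f_variance_test(kept[ca], kept[cb], labels=(ca, cb)))
    if bonferroni and comparisons:
        m = len(comparisons)
        comparisons = [
            GroupComparison(
                c.labels, c.test, c.statistic, min(1.0, c.p_value * m),
                n=c.n, note=f"bonferroni m={m}",
            )
            for c in comparisons
        ]
    return CategoryReport(
        values=kept,
        order_by_variance=ordered,
        comparisons=tuple(comparisons),
        excluded=tuple(sorted(excluded)),
        bonferroni=bonferroni,
    )
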