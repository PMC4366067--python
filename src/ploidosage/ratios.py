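"""Pairwise fold-change profiles between genomotype expression tables.

A profile divides each gene's abundance in a numerator library by its
abundance in a denominator library.  Ordered log2 ratios form the
characteristic "crescent curve": positive values mark genes expressed higher
in the numerator, negative values lower.  Chi-square tests ask whether the
lower/higher split departs from the 50:50 expected under no global shift
(goodness of fit) or differs between two comparisons (2x2 homogeneity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnalysisConfig, ExpressionTable, InvalidInputError

__all__ = [
    "RatioRecord",
    "ProfileResult",
    "ProfileSummary",
    "ratio_profile",
    "summarize_profile",
    "chi_square_goodness",
    "chi_square_2x2",
    "records_to_frame",
]


@dataclass(frozen=True)
class RatioRecord:
    """Per-gene fold change between two libraries (numerator / denominator)."""

    gene_id: str
    numerator_abundance: float
    denominator_abundance: float
    fold_change: float
    log2_ratio: float


@dataclass
class ProfileResult:
    """Ratio records plus the number of genes dropped by the zero policy."""

    records: list[RatioRecord]
    n_dropped: int


@dataclass
class ProfileSummary:
    n_positive: int
    n_negative: int
    n_zero: int
    median_log2: float
    ordered_log2: list[float]


def ratio_profile(
    numerator: ExpressionTable,
    denominator: ExpressionTable,
    config: AnalysisConfig | None = None,
) -> ProfileResult:
    """Fold change and log2 ratio for every gene shared by the two tables.

    Zero abundances are handled per ``config.zero_policy``: under ``exclude``
    genes with a zero in either library are dropped (count reported in
    ``n_dropped``); under ``pseudocount`` both abundances are shifted by
    ``config.pseudocount`` before dividing.
    """
    config = config or AnalysisConfig()
    shared = numerator.gene_ids.intersection(denominator.gene_ids)
    if len(shared) == 0:
        raise InvalidInputError("tables share no gene ids")
    num = numerator.abundances.loc[shared].to_numpy()
    den = denominator.abundances.loc[shared].to_numpy()

    if config.zero_policy == "pseudocount":
        num = num + config.pseudocount
        den = den + config.pseudocount
        keep = (num > 0) & (den > 0)  # pseudocount 0 with zero abundance still drops
    else:
        keep = (num > 0) & (den > 0)
    n_dropped = int((~keep).sum())

    fold = num[keep] / den[keep]
    log2r = np.log2(fold)
    records = [
        RatioRecord(
            gene_id=str(g),
            numerator_abundance=float(a),
            denominator_abundance=float(b),
            fold_change=float(f),
            log2_ratio=float(l),
        )
        for g, a, b, f, l in zip(shared[keep], num[keep], den[keep], fold, log2r)
    ]
    return ProfileResult(records=records, n_dropped=n_dropped)


def summarize_profile(records: Sequence[RatioRecord]) -> ProfileSummary:
    """Sign counts, median and the ordered log2 ratios of a profile.

    The median follows the midpoint convention (mean of the two central order
    statistics for even n); exact zeros are counted separately from the
    positive/negative tallies.
    """
    if not records:
        raise InvalidInputError("cannot summarize an empty profile")
    log2r = np.array([r.log2_ratio for r in records], dtype=float)
    ordered = np.sort(log2r)
    return ProfileSummary(
        n_positive=int((log2r > 0).sum()),
        n_negative=int((log2r < 0).sum()),
        n_zero=int((log2r == 0).sum()),
        median_log2=float(np.median(ordered)),
        ordered_log2=[float(x) for x in ordered],
    )


def chi_square_goodness(n_lower: int, n_higher: int) -> tuple[float, float]:
    """1-df chi-square of a lower/higher count pair against a 50:50 split.

    No continuity correction; the p-value comes from the chi-square(1)
    survival function.
    """
    if n_lower < 0 or n_higher < 0:
        raise InvalidInputError("counts must be nonnegative")
    n = n_lower + n_higher
    if n == 0:
        raise InvalidInputError("at least one count must be positive")
    expected = n / 2.0
    statistic = (n_lower - expected) ** 2 / expected + (n_higher - expected) ** 2 / expected
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """1-df contingency chi-square (no continuity correction) of the table
    ``[[a, b], [c, d]]`` — rows are two comparisons, columns lower/higher."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise InvalidInputError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidInputError("all row and column totals must be positive")
    statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


def records_to_frame(records: Sequence[RatioRecord]) -> pd.DataFrame:
    """Tabular view of a profile, one row per gene."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "numerator_abundance": [r.numerator_abundance for r in records],
            "denominator_abundance": [r.denominator_abundance for r in records],
            "fold_change": [r.fold_change for r in records],
            "log2_ratio": [r.log2_ratio for r in records],
        }
    )
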