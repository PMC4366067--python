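"""Similar-expression thresholding, dosage classes, and DE calling.

Two orthogonal calls are made per gene on the triploid/diploid (PAA/PA)
comparison:

* **SE (similar expression)** — ``|log2(fold change)| < 1`` (strict).  SE
  genes are partitioned into four dosage classes by their fold change:

  ======  =====================  ============================================
  class   fold-change interval   interpretation
  ======  =====================  ============================================
  I       [0.75, 1.25]           dosage compensated (triploid at diploid level)
  II      (1.25, 1.75]           dosage sensitive (ratio near 1.5, i.e. 3:2)
  III     < 0.75                 repressed beyond compensation
  IV      > 1.75                 overexpressed
  ======  =====================  ============================================

  The published interval notation leaves the boundary points unassigned;
  here class I is closed and class II half-open, so boundary ties resolve to
  the more conservative compensated/sensitive labels.  The bounds are
  configurable via :class:`~ploidosage.core.AnalysisConfig.class_bounds`.

* **DE (differential expression)** — significance from a per-gene exact test
  on the two libraries' fragment counts, corrected by the dependent-test FDR
  step-up of Benjamini and Yekutieli, with q <= 0.05 as the default cutoff.
  DE genes split into DEH (higher in the triploid) and DEL (lower).

The per-gene p-value engine here is a two-library exact binomial test (the
count in library A against Binomial(total, library-size share of A)); with a
single library per genomotype there is no replication from which to estimate
biological dispersion, so no dispersion model is fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import AnalysisConfig, ContractError, InvalidInputError, round_half_away
from .ratios import RatioRecord

__all__ = [
    "DosageClassRecord",
    "ClassTally",
    "classify_similarity",
    "assign_dosage_class",
    "de_exact_test",
    "fdr_adjust_dependent",
    "classify_records",
    "tally",
]

DOSAGE_CLASSES = ("I", "II", "III", "IV")
DE_GROUPS = ("DEH", "DEL")


@dataclass
class DosageClassRecord:
    """Per-gene similarity/dosage-class/DE status."""

    gene_id: str
    fold_change: float
    se_flag: bool
    dosage_class: str  # "I".."IV" or "NA"
    raw_p: Optional[float] = None
    fdr_q: Optional[float] = None
    de_flag: Optional[bool] = None
    de_direction: Optional[str] = None  # higher_in_triploid | lower_in_triploid | none


@dataclass
class ClassTally:
    """Counts and rounded percentages for the SE classes and DE groups.

    Percentages use round-half-away-from-zero; per-class and per-group
    percentages are integers, the DE share of the total is reported to one
    decimal.
    """

    n_total: int
    n_se: int
    n_de: int
    per_class: dict[str, int]
    per_de_group: dict[str, int]
    pct_se_of_total: int
    pct_class_of_se: dict[str, int]
    pct_class_of_total: dict[str, int]
    pct_de_of_total: float
    pct_group_of_de: dict[str, int]
    pct_group_of_total: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_se": self.n_se,
            "n_de": self.n_de,
            "per_class": dict(self.per_class),
            "per_de_group": dict(self.per_de_group),
            "pct_se_of_total": self.pct_se_of_total,
            "pct_class_of_se": dict(self.pct_class_of_se),
            "pct_class_of_total": dict(self.pct_class_of_total),
            "pct_de_of_total": self.pct_de_of_total,
            "pct_group_of_de": dict(self.pct_group_of_de),
            "pct_group_of_total": dict(self.pct_group_of_total),
        }


def classify_similarity(fold_change: float, config: AnalysisConfig | None = None) -> bool:
    """True iff ``|log2(fold_change)| < se_log2_threshold`` (strict)."""
    config = config or AnalysisConfig()
    if not (fold_change > 0) or not math.isfinite(fold_change):
        raise InvalidInputError("fold_change must be a positive finite number")
    return abs(math.log2(fold_change)) < config.se_log2_threshold


def assign_dosage_class(fold_change: float, config: AnalysisConfig | None = None) -> str:
    """Dosage class of an SE fold change (see module docstring for intervals).

    Raises :class:`ContractError` when called on a non-SE fold change.
    """
    config = config or AnalysisConfig()
    if not classify_similarity(fold_change, config):
        raise ContractError(
            f"fold change {fold_change:g} is outside the similar-expression band"
        )
    b_low, b_mid, b_high = config.class_bounds
    if fold_change < b_low:
        return "III"
    if fold_change <= b_mid:
        return "I"
    if fold_change <= b_high:
        return "II"
    return "IV"


def de_exact_test(
    count_a: int, count_b: int, libsize_a: int, libsize_b: int
) -> float:
    """Two-sided exact binomial test of two library counts for one gene.

    Under the null of equal relative abundance, ``count_a`` given the total
    ``count_a + count_b`` is Binomial(total, libsize_a / (libsize_a +
    libsize_b)); two-sidedness sums the probabilities of all outcomes no more
    likely than the observed one.  Returns 1.0 when both counts are zero.
    """
    if libsize_a <= 0 or libsize_b <= 0:
        raise InvalidInputError("library sizes must be positive")
    if count_a < 0 or count_b < 0:
        raise InvalidInputError("counts must be nonnegative")
    n = count_a + count_b
    if n == 0:
        return 1.0
    share = libsize_a / (libsize_a + libsize_b)
    return float(stats.binomtest(count_a, n=n, p=share, alternative="two-sided").pvalue)


def fdr_adjust_dependent(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up q-values, valid under arbitrary dependence.

    q_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with
    c(m) = sum_{k=1..m} 1/k; the output is returned in input order.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("raw_p must be a nonempty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    c_m = float(np.sum(1.0 / np.arange(1, m + 1)))
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(ranked[::-1])[::-1]
    stepped = np.minimum(stepped, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = stepped
    return out


def classify_records(
    ratios: Sequence[RatioRecord],
    config: AnalysisConfig | None = None,
    numerator_counts: Optional[Mapping[str, int]] = None,
    denominator_counts: Optional[Mapping[str, int]] = None,
    libsize_numerator: Optional[int] = None,
    libsize_denominator: Optional[int] = None,
) -> list[DosageClassRecord]:
    """SE/class calls for every ratio record, plus DE calls when counts exist.

    When both count maps are provided, each gene receives an exact-test raw
    p-value; q-values come from one dependent-test FDR pass over all genes.
    Library sizes default to the count totals.
    """
    config = config or AnalysisConfig()
    records: list[DosageClassRecord] = []
    for r in ratios:
        se = classify_similarity(r.fold_change, config)
        cls = assign_dosage_class(r.fold_change, config) if se else "NA"
        records.append(
            DosageClassRecord(gene_id=r.gene_id, fold_change=r.fold_change,
                              se_flag=se, dosage_class=cls)
        )

    if numerator_counts is not None and denominator_counts is not None:
        lib_a = libsize_numerator or int(sum(numerator_counts.values()))
        lib_b = libsize_denominator or int(sum(denominator_counts.values()))
        testable = [
            rec for rec in records
            if rec.gene_id in numerator_counts and rec.gene_id in denominator_counts
        ]
        raw = [
            de_exact_test(
                int(numerator_counts[rec.gene_id]),
                int(denominator_counts[rec.gene_id]),
                lib_a,
                lib_b,
            )
            for rec in testable
        ]
        if raw:
            qs = fdr_adjust_dependent(raw)
            for rec, p, q in zip(testable, raw, qs):
                rec.raw_p = float(p)
                rec.fdr_q = float(q)
                rec.de_flag = bool(q <= config.fdr_alpha)
                if rec.de_flag:
                    rec.de_direction = (
                        "higher_in_triploid" if rec.fold_change > 1
                        else "lower_in_triploid"
                    )
                else:
                    rec.de_direction = "none"
    return records


def tally(records: Sequence[DosageClassRecord]) -> ClassTally:
    """Aggregate SE-class and DE-group counts with reported-style percentages."""
    if not records:
        raise InvalidInputError("cannot tally an empty record list")
    n_total = len(records)
    per_class = {c: 0 for c in DOSAGE_CLASSES}
    for rec in records:
        if rec.se_flag:
            per_class[rec.dosage_class] += 1
    n_se = sum(per_class.values())
    per_group = {g: 0 for g in DE_GROUPS}
    for rec in records:
        if rec.de_flag:
            if rec.de_direction == "higher_in_triploid":
                per_group["DEH"] += 1
            elif rec.de_direction == "lower_in_triploid":
                per_group["DEL"] += 1
    n_de = sum(per_group.values())

    def pct(n: int, d: int, nd: int = 0) -> float:
        if d == 0:
            return 0.0 if nd else 0
        v = round_half_away(100.0 * n / d, nd)
        return v if nd else int(v)

    return ClassTally(
        n_total=n_total,
        n_se=n_se,
        n_de=n_de,
        per_class=per_class,
        per_de_group=per_group,
        pct_se_of_total=pct(n_se, n_total),
        pct_class_of_se={c: pct(per_class[c], n_se) for c in DOSAGE_CLASSES},
        pct_class_of_total={c: pct(per_class[c], n_total) for c in DOSAGE_CLASSES},
        pct_de_of_total=pct(n_de, n_total, 1),
        pct_group_of_de={g: pct(per_group[g], n_de) for g in DE_GROUPS},
        pct_group_of_total={g: pct(per_group[g], n_total, 2) for g in DE_GROUPS},
    )
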