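"""Mid-parent (additivity) expectation for hybrid expression.

If each haplome copy in a hybrid transcribed exactly as it does in the
corresponding parental diploid, a hybrid gene's expected abundance is the
copy-weighted half-sum of the parental diploid values:

    expected = (copies_P * PP + copies_A * AA) / 2

so PA expects PP/2 + AA/2 and the triploid PAA expects PP/2 + AA/2 + AA/2.
A gene is *additive* when -1 < log2(observed / expected) < 1 (strict);
otherwise it is below or above the additivity expectation.  Genes with a
zero observed or expected value have no finite log ratio and are reported
as ``undefined`` and excluded from percentage summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    ExpressionTable,
    GenomotypeSpec,
    InvalidInputError,
    round_half_away,
)

__all__ = [
    "AdditivityRecord",
    "AdditivityTally",
    "expected_additive",
    "classify_additivity",
    "additivity_profile",
    "additivity_tally",
]

CATEGORIES = ("below_additive", "additive", "above_additive")


@dataclass(frozen=True)
class AdditivityRecord:
    gene_id: str
    observed: float
    expected: float
    log2_obs_over_exp: float  # NaN when undefined
    category: str  # below_additive | additive | above_additive | undefined


@dataclass
class AdditivityTally:
    counts: dict[str, int]
    n_defined: int
    n_undefined: int
    percentages: dict[str, float]  # of defined records, integer-rounded


def expected_additive(
    pp_value: float, aa_value: float, genomotype: GenomotypeSpec
) -> float:
    """Copy-weighted mid-parent expectation for one gene in a P/A hybrid."""
    if pp_value < 0 or aa_value < 0:
        raise InvalidInputError("parental abundances must be nonnegative")
    extra = set(genomotype.haplome_copies) - {"P", "A"}
    if extra:
        raise InvalidInputError(
            f"genomotype {genomotype.label} carries unsupported haplomes: {sorted(extra)}"
        )
    copies_p = genomotype.haplome_copies.get("P", 0)
    copies_a = genomotype.haplome_copies.get("A", 0)
    return (copies_p * pp_value + copies_a * aa_value) / 2.0


def classify_additivity(observed: float, expected: float, window_log2: float = 1.0) -> str:
    """Category of an observed/expected pair under the strict log2 window."""
    if observed < 0 or expected < 0:
        raise InvalidInputError("abundances must be nonnegative")
    if observed == 0 or expected == 0:
        return "undefined"
    log2r = math.log2(observed / expected)
    if -window_log2 < log2r < window_log2:
        return "additive"
    return "below_additive" if observed < expected else "above_additive"


def additivity_profile(
    pp: ExpressionTable,
    aa: ExpressionTable,
    hybrid: ExpressionTable,
    genomotype: GenomotypeSpec,
    config: AnalysisConfig | None = None,
) -> list[AdditivityRecord]:
    """Observed-vs-expected additivity record for every gene shared by the
    parental and hybrid tables."""
    config = config or AnalysisConfig()
    shared = pp.gene_ids.intersection(aa.gene_ids).intersection(hybrid.gene_ids)
    if len(shared) == 0:
        raise InvalidInputError("no gene is shared by the parental and hybrid tables")
    copies_p = genomotype.haplome_copies.get("P", 0)
    copies_a = genomotype.haplome_copies.get("A", 0)
    extra = set(genomotype.haplome_copies) - {"P", "A"}
    if extra:
        raise InvalidInputError(
            f"genomotype {genomotype.label} carries unsupported haplomes: {sorted(extra)}"
        )
    pp_v = pp.abundances.loc[shared].to_numpy()
    aa_v = aa.abundances.loc[shared].to_numpy()
    obs = hybrid.abundances.loc[shared].to_numpy()
    exp = (copies_p * pp_v + copies_a * aa_v) / 2.0

    records = []
    for gid, o, e in zip(shared, obs, exp):
        cat = classify_additivity(float(o), float(e), config.se_log2_threshold)
        log2r = math.log2(o / e) if cat != "undefined" else math.nan
        records.append(
            AdditivityRecord(
                gene_id=str(gid), observed=float(o), expected=float(e),
                log2_obs_over_exp=log2r, category=cat,
            )
        )
    return records


def additivity_tally(records: Sequence[AdditivityRecord]) -> AdditivityTally:
    """Category counts and integer percentages over the defined records."""
    if not records:
        raise InvalidInputError("cannot tally an empty record list")
    counts = {c: 0 for c in CATEGORIES}
    n_undefined = 0
    for rec in records:
        if rec.category == "undefined":
            n_undefined += 1
        else:
            counts[rec.category] += 1
    n_defined = sum(counts.values())
    if n_defined:
        pct = {c: int(round_half_away(100.0 * counts[c] / n_defined)) for c in CATEGORIES}
    else:
        pct = {c: 0 for c in CATEGORIES}
    return AdditivityTally(
        counts=counts, n_defined=n_defined, n_undefined=n_undefined, percentages=pct
    )
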