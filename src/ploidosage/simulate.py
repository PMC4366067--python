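"""Synthetic four-genomotype expression tables and qPCR plates with ground truth.

The generator emulates the structure of the study data so that every pipeline
stage can be exercised with a known answer:

* one RNA-seq library per genomotype (PP, AA, PA, PAA), with log-normal AA
  abundances, a log2-normal divergence offset for PP, hybrids built either as
  exact mid-parent mixtures or from a configurable mixture of triploid/diploid
  dosage-response classes, and independent per-library multiplicative
  (log2-normal) measurement noise applied last;
* a qPCR plate with the study layout — two genomotypes (PA, PAA), five
  biological by three technical replicates, six cDNA target genes and three
  gDNA reference targets — where the true per-genome ratios are configured
  and per-well Gaussian Cq noise is added.

Every gene carries exactly one ground-truth label, so confusion matrices for
the classifier need no external references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import ExpressionTable, InvalidInputError
from .qpcr import DEFAULT_REFERENCE_TARGETS, QpcrSample, QpcrWell

__all__ = [
    "QpcrSimConfig",
    "SimulationConfig",
    "simulate_expression",
    "simulate_qpcr",
    "target_expression_tables",
    "DEFAULT_CLASS_MIXTURE",
    "DEFAULT_TRUE_PER_GENOME_RATIOS",
]

#: Dosage-class mixture matching the triploid/diploid SE-class proportions
#: observed in whole-body juveniles (classes I:II:III:IV = 45:17:34:4).
DEFAULT_CLASS_MIXTURE: Mapping[str, float] = {
    "I": 0.45,
    "II": 0.17,
    "III": 0.34,
    "IV": 0.04,
}

#: Study-like true PAA/PA per-genome ratios for the six qPCR target genes.
DEFAULT_TRUE_PER_GENOME_RATIOS: Mapping[str, float] = {
    "rpl8": 0.8,
    "eef1a": 0.8,
    "actb2": 0.6,
    "rpsa": 0.9,
    "pabpc1a": 0.8,
    "rpl35": 0.8,
}

# Fold-change intervals the generator draws from per label.  Class draws sit
# a small margin inside the classification boundaries so that noiseless data
# classify back into the assigned class despite floating-point round-trips.
_MARGIN = 1e-3
_CLASS_FOLD_INTERVALS = {
    "I": (0.75 + _MARGIN, 1.25 - _MARGIN),
    "II": (1.25 + _MARGIN, 1.75 - _MARGIN),
    "III": (0.5 * (1 + 2 * _MARGIN), 0.75 - _MARGIN),
    "IV": (1.75 + _MARGIN, 2.0 * (1 - _MARGIN)),
}


@dataclass
class QpcrSimConfig:
    """Plate layout and noise for the simulated qPCR assay.

    Defaults mirror the study design: 5 biological x 3 technical replicates
    per genomotype, six cDNA targets, three gDNA reference targets, Cq noise
    of 0.15 cycles per well.
    """

    n_biological: int = 5
    n_technical: int = 3
    cq_noise_sd: float = 0.15
    true_per_genome_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PER_GENOME_RATIOS)
    )
    reference_targets: tuple[str, ...] = DEFAULT_REFERENCE_TARGETS
    baseline_gdna_cq: float = 22.0
    baseline_delta_cq: float = 5.0
    numerator_genomotype: str = "PAA"
    denominator_genomotype: str = "PA"

    def __post_init__(self) -> None:
        if self.n_technical < 1:
            raise InvalidInputError("n_technical must be >= 1")
        if self.n_biological < 1:
            raise InvalidInputError("n_biological must be >= 1")
        if self.cq_noise_sd < 0:
            raise InvalidInputError("cq_noise_sd must be >= 0")
        for g, r in self.true_per_genome_ratios.items():
            if r <= 0:
                raise InvalidInputError(f"true per-genome ratio for {g!r} must be positive")


@dataclass
class SimulationConfig:
    """Ground-truth model for the synthetic expression tables.

    ``class_mixture`` fractions (summing to <= 1) assign true PAA/PA fold
    changes inside the class intervals; labels ``DE_up``/``DE_down`` place
    genes outside the similar-expression band; any remainder is drawn
    log2-uniformly across the SE band.  ``additive_fraction`` genes are built
    as exact mid-parent mixtures instead.  ``measurement_log2_sd`` is the
    standard deviation of independent per-library log2-normal multiplicative
    measurement noise, applied after the true tables are built.
    """

    n_genes: int = 20000
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.2
    parental_divergence_log2_sd: float = 1.0
    additive_fraction: float = 0.0
    measurement_log2_sd: float = 0.2
    library_sizes: dict[str, int] = field(
        default_factory=lambda: {g: 20_000_000 for g in ("PP", "AA", "PA", "PAA")}
    )
    gene_length_range: tuple[int, int] = (500, 5000)
    qpcr: QpcrSimConfig = field(default_factory=QpcrSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidInputError("n_genes must be positive")
        allowed = set(_CLASS_FOLD_INTERVALS) | {"DE_up", "DE_down"}
        bad = set(self.class_mixture) - allowed
        if bad:
            raise InvalidInputError(f"unknown class_mixture labels: {sorted(bad)}")
        total = sum(self.class_mixture.values())
        if any(f < 0 for f in self.class_mixture.values()) or total > 1 + 1e-12:
            raise InvalidInputError("class_mixture fractions must be in [0,1] and sum to <= 1")
        if not 0 <= self.additive_fraction <= 1:
            raise InvalidInputError("additive_fraction must lie in [0, 1]")
        if self.measurement_log2_sd < 0 or self.parental_divergence_log2_sd < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")
        for g, n in self.library_sizes.items():
            if n < 1:
                raise InvalidInputError(f"library size for {g!r} must be positive")


def _allocate_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Integer allocation of n items to labelled fractions (largest remainder);
    the label ``"background"`` absorbs whatever the fractions leave over."""
    labels = list(fractions)
    raw = np.array([fractions[k] * n for k in labels], dtype=float)
    base = np.floor(raw).astype(int)
    short = int(round(raw.sum())) - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="mergesort")
        for i in order[:short]:
            base[i] += 1
    out = dict(zip(labels, (int(b) for b in base)))
    out["background"] = n - int(base.sum())
    return out


def _draw_fold(label: str, rng: np.random.Generator) -> float:
    """True PAA/PA fold change for one gene under its assigned label."""
    if label in _CLASS_FOLD_INTERVALS:
        lo, hi = _CLASS_FOLD_INTERVALS[label]
        return float(2.0 ** rng.uniform(math.log2(lo), math.log2(hi)))
    if label == "DE_up":
        return float(2.0 ** rng.uniform(1.05, 3.0))
    if label == "DE_down":
        return float(2.0 ** rng.uniform(-3.0, -1.05))
    # background: anywhere in the SE band
    return float(2.0 ** rng.uniform(-0.99, 0.99))


def _expected_class(fold: float) -> str:
    if not 0.5 < fold < 2.0:
        return "NA"
    if fold < 0.75:
        return "III"
    if fold <= 1.25:
        return "I"
    if fold <= 1.75:
        return "II"
    return "IV"


def simulate_expression(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionTable], pd.DataFrame]:
    """Generate the four genomotype tables and a per-gene ground-truth frame.

    Returns ``(tables, truth)`` where ``tables`` maps genomotype label to
    :class:`~ploidosage.core.ExpressionTable` and ``truth`` has columns
    ``gene_id``, ``group`` (assigned label), ``dosage_class`` (the class a
    noiseless classifier should call, or NA), ``true_fold_paa_pa`` and
    ``is_additive``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    n = config.n_genes
    gene_ids = np.array([f"g{i:06d}" for i in range(n)])

    aa = rng.lognormal(mean=config.baseline_log_mean, sigma=config.baseline_log_sd, size=n)
    delta = rng.normal(0.0, config.parental_divergence_log2_sd, size=n)
    pp = aa * 2.0 ** delta
    pa_base = (pp + aa) / 2.0  # mid-parent diploid expectation

    n_additive = int(round(config.additive_fraction * n))
    # remaining genes receive class-mixture labels
    alloc = _allocate_counts(n - n_additive, config.class_mixture)
    labels = np.empty(n, dtype=object)
    labels[:n_additive] = "additive"
    pos = n_additive
    for lbl, cnt in alloc.items():
        labels[pos: pos + cnt] = lbl
        pos += cnt
    rng.shuffle(labels)

    pa = pa_base.copy()
    paa = np.empty(n)
    true_fold = np.empty(n)
    is_additive = labels == "additive"
    paa_additive = pp / 2.0 + aa  # PP/2 + AA/2 + AA/2
    for i in range(n):
        if is_additive[i]:
            paa[i] = paa_additive[i]
            true_fold[i] = paa[i] / pa[i] if pa[i] > 0 else math.nan
        else:
            f = _draw_fold(labels[i], rng)
            true_fold[i] = f
            paa[i] = pa[i] * f

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group": labels,
            "dosage_class": [_expected_class(f) for f in true_fold],
            "true_fold_paa_pa": true_fold,
            "is_additive": is_additive,
        }
    )

    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n)
    tables: dict[str, ExpressionTable] = {}
    for geno, values in (("PP", pp), ("AA", aa), ("PA", pa), ("PAA", paa)):
        if config.measurement_log2_sd > 0:
            noise = 2.0 ** rng.normal(0.0, config.measurement_log2_sd, size=n)
            observed = values * noise
        else:
            observed = values.copy()
        libsize = config.library_sizes.get(geno, 20_000_000)
        counts = np.rint(observed * lengths * libsize / 1.0e9).astype(np.int64)
        df = pd.DataFrame(
            {"length": lengths, "count": counts, "fpkm": observed}, index=gene_ids
        )
        tables[geno] = ExpressionTable(
            library_label=f"sim-{geno}", genomotype=geno, data=df
        )
    return tables, truth


def simulate_qpcr(config: SimulationConfig) -> list[QpcrSample]:
    """Generate a qPCR plate whose Livak estimates recover the configured
    per-genome ratios exactly when ``cq_noise_sd`` is zero.

    Reference gDNA Cqs sit at a per-sample baseline (genomotype-independent:
    qPCR on genomic DNA sees genome copies, which the normalization is meant
    to cancel); each target's cDNA Cq is offset by the target dCq, shifted in
    the numerator genomotype by ``-log2(true ratio)``.
    """
    qc = config.qpcr
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    samples: list[QpcrSample] = []
    ref_offsets = {ref: 0.7 * i for i, ref in enumerate(qc.reference_targets)}
    for geno in (qc.denominator_genomotype, qc.numerator_genomotype):
        for b in range(1, qc.n_biological + 1):
            baseline = qc.baseline_gdna_cq + rng.normal(0.0, 0.3)
            wells: list[QpcrWell] = []
            for ref, off in ref_offsets.items():
                for rep in range(1, qc.n_technical + 1):
                    cq = baseline + off + rng.normal(0.0, qc.cq_noise_sd) if qc.cq_noise_sd else baseline + off
                    wells.append(QpcrWell(target=ref, template="gdna", cq=cq, replicate=rep))
            ref_mean = baseline + float(np.mean(list(ref_offsets.values())))
            for target, ratio in qc.true_per_genome_ratios.items():
                dcq = qc.baseline_delta_cq
                if geno == qc.numerator_genomotype:
                    dcq = dcq - math.log2(ratio)
                for rep in range(1, qc.n_technical + 1):
                    cq = ref_mean + dcq
                    if qc.cq_noise_sd:
                        cq += rng.normal(0.0, qc.cq_noise_sd)
                    wells.append(QpcrWell(target=target, template="cdna", cq=cq, replicate=rep))
            samples.append(
                QpcrSample(sample_id=f"{geno}_{b}", genomotype=geno, wells=wells)
            )
    return samples


def target_expression_tables(
    config: SimulationConfig,
    true_size_ratio: float = 1.0,
    base_abundance: float = 50.0,
    gene_length_bp: int = 2000,
) -> tuple[ExpressionTable, ExpressionTable]:
    """RNA-seq tables for the qPCR target genes consistent with a chosen
    relative transcriptome size.

    Per-transcriptome ratio per gene is set to ``per_cell / true_size_ratio``
    where per-cell is 1.5x the configured true per-genome ratio, so the full
    estimator recovers ``true_size_ratio`` in expectation.  Counts and
    lengths are filled by inverse-FPKM rounding against the configured
    library sizes so the tables can be merged into count-complete libraries.
    """
    if true_size_ratio <= 0:
        raise InvalidInputError("true_size_ratio must be positive")
    qc = config.qpcr
    abunds = {
        "PA": {g: base_abundance for g in qc.true_per_genome_ratios},
        "PAA": {
            g: base_abundance * (1.5 * r / true_size_ratio)
            for g, r in qc.true_per_genome_ratios.items()
        },
    }
    tables = {}
    for geno, ab in abunds.items():
        libsize = config.library_sizes.get(geno, 20_000_000)
        df = pd.DataFrame(
            {
                "length": gene_length_bp,
                "count": {
                    g: int(round(v * gene_length_bp * libsize / 1.0e9))
                    for g, v in ab.items()
                },
                "fpkm": pd.Series(ab, dtype=float),
            }
        )
        tables[geno] = ExpressionTable(f"sim-liv-{geno}", geno, df)
    return tables["PAA"], tables["PA"]
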