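"""Genome-normalized qPCR quantification and relative transcriptome size.

RNA-seq abundances are *per transcriptome*: a global change in total mRNA per
cell is invisible to them.  To compare a triploid (PAA) with a diploid (PA)
per cell, expression is first quantified *per genome* by qPCR on total
nucleic acid: each target gene's cDNA amplification is normalized to the
genomic-DNA amplification of reference targets from the same extraction, so
the in vivo RNA/gDNA ratio is preserved and genome copy number is the
internal scale.

Quantities per target gene (PAA relative to PA):

* transcripts/genome — relative quantity ``2^-ddCq`` (Livak), where each
  sample's dCq is the mean target cDNA Cq minus the arithmetic mean of the
  reference gDNA Cqs (the log-scale equivalent of geometric-mean
  normalization of linear quantities at amplification efficiency 2);
* transcripts/cell — transcripts/genome x (3/2), since each triploid cell
  carries 1.5x the genomes of a diploid cell;
* transcriptome size — transcripts/cell divided by transcripts/transcriptome
  (the RNA-seq FPKM ratio for the same gene).

Across target genes the size estimates are averaged, screened for outliers
with Tukey's 1.5 x IQR fences, and tested by one-sample t-tests against 1.5
(genome-wide dosage effect) and 1.0 (genome-wide dosage compensation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable, InvalidInputError

__all__ = [
    "QpcrWell",
    "QpcrSample",
    "GenomeNormalizedExpression",
    "TranscriptomeSizeEstimate",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "livak_per_genome",
    "per_cell_ratio",
    "size_ratio",
    "one_sample_t",
    "tukey_outliers",
    "estimate_transcriptome_size",
    "DEFAULT_REFERENCE_TARGETS",
]

#: Reference genes with gDNA-specific primers used for genome normalization.
DEFAULT_REFERENCE_TARGETS = ("rpl8", "eef1a", "actb2")


@dataclass(frozen=True)
class QpcrWell:
    target: str
    template: str  # "cdna" | "gdna"
    cq: float
    replicate: int

    def __post_init__(self) -> None:
        if self.template not in ("cdna", "gdna"):
            raise InvalidInputError(f"template must be 'cdna' or 'gdna', got {self.template!r}")
        if not math.isfinite(self.cq) or self.cq <= 0:
            raise InvalidInputError(f"Cq must be finite and positive, got {self.cq!r}")


@dataclass
class QpcrSample:
    """One biological replicate: a set of wells from one individual."""

    sample_id: str
    genomotype: str
    wells: list[QpcrWell]

    def mean_cq(self, target: str, template: str) -> Optional[float]:
        """Arithmetic mean Cq over technical replicates, or None if absent."""
        cqs = [w.cq for w in self.wells if w.target == target and w.template == template]
        if not cqs:
            return None
        return float(np.mean(cqs))


@dataclass
class GenomeNormalizedExpression:
    """Livak relative quantity per genome for one target gene."""

    target_gene: str
    per_sample_delta_cq: dict[str, float]
    per_genomotype_mean_delta_cq: dict[str, float]
    ratio_per_genome: float
    sd_ratio: float


@dataclass
class TranscriptomeSizeEstimate:
    """Per-gene and aggregate relative transcriptome-size results."""

    per_gene: dict[str, dict[str, float]]
    mean_size: float
    sd_size: float
    mean_per_genome: float
    sd_per_genome: float
    t_vs_dosage_effect: tuple[float, int, float]  # against null 1.5
    t_vs_compensation: tuple[float, int, float]  # against null 1.0
    outlier_flags: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "per_gene": {g: dict(v) for g, v in self.per_gene.items()},
            "mean_size": self.mean_size,
            "sd_size": self.sd_size,
            "mean_per_genome": self.mean_per_genome,
            "sd_per_genome": self.sd_per_genome,
            "t_vs_dosage_effect": {
                "t": self.t_vs_dosage_effect[0],
                "df": self.t_vs_dosage_effect[1],
                "p": self.t_vs_dosage_effect[2],
            },
            "t_vs_compensation": {
                "t": self.t_vs_compensation[0],
                "df": self.t_vs_compensation[1],
                "p": self.t_vs_compensation[2],
            },
            "outlier_flags": dict(self.outlier_flags),
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["sample_id", "genomotype", "target", "template", "replicate", "cq"]


def read_qpcr_csv(path: str | Path) -> list[QpcrSample]:
    """Read long-format plate data: ``sample_id,genomotype,target,template,replicate,cq``."""
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "genomotype": str, "target": str},
        float_precision="round_trip",
    )
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    samples: list[QpcrSample] = []
    for (sid, geno), grp in df.groupby(["sample_id", "genomotype"], sort=False):
        wells = [
            QpcrWell(target=row.target, template=row.template,
                     cq=float(row.cq), replicate=int(row.replicate))
            for row in grp.itertuples()
        ]
        samples.append(QpcrSample(sample_id=sid, genomotype=geno, wells=wells))
    return samples


def write_qpcr_csv(samples: Sequence[QpcrSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "genomotype": s.genomotype,
            "target": w.target,
            "template": w.template,
            "replicate": w.replicate,
            "cq": w.cq,
        }
        for s in samples
        for w in s.wells
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g", lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Livak relative quantification
# ---------------------------------------------------------------------------


def _sample_delta_cq(
    sample: QpcrSample, target: str, reference_targets: Sequence[str]
) -> float:
    """dCq = mean target cDNA Cq - mean of reference gDNA Cqs for one sample."""
    target_cq = sample.mean_cq(target, "cdna")
    if target_cq is None:
        raise InvalidInputError(
            f"sample {sample.sample_id}: no cDNA wells for target {target!r}"
        )
    ref_means = []
    for ref in reference_targets:
        m = sample.mean_cq(ref, "gdna")
        if m is None:
            raise InvalidInputError(
                f"sample {sample.sample_id}: no gDNA wells for reference target {ref!r}"
            )
        ref_means.append(m)
    return target_cq - float(np.mean(ref_means))


def livak_per_genome(
    samples: Sequence[QpcrSample],
    target: str,
    reference_targets: Sequence[str] = DEFAULT_REFERENCE_TARGETS,
    numerator_genomotype: str = "PAA",
    denominator_genomotype: str = "PA",
) -> GenomeNormalizedExpression:
    """Relative genome-normalized expression (2^-ddCq) of one target gene.

    Technical replicates are averaged per sample; ddCq is the difference of
    the two genomotypes' mean dCq; ``sd_ratio`` is the standard deviation of
    the numerator samples' individual relative quantities
    ``2^-(dCq - mean dCq of the denominator genomotype)``.
    """
    if not reference_targets:
        raise InvalidInputError("at least one reference target is required")
    by_geno: dict[str, list[QpcrSample]] = {}
    for s in samples:
        by_geno.setdefault(s.genomotype, []).append(s)
    for geno in (numerator_genomotype, denominator_genomotype):
        if geno not in by_geno:
            raise InvalidInputError(f"no samples with genomotype {geno!r}")

    per_sample: dict[str, float] = {}
    per_geno_values: dict[str, list[float]] = {}
    for geno in (numerator_genomotype, denominator_genomotype):
        vals = []
        for s in by_geno[geno]:
            d = _sample_delta_cq(s, target, reference_targets)
            per_sample[s.sample_id] = d
            vals.append(d)
        per_geno_values[geno] = vals

    mean_num = float(np.mean(per_geno_values[numerator_genomotype]))
    mean_den = float(np.mean(per_geno_values[denominator_genomotype]))
    ddcq = mean_num - mean_den
    ratio = 2.0 ** (-ddcq)
    num_ratios = [2.0 ** -(d - mean_den) for d in per_geno_values[numerator_genomotype]]
    sd_ratio = float(np.std(num_ratios, ddof=1)) if len(num_ratios) > 1 else 0.0
    return GenomeNormalizedExpression(
        target_gene=target,
        per_sample_delta_cq=per_sample,
        per_genomotype_mean_delta_cq={
            numerator_genomotype: mean_num,
            denominator_genomotype: mean_den,
        },
        ratio_per_genome=float(ratio),
        sd_ratio=sd_ratio,
    )


def per_cell_ratio(
    per_genome_ratio: float, numerator_ploidy: int, denominator_ploidy: int
) -> float:
    """Per-cell expression ratio: per-genome ratio scaled by the ploidy ratio
    (3/2 = 1.5 for a triploid over a diploid)."""
    if per_genome_ratio <= 0:
        raise InvalidInputError("per_genome_ratio must be positive")
    if numerator_ploidy < 1 or denominator_ploidy < 1:
        raise InvalidInputError("ploidies must be >= 1")
    return per_genome_ratio * numerator_ploidy / denominator_ploidy


def size_ratio(per_cell: float, per_transcriptome: float) -> float:
    """Relative transcriptome size: transcripts/cell over transcripts/transcriptome."""
    if per_transcriptome <= 0:
        raise InvalidInputError("per_transcriptome ratio must be positive")
    return per_cell / per_transcriptome


# ---------------------------------------------------------------------------
# Inference helpers
# ---------------------------------------------------------------------------


def one_sample_t(values: Sequence[float], null_value: float) -> tuple[float, int, float]:
    """Classical one-sample two-sided t-test; returns ``(t, df, p)``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("one_sample_t requires at least two values")
    df = int(arr.size - 1)
    if float(np.std(arr, ddof=1)) == 0.0:
        if float(np.mean(arr)) == null_value:
            return 0.0, df, 1.0
        warnings.warn(
            "zero sample variance with mean != null value; p reported as the 0 limit",
            RuntimeWarning,
            stacklevel=2,
        )
        t = math.copysign(math.inf, float(np.mean(arr)) - null_value)
        return t, df, 0.0
    res = stats.ttest_1samp(arr, popmean=null_value, alternative="two-sided")
    return float(res.statistic), df, float(res.pvalue)


def tukey_outliers(values: Sequence[float]) -> dict[int, bool]:
    """Flag values outside Tukey's fences ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``.

    Quartiles are Tukey hinges: medians of the lower and upper halves of the
    sorted data, with the overall median included in both halves for odd n.
    Returns a map from input index to outlier flag; requires n >= 4.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise InvalidInputError("tukey_outliers requires at least four values")
    srt = np.sort(arr)
    half = (arr.size + 1) // 2
    q1 = float(np.median(srt[:half]))
    q3 = float(np.median(srt[arr.size - half:]))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {i: bool(v < lo or v > hi) for i, v in enumerate(arr)}


# ---------------------------------------------------------------------------
# Full estimator
# ---------------------------------------------------------------------------


def estimate_transcriptome_size(
    samples: Sequence[QpcrSample],
    rnaseq_numerator: ExpressionTable,
    rnaseq_denominator: ExpressionTable,
    target_genes: Sequence[str],
    reference_targets: Sequence[str] = DEFAULT_REFERENCE_TARGETS,
    numerator_genomotype: str = "PAA",
    denominator_genomotype: str = "PA",
    numerator_ploidy: int = 3,
    denominator_ploidy: int = 2,
) -> TranscriptomeSizeEstimate:
    """Relative transcriptome size of the numerator genomotype vs the denominator.

    Per target gene: Livak per-genome ratio from the qPCR plate, scaled to
    per cell by the ploidy ratio, divided by the RNA-seq per-transcriptome
    ratio.  Aggregates the per-gene size ratios (mean, SD), runs one-sample
    t-tests against 1.5 (dosage effect) and 1.0 (dosage compensation) and
    Tukey outlier screening.
    """
    if not target_genes:
        raise InvalidInputError("at least one target gene is required")
    per_gene: dict[str, dict[str, float]] = {}
    sizes: list[float] = []
    genomes: list[float] = []
    for gene in target_genes:
        for tbl, side in ((rnaseq_numerator, "numerator"), (rnaseq_denominator, "denominator")):
            if gene not in tbl.gene_ids:
                raise InvalidInputError(
                    f"target gene {gene!r} absent from the {side} RNA-seq table"
                )
        den_ab = float(rnaseq_denominator.abundances.loc[gene])
        num_ab = float(rnaseq_numerator.abundances.loc[gene])
        if den_ab <= 0:
            raise InvalidInputError(
                f"target gene {gene!r} has zero abundance in the denominator RNA-seq table"
            )
        expr = livak_per_genome(
            samples, gene, reference_targets, numerator_genomotype, denominator_genomotype
        )
        per_genome = expr.ratio_per_genome
        per_cell = per_cell_ratio(per_genome, numerator_ploidy, denominator_ploidy)
        per_transcriptome = num_ab / den_ab
        size = size_ratio(per_cell, per_transcriptome)
        per_gene[gene] = {
            "per_genome_ratio": per_genome,
            "sd_per_genome_ratio": expr.sd_ratio,
            "per_cell_ratio": per_cell,
            "per_transcriptome_ratio": per_transcriptome,
            "size_ratio": size,
        }
        sizes.append(size)
        genomes.append(per_genome)

    sizes_arr = np.asarray(sizes)
    genomes_arr = np.asarray(genomes)
    t_dosage = one_sample_t(sizes, 1.5) if len(sizes) >= 2 else (math.nan, 0, math.nan)
    t_comp = one_sample_t(sizes, 1.0) if len(sizes) >= 2 else (math.nan, 0, math.nan)
    flags = (
        {g: f for (g, f) in zip(target_genes, tukey_outliers(sizes).values())}
        if len(sizes) >= 4
        else {g: False for g in target_genes}
    )
    return TranscriptomeSizeEstimate(
        per_gene=per_gene,
        mean_size=float(np.mean(sizes_arr)),
        sd_size=float(np.std(sizes_arr, ddof=1)) if len(sizes) > 1 else 0.0,
        mean_per_genome=float(np.mean(genomes_arr)),
        sd_per_genome=float(np.std(genomes_arr, ddof=1)) if len(genomes) > 1 else 0.0,
        t_vs_dosage_effect=t_dosage,
        t_vs_compensation=t_comp,
        outlier_flags=flags,
    )
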