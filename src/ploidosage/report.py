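"""Pipeline orchestration: compose the stages and emit a consolidated report.

Stages (each independently skippable when its inputs are absent):

1. ``profile``   — PAA/PA ratio profile with sign counts and chi-square;
2. ``classify``  — SE/dosage-class calls and, when counts are available,
                   exact-test DE calls with dependent-test FDR;
3. ``additivity``— observed vs mid-parent expected for each hybrid
                   (needs both parental tables);
4. ``tsize``     — relative transcriptome size from a qPCR plate plus the
                   two liver-like RNA-seq tables.

The report is a plain dict (JSON-serializable); a :class:`RunManifest`
records digests, seeds and per-stage record counts.  The report digest is
computed over the stage content only, so reruns with identical inputs yield
identical digests regardless of wall-clock timestamps.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from .additivity import additivity_profile, additivity_tally
from .core import AnalysisConfig, ExpressionTable, GENOMOTYPES, InvalidInputError, validate_table
from .dosage import classify_records, tally
from .qpcr import (
    DEFAULT_REFERENCE_TARGETS,
    QpcrSample,
    estimate_transcriptome_size,
)
from .ratios import chi_square_goodness, ratio_profile, records_to_frame, summarize_profile

logger = logging.getLogger("ploidosage")

__all__ = ["RunManifest", "run_full_pipeline", "report_digest"]


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    started: str
    finished: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    stages_skipped: dict[str, str] = field(default_factory=dict)
    stages_failed: dict[str, str] = field(default_factory=dict)
    report_digest: str = ""

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "input_digests": dict(self.input_digests),
            "output_digests": dict(self.output_digests),
            "stage_counts": dict(self.stage_counts),
            "stages_skipped": dict(self.stages_skipped),
            "stages_failed": dict(self.stages_failed),
            "report_digest": self.report_digest,
        }


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def report_digest(report: Mapping) -> str:
    """Deterministic digest of report content (sorted-key canonical JSON)."""
    payload = json.dumps(report, sort_keys=True, default=str).encode("utf-8")
    return _sha256_bytes(payload)


def _summary_dict(records, n_dropped: int) -> dict:
    s = summarize_profile(records)
    chi_stat, chi_p = chi_square_goodness(s.n_negative, s.n_positive)
    return {
        "n_records": len(records),
        "n_dropped": n_dropped,
        "n_positive": s.n_positive,
        "n_negative": s.n_negative,
        "n_zero": s.n_zero,
        "median_log2": s.median_log2,
        "chi_square_lower_vs_higher": {"statistic": chi_stat, "p_value": chi_p},
    }


def run_full_pipeline(
    tables: Mapping[str, ExpressionTable],
    config: AnalysisConfig | None = None,
    qpcr_samples: Optional[Sequence[QpcrSample]] = None,
    qpcr_targets: Optional[Sequence[str]] = None,
    reference_targets: Sequence[str] = DEFAULT_REFERENCE_TARGETS,
    outdir: Optional[str | Path] = None,
    input_paths: Optional[Mapping[str, str | Path]] = None,
) -> tuple[dict, RunManifest]:
    """Run every stage whose inputs are present; return (report, manifest).

    ``tables`` maps genomotype labels (subset of PP/AA/PA/PAA) to validated
    expression tables.  Invalid tables abort before any stage runs.
    """
    config = config or AnalysisConfig()
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_sha256_bytes(
            json.dumps(config.to_dict(), sort_keys=True).encode("utf-8")
        ),
        seed=config.seed,
        started=started,
    )
    if input_paths:
        for name, p in input_paths.items():
            manifest.input_digests[str(name)] = _sha256_file(Path(p))

    for geno, tbl in tables.items():
        violations = validate_table(tbl)
        if violations:
            raise InvalidInputError(
                f"table {geno} failed validation: {violations[:3]}"
            )

    report: dict = {"stages": {}}
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)

    # -- profile + classify -------------------------------------------------
    if "PAA" in tables and "PA" in tables:
        logger.info("stage profile: PAA vs PA")
        prof = ratio_profile(tables["PAA"], tables["PA"], config)
        report["stages"]["profile"] = _summary_dict(prof.records, prof.n_dropped)
        manifest.stage_counts["profile"] = len(prof.records)
        logger.info("stage profile: %d records, %d dropped", len(prof.records), prof.n_dropped)

        num_counts = tables["PAA"].data["count"]
        den_counts = tables["PA"].data["count"]
        have_counts = not num_counts.isna().any() and not den_counts.isna().any()
        recs = classify_records(
            prof.records,
            config,
            numerator_counts=num_counts.to_dict() if have_counts else None,
            denominator_counts=den_counts.to_dict() if have_counts else None,
        )
        t = tally(recs)
        report["stages"]["classify"] = t.to_dict()
        manifest.stage_counts["classify"] = t.n_total

        if outdir_path is not None:
            frame = records_to_frame(prof.records)
            by_gene = {r.gene_id: r for r in recs}
            frame["se_flag"] = [by_gene[g].se_flag for g in frame["gene_id"]]
            frame["dosage_class"] = [by_gene[g].dosage_class for g in frame["gene_id"]]
            frame["raw_p"] = [by_gene[g].raw_p for g in frame["gene_id"]]
            frame["fdr_q"] = [by_gene[g].fdr_q for g in frame["gene_id"]]
            frame["de_flag"] = [by_gene[g].de_flag for g in frame["gene_id"]]
            frame["de_direction"] = [by_gene[g].de_direction for g in frame["gene_id"]]
            path = outdir_path / "classified.tsv"
            frame.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")
            manifest.output_digests[path.name] = _sha256_file(path)
    else:
        missing = [g for g in ("PAA", "PA") if g not in tables]
        reason = f"missing tables: {missing}"
        manifest.stages_skipped["profile"] = reason
        manifest.stages_skipped["classify"] = reason
        logger.info("stages profile/classify skipped: %s", reason)

    # -- additivity ---------------------------------------------------------
    if "PP" in tables and "AA" in tables:
        for hybrid in ("PA", "PAA"):
            if hybrid not in tables:
                manifest.stages_skipped[f"additivity_{hybrid}"] = "hybrid table missing"
                continue
            logger.info("stage additivity: %s", hybrid)
            recs = additivity_profile(
                tables["PP"], tables["AA"], tables[hybrid], GENOMOTYPES[hybrid], config
            )
            at = additivity_tally(recs)
            below = at.counts["below_additive"]
            above = at.counts["above_additive"]
            chi = (
                chi_square_goodness(below, above) if below + above > 0 else (0.0, 1.0)
            )
            report["stages"][f"additivity_{hybrid}"] = {
                "counts": at.counts,
                "n_defined": at.n_defined,
                "n_undefined": at.n_undefined,
                "percentages": at.percentages,
                "chi_square_nonadditive": {"statistic": chi[0], "p_value": chi[1]},
            }
            manifest.stage_counts[f"additivity_{hybrid}"] = len(recs)
    else:
        missing = [g for g in ("PP", "AA") if g not in tables]
        reason = f"missing parental tables: {missing}"
        manifest.stages_skipped["additivity"] = reason
        logger.info("stage additivity skipped: %s", reason)

    # -- transcriptome size -------------------------------------------------
    if qpcr_samples and "PAA" in tables and "PA" in tables:
        targets = list(qpcr_targets) if qpcr_targets else sorted(
            {w.target for s in qpcr_samples for w in s.wells if w.template == "cdna"}
        )
        logger.info("stage tsize: %d target genes", len(targets))
        try:
            est = estimate_transcriptome_size(
                qpcr_samples, tables["PAA"], tables["PA"], targets, reference_targets
            )
        except InvalidInputError as exc:
            manifest.stages_failed["tsize"] = str(exc)
            logger.error("stage tsize failed: %s", exc)
        else:
            report["stages"]["tsize"] = est.to_dict()
            manifest.stage_counts["tsize"] = len(targets)
    elif qpcr_samples:
        manifest.stages_skipped["tsize"] = "PAA/PA RNA-seq tables required"
    else:
        manifest.stages_skipped["tsize"] = "no qPCR samples provided"

    manifest.report_digest = report_digest(report)
    manifest.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()

    if outdir_path is not None:
        report_path = outdir_path / "report.json"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.output_digests[report_path.name] = _sha256_file(report_path)
        with open(outdir_path / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report, manifest
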