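"""Domain types and abundance normalization shared by every analysis stage.

The package compares per-gene transcript abundance among fish *genomotypes* —
genome compositions built from two parental haplomes, P (from *Squalius
pyrenaicus*) and A (from an *Anaecypris hispanica*-like ancestor).  The four
compositions of interest are the parental-like diploids PP and AA, the
allodiploid hybrid PA and the allotriploid hybrid PAA.  Abundances are
expressed as FPKM (fragments per kilobase of transcript per million mapped
fragments), which normalizes a fragment count by gene length and by the size
of the sequenced library, i.e. abundance *per transcriptome*.

This module holds:

* :class:`GenomotypeSpec` — a genome composition (haplome copy numbers and
  ploidy);
* :class:`ExpressionTable` — one library's per-gene abundances, backed by a
  :class:`pandas.DataFrame`;
* :class:`AnalysisConfig` — the thresholds that drive similarity and dosage
  classification;
* :func:`compute_fpkm` and :func:`validate_table`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InvalidInputError",
    "ContractError",
    "GenomotypeSpec",
    "GENOMOTYPES",
    "AnalysisConfig",
    "ExpressionTable",
    "compute_fpkm",
    "fpkm_array",
    "validate_table",
    "round_half_away",
]

FPKM_SCALE = 1.0e9  # 10^3 (per kilobase) x 10^6 (per million fragments)


class InvalidInputError(ValueError):
    """Raised when an input value violates an operation's precondition."""


class ContractError(RuntimeError):
    """Raised when an operation is called outside its documented contract."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (the convention used for all
    reported percentages), unlike Python's default banker's rounding."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * math.copysign(1.0, scaled)
    return rounded / factor


# ---------------------------------------------------------------------------
# Genomotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomotypeSpec:
    """A genome composition: haplome symbols with copy counts.

    ``ploidy`` is derived as the sum of copy counts; e.g. PAA carries one P
    haplome and two A haplomes, giving ploidy 3.
    """

    label: str
    haplome_copies: Mapping[str, int]

    def __post_init__(self) -> None:
        copies = dict(self.haplome_copies)
        if not copies:
            raise InvalidInputError("haplome_copies must not be empty")
        for sym, n in copies.items():
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise InvalidInputError(
                    f"copy count for haplome {sym!r} must be a nonnegative integer"
                )
        if all(n == 0 for n in copies.values()):
            raise InvalidInputError("at least one haplome must have copy count >= 1")
        object.__setattr__(self, "haplome_copies", copies)

    @property
    def ploidy(self) -> int:
        return int(sum(self.haplome_copies.values()))

    @classmethod
    def from_label(cls, label: str) -> "GenomotypeSpec":
        """Build a spec by counting haplome letters in a label like ``"PAA"``."""
        if not label or not label.isalpha():
            raise InvalidInputError(f"invalid genomotype label {label!r}")
        return cls(label=label, haplome_copies=dict(Counter(label.upper())))


#: The four genome compositions of the study system.
GENOMOTYPES: Mapping[str, GenomotypeSpec] = {
    lbl: GenomotypeSpec.from_label(lbl) for lbl in ("PP", "AA", "PA", "PAA")
}


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Thresholds and policies for the dosage-response analysis.

    Parameters
    ----------
    se_log2_threshold:
        Half-width of the similar-expression (SE) band: a gene is SE when
        ``|log2(fold change)| < se_log2_threshold`` (strict).  Default 1.0,
        i.e. less than twofold difference.
    class_bounds:
        The three fold-change boundaries partitioning the SE band into the
        four dosage classes: compensated (class I, around ratio 1),
        dosage-sensitive (class II, around 1.5), repressed (class III, below
        the lower bound) and overexpressed (class IV, above the upper bound).
        Defaults ``(0.75, 1.25, 1.75)``.
    fdr_alpha:
        Significance cutoff on the dependent-test FDR q-value. Default 0.05.
    zero_policy:
        How genes with a zero abundance in either library enter ratio
        computations: ``"exclude"`` drops them (default), ``"pseudocount"``
        adds ``pseudocount`` to both abundances before dividing.
    pseudocount:
        Value added under the ``pseudocount`` policy. Default 0.5 FPKM.
    seed:
        Seed for any randomized step downstream (simulation, bootstraps).
    """

    se_log2_threshold: float = 1.0
    class_bounds: tuple[float, float, float] = (0.75, 1.25, 1.75)
    fdr_alpha: float = 0.05
    zero_policy: str = "exclude"
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.se_log2_threshold <= 0:
            raise InvalidInputError("se_log2_threshold must be positive")
        b = tuple(float(x) for x in self.class_bounds)
        if len(b) != 3 or not (0 < b[0] < b[1] < b[2]):
            raise InvalidInputError("class_bounds must be three increasing positive reals")
        lo, hi = 2.0 ** -self.se_log2_threshold, 2.0 ** self.se_log2_threshold
        if not (lo < b[0] and b[2] < hi):
            raise InvalidInputError(
                "class_bounds must lie strictly inside the similar-expression band "
                f"({lo:g}, {hi:g})"
            )
        self.class_bounds = b
        if not 0 < self.fdr_alpha < 1:
            raise InvalidInputError("fdr_alpha must lie in (0, 1)")
        if self.zero_policy not in ("exclude", "pseudocount"):
            raise InvalidInputError("zero_policy must be 'exclude' or 'pseudocount'")
        if self.pseudocount < 0:
            raise InvalidInputError("pseudocount must be nonnegative")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "se_log2_threshold": self.se_log2_threshold,
            "class_bounds": list(self.class_bounds),
            "fdr_alpha": self.fdr_alpha,
            "zero_policy": self.zero_policy,
            "pseudocount": self.pseudocount,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        kwargs = dict(d)
        if "class_bounds" in kwargs:
            kwargs["class_bounds"] = tuple(kwargs["class_bounds"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InvalidInputError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def compute_fpkm(
    fragment_count: int, gene_length_bp: int, total_mapped_fragments: int
) -> float:
    """FPKM of one gene: ``count * 1e9 / (length_bp * total_mapped_fragments)``.

    Raises
    ------
    InvalidInputError
        If the count is negative or length/total are not positive.
    """
    if fragment_count < 0:
        raise InvalidInputError("fragment_count must be nonnegative")
    if gene_length_bp <= 0:
        raise InvalidInputError("gene_length_bp must be positive")
    if total_mapped_fragments <= 0:
        raise InvalidInputError("total_mapped_fragments must be positive")
    return fragment_count * FPKM_SCALE / (gene_length_bp * total_mapped_fragments)


def fpkm_array(
    counts: np.ndarray, lengths_bp: np.ndarray, total_mapped_fragments: int
) -> np.ndarray:
    """Vectorized :func:`compute_fpkm` over aligned count/length arrays."""
    if total_mapped_fragments <= 0:
        raise InvalidInputError("total_mapped_fragments must be positive")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if np.any(lengths <= 0):
        raise InvalidInputError("gene_length_bp must be positive")
    if np.any(counts < 0):
        raise InvalidInputError("fragment_count must be nonnegative")
    return counts * FPKM_SCALE / (lengths * total_mapped_fragments)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("length", "count", "fpkm")


@dataclass
class ExpressionTable:
    """One library's per-gene abundances.

    ``data`` is a DataFrame indexed by gene id with columns ``length``
    (gene length in bp, nullable), ``count`` (mapped fragment count,
    nullable) and ``fpkm`` (abundance; always present).
    """

    library_label: str
    genomotype: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _TSV_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError(f"expression table missing columns: {missing}")
        df = df[list(_TSV_COLUMNS)].copy()
        df.index = df.index.astype(str)
        df.index.name = "gene_id"
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise InvalidInputError(f"duplicate gene ids in table: {dups}")
        df["length"] = df["length"].astype("Int64")
        df["count"] = df["count"].astype("Int64")
        df["fpkm"] = df["fpkm"].astype(float)
        self.data = df

    # -- convenience --------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def abundances(self) -> pd.Series:
        return self.data["fpkm"]

    @property
    def total_fragments(self) -> Optional[int]:
        """Sum of the stored fragment counts, or ``None`` if any is missing."""
        counts = self.data["count"]
        if counts.isna().any():
            return None
        return int(counts.sum())

    def __len__(self) -> int:
        return len(self.data)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        library_label: str,
        genomotype: str,
        records: Mapping[str, tuple],
    ) -> "ExpressionTable":
        """Build from ``{gene_id: (count | None, length_bp | None, fpkm)}``."""
        rows = {
            gid: {"count": c, "length": ln, "fpkm": ab}
            for gid, (c, ln, ab) in records.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        if df.empty:
            df = pd.DataFrame(columns=list(_TSV_COLUMNS))
        return cls(library_label=library_label, genomotype=genomotype, data=df)

    @classmethod
    def from_abundances(
        cls, library_label: str, genomotype: str, abundances: Mapping[str, float]
    ) -> "ExpressionTable":
        df = pd.DataFrame(
            {"length": pd.NA, "count": pd.NA, "fpkm": pd.Series(abundances, dtype=float)}
        )
        return cls(library_label=library_label, genomotype=genomotype, data=df)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def read_tsv(
        cls, path: str | Path, library_label: str | None = None, genomotype: str = ""
    ) -> "ExpressionTable":
        """Read a tab-separated table ``gene_id length count fpkm``.

        Empty ``length``/``count`` fields denote missing values.
        """
        df = pd.read_csv(
            path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip"
        )
        expected = {"gene_id", *_TSV_COLUMNS}
        if set(df.columns) != expected:
            raise InvalidInputError(
                f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}"
            )
        df = df.set_index("gene_id")
        label = library_label if library_label is not None else Path(path).stem
        return cls(library_label=label, genomotype=genomotype, data=df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.reset_index()
        out.to_csv(
            path, sep="\t", index=False, na_rep="", float_format="%.17g",
            lineterminator="\n",
        )


def validate_table(
    table: ExpressionTable,
    total_mapped_fragments: Optional[int] = None,
    rel_tol: float = 1e-9,
) -> list[str]:
    """Diagnostic check of :class:`ExpressionTable` invariants.

    Returns a list of human-readable violations (empty when the table is
    valid).  When ``total_mapped_fragments`` is supplied, rows carrying both a
    count and a length must agree with the FPKM formula to ``rel_tol``
    relative error.
    """
    violations: list[str] = []
    df = table.data
    bad_fpkm = df.index[(df["fpkm"] < 0) | ~np.isfinite(df["fpkm"])]
    violations.extend(
        f"gene {gid}: abundance must be a finite nonnegative FPKM" for gid in bad_fpkm
    )
    lengths = df["length"]
    bad_len = df.index[lengths.notna() & (lengths <= 0)]
    violations.extend(f"gene {gid}: gene length must be positive" for gid in bad_len)
    counts = df["count"]
    bad_count = df.index[counts.notna() & (counts < 0)]
    violations.extend(f"gene {gid}: fragment count must be nonnegative" for gid in bad_count)

    if total_mapped_fragments is not None:
        if total_mapped_fragments <= 0:
            raise InvalidInputError("total_mapped_fragments must be positive")
        have = counts.notna() & lengths.notna() & (lengths > 0) & (counts >= 0)
        if have.any():
            sub = df.loc[have]
            expect = fpkm_array(
                sub["count"].to_numpy(dtype=float),
                sub["length"].to_numpy(dtype=float),
                total_mapped_fragments,
            )
            got = sub["fpkm"].to_numpy()
            denom = np.maximum(np.abs(expect), 1e-300)
            off = np.abs(got - expect) / denom > rel_tol
            # zero-count rows: require exact zero
            zero = expect == 0
            off = np.where(zero, got != 0, off)
            violations.extend(
                f"gene {gid}: stored FPKM {g:g} inconsistent with formula value {e:g}"
                for gid, g, e in zip(sub.index[off], got[off], expect[off])
            )
    return violations
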