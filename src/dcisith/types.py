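"""Core domain types for paired-sample tumor heterogeneity analysis.

A study unit is one patient carrying two geographically distinct samples of
the same in-situ lesion (optionally plus one invasive sample).  Molecular
state per sample comes in three modalities: somatic SNV call sets, bin-level
copy-number profiles (corrected log2 ratios on a fixed genomic grid), and
ordinal immunohistochemistry staining profiles.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "VariantKey",
    "SampleVariantSet",
    "GenomicBin",
    "CopyNumberProfile",
    "IHCProfile",
    "PatientRecord",
    "AnalysisConfig",
    "FOUR_LEVEL",
    "TWO_LEVEL",
    "COHORTS_LONGITUDINAL",
    "COHORTS_CROSS_SECTIONAL",
    "EVENT_NONE",
    "EVENT_RECURRENCE",
    "EVENT_PROGRESSION",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


# Ordered staining-intensity category systems.
FOUR_LEVEL: tuple[str, ...] = ("absence", "low", "medium", "high")
TWO_LEVEL: tuple[str, ...] = ("absent", "present")

COHORTS_LONGITUDINAL = ("nonrecurrent", "recurrent", "progressor")
COHORTS_CROSS_SECTIONAL = ("pure_dcis", "synchronous_dcis")

EVENT_NONE = "none"
EVENT_RECURRENCE = "dcis_recurrence"
EVENT_PROGRESSION = "progression"

_EVENT_FOR_COHORT = {
    "nonrecurrent": EVENT_NONE,
    "recurrent": EVENT_RECURRENCE,
    "progressor": EVENT_PROGRESSION,
}


class VariantKey(NamedTuple):
    """Identity of one somatic SNV: chromosome, 1-based position, ref, alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "VariantKey":
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt alleles are identical: {self!r}")
        return self


@dataclass(frozen=True)
class SampleVariantSet:
    """All somatic SNVs called in one tumor sample."""

    sample_id: str
    patient_id: str
    variants: frozenset[VariantKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", frozenset(self.variants))
        for v in self.variants:
            v.validate()

    def __len__(self) -> int:
        return len(self.variants)


class GenomicBin(NamedTuple):
    """One bin of the copy-number grid; BED convention (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    bin_id: int

    def validate(self) -> "GenomicBin":
        if self.end <= self.start:
            raise ValidationError(
                f"bin end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        return self

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberProfile:
    """Bin-level corrected log2 copy-number ratios for one sample.

    ``log2`` is aligned with ``bins``; NaN marks bins filtered upstream
    (mappability/QC), which are excluded from both numerator and denominator
    of every burden/divergence computation.  The altered/normal call is
    derived lazily from the threshold rule, never stored.
    """

    sample_id: str
    patient_id: str
    bins: list[GenomicBin]
    log2: np.ndarray

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        if len(self.bins) != self.log2.shape[0]:
            raise ValidationError(
                f"sample {self.sample_id}: {len(self.bins)} bins but "
                f"{self.log2.shape[0]} log2 values"
            )
        for b in self.bins:
            b.validate()
        _check_non_overlapping(self.bins, self.sample_id)

    @property
    def usable(self) -> np.ndarray:
        """Boolean mask of bins with a non-missing log2 ratio."""
        return ~np.isnan(self.log2)

    def same_grid(self, other: "CopyNumberProfile") -> bool:
        return self.bins == other.bins


def _check_non_overlapping(bins: Sequence[GenomicBin], sample_id: str) -> None:
    by_chrom: dict[str, list[GenomicBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        for prev, cur in zip(bs, bs[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"sample {sample_id}: overlapping or unsorted bins on "
                    f"{chrom}: {prev.start}-{prev.end} then {cur.start}-{cur.end}"
                )


@dataclass(frozen=True)
class IHCProfile:
    """Staining-intensity histogram for one marker in one sample.

    Proportions over ordered categories (4-level absence/low/medium/high or
    2-level absent/present); must be non-negative and sum to 1 within 1e-6.
    """

    sample_id: str
    marker: str
    categories: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        cats = tuple(self.categories)
        props = tuple(float(p) for p in self.proportions)
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "proportions", props)
        if cats not in (FOUR_LEVEL, TWO_LEVEL):
            raise ValidationError(f"unknown category system {cats!r}")
        if len(props) != len(cats):
            raise ValidationError(
                f"{len(props)} proportions for {len(cats)} categories"
            )
        if any(p < 0 for p in props):
            raise ValidationError(f"negative proportion in {props}")
        if not math.isclose(sum(props), 1.0, abs_tol=1e-6):
            raise ValidationError(
                f"proportions sum to {sum(props):.8f}, expected 1 "
                f"(sample {self.sample_id}, marker {self.marker})"
            )

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass
class PatientRecord:
    """Clinical and structural record for one patient.

    ``covariates`` is an open-ended map carrying the study's additional
    clinical covariates; its schema is configuration, not code.
    """

    patient_id: str
    cohort: str
    sample_ids: tuple[str, str]
    outcome_time: float | None = None  # months
    outcome_event: str = EVENT_NONE
    treatment: str | None = None
    er_status: str = "unknown"
    surgical_margin_mm: float | None = None
    covariates: dict[str, object] = field(default_factory=dict)
    idc_sample_id: str | None = None

    def __post_init__(self) -> None:
        known = COHORTS_LONGITUDINAL + COHORTS_CROSS_SECTIONAL
        if self.cohort not in known:
            raise ValidationError(
                f"unknown cohort {self.cohort!r} for patient {self.patient_id}"
            )
        if len(tuple(self.sample_ids)) != 2:
            raise ValidationError(
                f"patient {self.patient_id}: exactly two DCIS samples required"
            )
        self.sample_ids = tuple(self.sample_ids)
        if self.outcome_time is not None:
            if not (self.outcome_time > 0 or np.isnan(self.outcome_time)):
                raise ValidationError(
                    f"patient {self.patient_id}: outcome_time must be > 0"
                )
        expected = _EVENT_FOR_COHORT.get(self.cohort)
        if expected is not None and self.outcome_event != expected:
            raise ValidationError(
                f"patient {self.patient_id}: cohort {self.cohort!r} is "
                f"inconsistent with outcome_event {self.outcome_event!r}"
            )


@dataclass
class AnalysisConfig:
    """Printed analysis constants, collected so a run is reproducible.

    Defaults: alteration threshold |log2| > 0.3 (strict); divergence needs a
    union of >= 5 SNVs; variable selection repeats 10-fold-CV Cox-LASSO 100
    times and keeps covariates selected in >= 90% of repetitions.
    """

    cna_log2_threshold: float = 0.3
    min_union_snvs: int = 5
    lasso_reps: int = 100
    cv_folds: int = 10
    selection_freq_threshold: float = 0.9
    base_seed: int = 0
    endpoint_mode: str = "recurrence"
    emd_normalize: bool = True
    direction_aware_cna_sharing: bool = False
    lasso_n_alphas: int = 100
    lasso_alpha_decades: float = 4.0
    intensity_weights: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    mann_whitney_exact_max_n: int = 30

    def __post_init__(self) -> None:
        if self.cna_log2_threshold <= 0:
            raise ValidationError("cna_log2_threshold must be > 0")
        if self.min_union_snvs < 1:
            raise ValidationError("min_union_snvs must be >= 1")
        if not 0 < self.selection_freq_threshold <= 1:
            raise ValidationError("selection_freq_threshold must be in (0, 1]")
        if self.lasso_reps < 1 or self.cv_folds < 2:
            raise ValidationError("lasso_reps >= 1 and cv_folds >= 2 required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intensity_weights"] = list(self.intensity_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "intensity_weights" in d:
            d["intensity_weights"] = tuple(d["intensity_weights"])
        return cls(**d)
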