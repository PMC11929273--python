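"""Paired-sample SNV and copy-number burden and divergence statistics.

Divergence measures the evolutionary separation of two geographically
distinct samples of one tumor: the fraction of alterations (SNVs, or
altered genomic bins) private to either sample, relative to the union of
alterations across both.  SNV divergence is only reported when the union
holds at least ``min_union`` mutations (default 5); CNA divergence is
undefined when neither sample carries an alteration.  Missing values are
explicit (NaN), never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AnalysisConfig, CopyNumberProfile, SampleVariantSet, ValidationError

__all__ = [
    "snv_burden",
    "snv_divergence",
    "call_altered_bins",
    "cna_burden",
    "cna_divergence",
    "dcis_idc_divergence",
    "BurdenResult",
    "DivergenceResult",
    "patient_metrics_table",
]


@dataclass
class BurdenResult:
    patient_id: str
    snv_burden: int
    cna_burden_per_sample: tuple[float, ...]


@dataclass
class DivergenceResult:
    patient_id: str
    snv_divergence: float  # percent, NaN when union < min_union
    cna_divergence: float  # percent, NaN when no altered bin in either sample
    n_union_snvs: int
    altered_union_bins: int


def _check_same_patient(*sets: SampleVariantSet) -> None:
    pids = {s.patient_id for s in sets}
    if len(pids) != 1:
        raise ValidationError(f"samples belong to different patients: {sorted(pids)}")


def snv_burden(a: SampleVariantSet, b: SampleVariantSet) -> int:
    """Number of distinct somatic SNVs in the union of the two samples."""
    _check_same_patient(a, b)
    return len(a.variants | b.variants)


def snv_divergence(
    a: SampleVariantSet, b: SampleVariantSet, min_union: int = 5
) -> float:
    """Percent of union SNVs private to one sample; NaN if union < min_union."""
    _check_same_patient(a, b)
    union = a.variants | b.variants
    if len(union) < min_union:
        return math.nan
    shared = a.variants & b.variants
    return 100.0 * (len(union) - len(shared)) / len(union)


def call_altered_bins(
    p: CopyNumberProfile, threshold: float = 0.3
) -> set[tuple[int, str]]:
    """Bins whose |corrected log2 ratio| strictly exceeds the threshold.

    Returns (bin_id, direction) pairs, direction 'gain' for log2 > 0 and
    'loss' otherwise.  Bins with missing log2 are never called.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    log2 = p.log2
    with np.errstate(invalid="ignore"):
        hit = np.abs(log2) > threshold
    hit &= ~np.isnan(log2)
    bin_ids = np.array([b.bin_id for b in p.bins])
    return {
        (int(bid), "gain" if v > 0 else "loss")
        for bid, v in zip(bin_ids[hit], log2[hit])
    }


def cna_burden(p: CopyNumberProfile, threshold: float = 0.3) -> float:
    """Fraction of the considered genome that is altered.

    Weighted by bin width in bp; bins with missing log2 are excluded from
    numerator and denominator alike.
    """
    usable = p.usable
    if not usable.any():
        raise ValidationError(f"sample {p.sample_id}: no considered genome")
    widths = np.array([b.width for b in p.bins], dtype=float)
    altered_ids = {bid for bid, _ in call_altered_bins(p, threshold)}
    altered = np.array([b.bin_id in altered_ids for b in p.bins])
    return float(widths[altered & usable].sum() / widths[usable].sum())


def cna_divergence(
    pa: CopyNumberProfile,
    pb: CopyNumberProfile,
    threshold: float = 0.3,
    direction_aware: bool = False,
) -> float:
    """Percent of the altered genome private to one sample (bp-weighted).

    With A and B the altered bin sets of the two samples, returns
    100 * bp(A Δ B) / bp(A ∪ B).  Bins missing in either sample are dropped
    from both.  When ``direction_aware`` a bin altered in both samples but in
    opposite directions counts as discordant (contributes to the numerator).
    NaN when no bin is altered in either sample.
    """
    if not pa.same_grid(pb):
        raise ValidationError(
            f"samples {pa.sample_id} and {pb.sample_id} are on different bin grids"
        )
    usable = pa.usable & pb.usable
    usable_ids = {b.bin_id for b, u in zip(pa.bins, usable) if u}
    calls_a = {c for c in call_altered_bins(pa, threshold) if c[0] in usable_ids}
    calls_b = {c for c in call_altered_bins(pb, threshold) if c[0] in usable_ids}
    union_ids = {bid for bid, _ in calls_a} | {bid for bid, _ in calls_b}
    if not union_ids:
        return math.nan
    if direction_aware:
        shared_ids = {bid for bid, _ in calls_a & calls_b}
    else:
        shared_ids = {bid for bid, _ in calls_a} & {bid for bid, _ in calls_b}
    width = {b.bin_id: b.width for b in pa.bins}
    bp_union = sum(width[i] for i in union_ids)
    bp_shared = sum(width[i] for i in shared_ids)
    return 100.0 * (bp_union - bp_shared) / bp_union


def dcis_idc_divergence(
    dcis1: SampleVariantSet,
    dcis2: SampleVariantSet,
    idc: SampleVariantSet,
    min_union: int = 5,
) -> float:
    """Mean SNV divergence of each in-situ sample against the invasive sample.

    If only one of the two comparisons reaches the union-size requirement,
    the computable one is returned; NaN when both are missing.
    """
    _check_same_patient(dcis1, dcis2, idc)
    d1 = snv_divergence(dcis1, idc, min_union)
    d2 = snv_divergence(dcis2, idc, min_union)
    vals = [d for d in (d1, d2) if not math.isnan(d)]
    if not vals:
        return math.nan
    return float(np.mean(vals))


def patient_metrics_table(
    patients,
    variant_sets: list[SampleVariantSet],
    cna_profiles: list[CopyNumberProfile],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-patient burden/divergence table (one row per patient).

    Patients missing a modality get NaN in that modality's columns only.
    """
    config = config or AnalysisConfig()
    by_sid_var = {v.sample_id: v for v in variant_sets}
    by_sid_cna = {p.sample_id: p for p in cna_profiles}
    rows = []
    for pt in patients:
        s1, s2 = pt.sample_ids
        row: dict[str, object] = {"patient_id": pt.patient_id}
        va, vb = by_sid_var.get(s1), by_sid_var.get(s2)
        if va is not None and vb is not None:
            union = va.variants | vb.variants
            row["snv_burden"] = snv_burden(va, vb)
            row["snv_divergence"] = snv_divergence(va, vb, config.min_union_snvs)
            row["n_union_snvs"] = len(union)
        else:
            row.update(snv_burden=np.nan, snv_divergence=np.nan, n_union_snvs=np.nan)
        ca, cb = by_sid_cna.get(s1), by_sid_cna.get(s2)
        if ca is not None and cb is not None:
            thr = config.cna_log2_threshold
            row["cna_burden_s1"] = cna_burden(ca, thr)
            row["cna_burden_s2"] = cna_burden(cb, thr)
            row["cna_divergence"] = cna_divergence(
                ca, cb, thr, config.direction_aware_cna_sharing
            )
            a_ids = {bid for bid, _ in call_altered_bins(ca, thr)}
            b_ids = {bid for bid, _ in call_altered_bins(cb, thr)}
            row["altered_union_bins"] = len(a_ids | b_ids)
        else:
            row.update(
                cna_burden_s1=np.nan,
                cna_burden_s2=np.nan,
                cna_divergence=np.nan,
                altered_union_bins=np.nan,
            )
        rows.append(row)
    cols = [
        "patient_id",
        "snv_burden",
        "snv_divergence",
        "n_union_snvs",
        "cna_burden_s1",
        "cna_burden_s2",
        "cna_divergence",
        "altered_union_bins",
    ]
    return pd.DataFrame(rows, columns=cols)
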