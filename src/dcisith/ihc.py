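"""Ordinal immunohistochemistry statistics at three scales of comparison.

For each marker and patient we summarize (i) average staining intensity
across the patient's samples (mean intensity score, MIS), (ii) between-sample
divergence of the staining histograms (Earth Mover's Distance, EMD), and
(iii) within-sample staining uniformity (Cumulative Density Index, CDI).

Intensity weights reflect visual scoring: medium staining is about twice as
intense as low, and high about three times, so 4-level profiles are scored
with weights (0, 1, 2, 3)/3; binary markers score as the stained fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import IHCProfile, ValidationError

__all__ = [
    "intensity_score",
    "mean_intensity_score",
    "profile_emd",
    "cdi",
    "patient_marker_summary",
    "marker_summary_table",
    "MarkerSummary",
]


@dataclass
class MarkerSummary:
    patient_id: str
    marker: str
    mis: float
    emd_between: float  # NaN when only one sample is available
    cdi_within: float


def intensity_score(p: IHCProfile, weights: Sequence[float] | None = None) -> float:
    """Weighted mean staining intensity, normalized to [0, 1].

    Default weights are (0, 1, 2, 3) for 4-level profiles and (0, 1) for
    binary markers, normalized by the maximum weight so a slide stained
    entirely at the highest level scores 1.
    """
    if weights is None:
        weights = tuple(range(p.n_categories))
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != p.n_categories:
        raise ValidationError(
            f"{w.shape[0]} weights for {p.n_categories} categories"
        )
    return float(np.dot(w, p.proportions) / w.max())


def mean_intensity_score(
    profiles: Sequence[IHCProfile], weights: Sequence[float] | None = None
) -> float:
    """Arithmetic mean intensity score over a patient's available samples."""
    if not profiles:
        return math.nan
    _check_comparable(profiles)
    return float(np.mean([intensity_score(p, weights) for p in profiles]))


def _check_comparable(profiles: Sequence[IHCProfile]) -> None:
    markers = {p.marker for p in profiles}
    systems = {p.categories for p in profiles}
    if len(markers) != 1 or len(systems) != 1:
        raise ValidationError(
            f"profiles are not comparable (markers {markers}, systems {systems})"
        )


def _emd_cdf(a: np.ndarray, b: np.ndarray) -> float:
    """Unnormalized EMD between histograms on unit-spaced ordered categories.

    Equal to the sum of absolute CDF differences at the K-1 interior cut
    points, which is the minimum-cost transport on the line.
    """
    diff = np.cumsum(a - b)[:-1]
    return float(np.abs(diff).sum())


def profile_emd(a: IHCProfile, b: IHCProfile, normalize: bool = True) -> float:
    """Earth Mover's Distance between two staining histograms of one marker.

    The minimum total mass movement (category steps x mass) turning one
    profile into the other.  With ``normalize`` the value is divided by K-1
    so 4-level and 2-level markers share a [0, 1] scale; for binary markers
    it reduces to |p_present(a) - p_present(b)|.
    """
    _check_comparable([a, b])
    raw = _emd_cdf(np.asarray(a.proportions), np.asarray(b.proportions))
    if normalize:
        return raw / (a.n_categories - 1)
    return raw


def cdi(p: IHCProfile) -> float:
    """Cumulative Density Index: staining uniformity within one sample.

    1 - EMD(p, uniform) / EMD(extreme, uniform) with unnormalized EMD,
    where uniform puts 1/K in every category and extreme is a point mass at
    the first category (by symmetry the last gives the same denominator).
    Ranges from 0 (all weight in one extreme category) to 1 (uniform).
    """
    k = p.n_categories
    uniform = np.full(k, 1.0 / k)
    extreme = np.zeros(k)
    extreme[0] = 1.0
    denom = _emd_cdf(extreme, uniform)
    return 1.0 - _emd_cdf(np.asarray(p.proportions), uniform) / denom


def patient_marker_summary(
    patient_id: str,
    profiles: Sequence[IHCProfile],
    weights: Sequence[float] | None = None,
    normalize_emd: bool = True,
) -> MarkerSummary:
    """Three-scale summary for one marker of one patient (1 or 2 samples).

    ``emd_between`` is NaN when only one sample is available; ``mis`` and
    ``cdi_within`` average over whatever samples exist.
    """
    if not 1 <= len(profiles) <= 2:
        raise ValidationError("expected 1 or 2 profiles per patient and marker")
    _check_comparable(profiles)
    mis = mean_intensity_score(profiles, weights)
    emd = (
        profile_emd(profiles[0], profiles[1], normalize=normalize_emd)
        if len(profiles) == 2
        else math.nan
    )
    cdi_within = float(np.mean([cdi(p) for p in profiles]))
    return MarkerSummary(
        patient_id=patient_id,
        marker=profiles[0].marker,
        mis=mis,
        emd_between=emd,
        cdi_within=cdi_within,
    )


def marker_summary_table(patients, ihc_profiles, weights=None, normalize_emd=True):
    """Tidy per-patient, per-marker summary table.

    Patients with no profile for a marker are absent from that marker's rows.
    """
    import pandas as pd

    by_sample: dict[str, list[IHCProfile]] = {}
    for p in ihc_profiles:
        by_sample.setdefault(p.sample_id, []).append(p)
    rows = []
    for pt in patients:
        per_marker: dict[str, list[IHCProfile]] = {}
        for sid in pt.sample_ids:
            for prof in by_sample.get(sid, []):
                per_marker.setdefault(prof.marker, []).append(prof)
        for marker in sorted(per_marker):
            s = patient_marker_summary(
                pt.patient_id, per_marker[marker], weights, normalize_emd
            )
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "marker": s.marker,
                    "mis": s.mis,
                    "emd_between": s.emd_between,
                    "cdi_within": s.cdi_within,
                }
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "marker", "mis", "emd_between", "cdi_within"]
    )
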