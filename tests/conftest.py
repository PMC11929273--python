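"""Shared fixtures: tiny hand-built cohorts and independent test oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from dcisith.types import (
    CopyNumberProfile,
    GenomicBin,
    PatientRecord,
    SampleVariantSet,
    VariantKey,
)


def vk(pos: int, chrom: str = "chr1") -> VariantKey:
    return VariantKey(chrom, int(pos) + 1, "A", "T")  # keep positions 1-based


def vset(sample_id: str, patient_id: str, positions) -> SampleVariantSet:
    return SampleVariantSet(sample_id, patient_id, frozenset(vk(p) for p in positions))


def make_profile(sample_id, patient_id, log2, width=50_000, chrom="chr1"):
    bins = [GenomicBin(chrom, i * width, (i + 1) * width, i) for i in range(len(log2))]
    return CopyNumberProfile(sample_id, patient_id, bins, np.asarray(log2, float))


def transport_emd(p, q):
    """Minimum-cost transport between two histograms on ordered categories,
    solved as a linear program; the independent oracle for the CDF formula."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    k = p.size
    cost = np.abs(np.subtract.outer(np.arange(k), np.arange(k))).ravel()
    a_eq = []
    for i in range(k):  # row sums -> p
        row = np.zeros((k, k))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(k):  # column sums -> q
        col = np.zeros((k, k))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(
        cost,
        A_eq=np.array(a_eq),
        b_eq=np.concatenate([p, q]),
        bounds=(0, None),
        method="highs",
    )
    assert res.success
    return res.fun


def brute_force_divergence(a: set, b: set) -> float:
    """Element-by-element shared/private classification (percent private)."""
    union = a | b
    if not union:
        return float("nan")
    private = sum(1 for x in union if (x in a) != (x in b))
    return 100.0 * private / len(union)


def brute_force_youden(risks, events):
    """Exhaustive scan over all thresholds (all midpoints and beyond)."""
    risks = np.asarray(risks, float)
    events = np.asarray(events, int)
    uniq = np.sort(np.unique(risks))
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = (None, -np.inf)
    for t in cands:
        pred = risks > t
        sens = (pred & (events == 1)).sum() / max(events.sum(), 1)
        spec = (~pred & (events == 0)).sum() / max((1 - events).sum(), 1)
        j = sens + spec - 1
        if j > best[1] + 1e-12:
            best = (t, j)
    return best


@pytest.fixture
def nine_patient_cohort():
    """Hand-built cohort covering every outcome type for endpoint tests."""
    rows = [
        ("N1", "nonrecurrent", 80.0, "none"),
        ("N2", "nonrecurrent", 117.0, "none"),
        ("N3", "nonrecurrent", 150.0, "none"),
        ("R1", "recurrent", 30.0, "dcis_recurrence"),
        ("R2", "recurrent", 45.0, "dcis_recurrence"),
        ("R3", "recurrent", 90.0, "dcis_recurrence"),
        ("G1", "progressor", 50.0, "progression"),
        ("G2", "progressor", 24.0, "progression"),
        ("G3", "progressor", 110.0, "progression"),
    ]
    return [
        PatientRecord(
            patient_id=pid,
            cohort=cohort,
            sample_ids=(f"{pid}_A", f"{pid}_B"),
            outcome_time=t,
            outcome_event=ev,
            treatment="lumpectomy_only",
            er_status="pos",
            surgical_margin_mm=2.0,
        )
        for pid, cohort, t, ev in rows
    ]
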