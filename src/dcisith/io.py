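"""Readers and writers for the pipeline's tab-separated input/output tables.

All tables are plain TSV.  Variants may alternatively be supplied as one
VCF per sample.  Readers are deterministic and independent of input row
order; every reader/writer pair round-trips content exactly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FOUR_LEVEL,
    TWO_LEVEL,
    AnalysisConfig,
    CopyNumberProfile,
    GenomicBin,
    IHCProfile,
    ParseError,
    PatientRecord,
    SampleVariantSet,
    ValidationError,
    VariantKey,
)

__all__ = [
    "read_variants",
    "read_cna_bins",
    "read_ihc",
    "read_clinical",
    "validate_cohort",
    "write_variants",
    "write_cna_bins",
    "write_ihc",
    "write_clinical",
    "write_run_manifest",
]

_VARIANT_COLS = ["sample_id", "patient_id", "chrom", "pos", "ref", "alt"]
_CNA_COLS = ["sample_id", "patient_id", "chrom", "start", "end", "log2"]


def _chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering: chr2 < chr10 < chrX."""
    m = re.match(r"(?:chr)?(\d+|[XYM]T?)$", str(chrom), re.IGNORECASE)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (0, int(tok), "")
        return (1, 0, tok)
    return (2, 0, str(chrom))


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")


def read_variants(
    path,
    dialect: str = "tsv",
    sample_id: str | None = None,
    patient_id: str | None = None,
) -> list[SampleVariantSet]:
    """Read somatic SNV calls into one variant set per sample.

    ``tsv`` expects columns sample_id/patient_id/chrom/pos/ref/alt (1-based
    positions, VCF convention); duplicate rows collapse to one variant.
    ``vcf`` reads a single-sample VCF; sample and patient identifiers default
    to the file stem.
    """
    path = Path(path)
    if dialect == "vcf":
        return [_read_vcf(path, sample_id, patient_id)]
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    _require_columns(df, _VARIANT_COLS, path)
    sets: dict[str, tuple[str, set[VariantKey]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: bad position {row.pos!r}") from exc
        key = VariantKey(str(row.chrom), pos, str(row.ref), str(row.alt))
        try:
            key.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
        sid = str(row.sample_id)
        entry = sets.setdefault(sid, (str(row.patient_id), set()))
        if entry[0] != str(row.patient_id):
            raise ValidationError(
                f"{path}: line {i}: sample {sid} mapped to two patients"
            )
        entry[1].add(key)
    return [
        SampleVariantSet(sample_id=sid, patient_id=pid, variants=frozenset(vs))
        for sid, (pid, vs) in sorted(sets.items())
    ]


def _read_vcf(path: Path, sample_id: str | None, patient_id: str | None) -> SampleVariantSet:
    sid = sample_id or path.stem.removesuffix(".vcf")
    pid = patient_id or sid
    variants: set[VariantKey] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}: line {lineno}: truncated VCF record")
            chrom, pos_s, _id, ref, alts = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad POS {pos_s!r}") from exc
            for alt in alts.split(","):
                if alt in (".", ""):
                    continue
                try:
                    variants.add(VariantKey(chrom, pos, ref, alt).validate())
                except ValidationError as exc:
                    raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return SampleVariantSet(sample_id=sid, patient_id=pid, variants=frozenset(variants))


def read_cna_bins(path) -> list[CopyNumberProfile]:
    """Read bin-level corrected log2 ratios into per-sample profiles.

    Bins are sorted by (chrom, start); an NA log2 marks a bin filtered
    upstream.  Overlapping bins within a sample are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _CNA_COLS, path)
    profiles = []
    for sid, g in sorted(df.groupby("sample_id", sort=True)):
        pids = g["patient_id"].unique()
        if len(pids) != 1:
            raise ValidationError(f"{path}: sample {sid} mapped to two patients")
        g = g.copy()
        g["_ck"] = g["chrom"].map(_chrom_sort_key)
        g = g.sort_values(["_ck", "start"], kind="mergesort")
        bins = []
        for i, row in enumerate(g.itertuples(index=False)):
            b = GenomicBin(str(row.chrom), int(row.start), int(row.end), i)
            b.validate()
            bins.append(b)
        profiles.append(
            CopyNumberProfile(
                sample_id=str(sid),
                patient_id=str(pids[0]),
                bins=bins,
                log2=g["log2"].to_numpy(dtype=float),
            )
        )
    return profiles


def _detect_categories(columns: list[str]) -> list[tuple[str, ...]]:
    systems = []
    for system in (FOUR_LEVEL, TWO_LEVEL):
        if all(c in columns for c in system):
            systems.append(system)
    return systems


def read_ihc(path) -> list[IHCProfile]:
    """Read staining-intensity profiles.

    Columns: sample_id, marker, plus one column per ordered category
    (4-level absence/low/medium/high and/or 2-level absent/present; a file
    may mix both systems, with the unused system's cells left empty).  Rows
    summing to ~100 are treated as percentages and rescaled; rows that sum
    to neither ~1 nor ~100 (1% tolerance) are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "marker"], path)
    systems = _detect_categories(list(df.columns))
    if not systems:
        raise ParseError(
            f"{path}: no known category columns found "
            f"(expected {FOUR_LEVEL} or {TWO_LEVEL})"
        )
    profiles = []
    for i, row in df.iterrows():
        lineno = i + 2
        chosen = None
        for system in systems:
            vals = [row[c] for c in system]
            if all(pd.notna(v) for v in vals):
                chosen = (system, [float(v) for v in vals])
                break
        if chosen is None:
            raise ParseError(f"{path}: line {lineno}: incomplete category row")
        system, vals = chosen
        total = sum(vals)
        if abs(total - 1.0) <= 0.01:
            props = [v / total for v in vals]
        elif abs(total - 100.0) <= 1.0:
            props = [v / total for v in vals]
        else:
            raise ValidationError(
                f"{path}: line {lineno}: row sums to {total:g}, "
                "expected ~1 (proportions) or ~100 (percent)"
            )
        profiles.append(
            IHCProfile(
                sample_id=str(row["sample_id"]),
                marker=str(row["marker"]),
                categories=system,
                proportions=tuple(props),
            )
        )
    return profiles


_CLINICAL_BASE = [
    "patient_id",
    "cohort",
    "outcome_time",
    "outcome_event",
    "treatment",
    "er_status",
    "surgical_margin_mm",
    "sample_id_1",
    "sample_id_2",
]


def read_clinical(path, schema: dict[str, str] | None = None) -> list[PatientRecord]:
    """Read the per-patient clinical/outcome table.

    ``schema`` maps extra covariate names to 'numeric' or 'categorical';
    covariates stay in each record's open-ended map.  Missingness is
    preserved (imputation is an explicit later step); a missing er_status
    becomes 'unknown'.
    """
    path = Path(path)
    schema = schema or {}
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _CLINICAL_BASE, path)
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate patient_id(s): {sorted(set(dup))}")
    records = []
    for row in df.itertuples(index=False):
        cov: dict[str, object] = {}
        for name, kind in schema.items():
            val = getattr(row, name, None)
            if pd.isna(val):
                cov[name] = np.nan if kind == "numeric" else None
            else:
                cov[name] = float(val) if kind == "numeric" else str(val)
        records.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                cohort=str(row.cohort),
                sample_ids=(str(row.sample_id_1), str(row.sample_id_2)),
                outcome_time=(
                    None if pd.isna(row.outcome_time) else float(row.outcome_time)
                ),
                outcome_event=str(row.outcome_event),
                treatment=None if pd.isna(row.treatment) else str(row.treatment),
                er_status=(
                    "unknown" if pd.isna(row.er_status) else str(row.er_status)
                ),
                surgical_margin_mm=(
                    None
                    if pd.isna(row.surgical_margin_mm)
                    else float(row.surgical_margin_mm)
                ),
                covariates=cov,
                idc_sample_id=(
                    None
                    if not hasattr(row, "idc_sample_id") or pd.isna(row.idc_sample_id)
                    else str(row.idc_sample_id)
                ),
            )
        )
    return records


def validate_cohort(
    patients: list[PatientRecord],
    variants: list[SampleVariantSet] | None = None,
    cna: list[CopyNumberProfile] | None = None,
    ihc: list[IHCProfile] | None = None,
) -> pd.DataFrame:
    """Cross-reference patient sample ids against the molecular tables.

    Report-only: each patient gets zero or more flags naming the modality
    whose metrics will be unavailable.  Analyses proceed per-modality on
    the patients that have complete data for that modality.
    """
    var_sids = {v.sample_id for v in variants} if variants is not None else None
    cna_sids = {p.sample_id for p in cna} if cna is not None else None
    ihc_sids = {p.sample_id for p in ihc} if ihc is not None else None
    rows = []
    for pt in patients:
        flags = []
        if len(set(pt.sample_ids)) != 2:
            flags.append("structural: duplicated DCIS sample ids")
        for label, sids in (
            ("SNV", var_sids),
            ("CNA", cna_sids),
            ("IHC", ihc_sids),
        ):
            if sids is None:
                continue
            missing = [s for s in pt.sample_ids if s not in sids]
            if missing:
                flags.append(
                    f"{label} metrics unavailable: missing sample(s) "
                    + ",".join(missing)
                )
        rows.append(
            {"patient_id": pt.patient_id, "n_flags": len(flags), "flags": "; ".join(flags)}
        )
    return pd.DataFrame(rows, columns=["patient_id", "n_flags", "flags"])


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)


def write_variants(sets: list[SampleVariantSet], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
        }
        for s in sets
        for v in sorted(s.variants)
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)


def write_cna_bins(profiles: list[CopyNumberProfile], path) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "patient_id": p.patient_id,
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "log2": p.log2[i],
        }
        for p in profiles
        for i, b in enumerate(p.bins)
    ]
    pd.DataFrame(rows, columns=_CNA_COLS).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_ihc(profiles: list[IHCProfile], path) -> None:
    has4 = any(p.categories == FOUR_LEVEL for p in profiles)
    has2 = any(p.categories == TWO_LEVEL for p in profiles)
    cols = ["sample_id", "marker"]
    cols += list(FOUR_LEVEL) if has4 else []
    cols += list(TWO_LEVEL) if has2 else []
    rows = []
    for p in profiles:
        row: dict[str, object] = {"sample_id": p.sample_id, "marker": p.marker}
        row.update(dict(zip(p.categories, p.proportions)))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_clinical(
    patients: list[PatientRecord], path, schema: dict[str, str] | None = None
) -> None:
    schema = schema or {}
    rows = []
    for pt in patients:
        row: dict[str, object] = {
            "patient_id": pt.patient_id,
            "cohort": pt.cohort,
            "outcome_time": pt.outcome_time,
            "outcome_event": pt.outcome_event,
            "treatment": pt.treatment,
            "er_status": pt.er_status,
            "surgical_margin_mm": pt.surgical_margin_mm,
            "sample_id_1": pt.sample_ids[0],
            "sample_id_2": pt.sample_ids[1],
            "idc_sample_id": pt.idc_sample_id,
        }
        for name in schema:
            row[name] = pt.covariates.get(name)
        rows.append(row)
    pd.DataFrame(rows, columns=_CLINICAL_BASE + ["idc_sample_id"] + list(schema)).to_csv(
        path, sep="\t", index=False
    )


def write_run_manifest(path, config: AnalysisConfig, seed: int, extra: dict | None = None) -> None:
    """Serialize the resolved configuration and seed alongside run output."""
    manifest = {"config": config.to_dict(), "seed": int(seed)}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
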