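"""End-to-end orchestration: metric tables, feature matrix, outcome models."""

from __future__ import annotations

import pandas as pd

from .divergence import patient_metrics_table
from .ihc import marker_summary_table
from .survival import OutcomeModelResult, run_outcome_model
from .types import AnalysisConfig

__all__ = ["molecular_feature_table", "run_all"]


def molecular_feature_table(
    patients,
    variant_sets,
    cna_profiles,
    ihc_profiles,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-patient molecular/phenotypic feature matrix for outcome modeling.

    Columns: snv_burden, snv_divergence, cna_burden (mean of the two
    samples), cna_divergence, plus mis_/emd_/cdi_ per marker.  Missing
    modalities stay NaN; these columns are never imputed downstream.
    """
    config = config or AnalysisConfig()
    gen = patient_metrics_table(patients, variant_sets, cna_profiles, config)
    gen = gen.set_index("patient_id")
    feats = pd.DataFrame(index=gen.index)
    feats["snv_burden"] = gen["snv_burden"]
    feats["snv_divergence"] = gen["snv_divergence"]
    feats["cna_burden"] = gen[["cna_burden_s1", "cna_burden_s2"]].mean(axis=1)
    feats["cna_divergence"] = gen["cna_divergence"]
    if ihc_profiles:
        ihc = marker_summary_table(
            patients,
            ihc_profiles,
            weights=None,
            normalize_emd=config.emd_normalize,
        )
        wide = ihc.pivot(index="patient_id", columns="marker")
        wide.columns = [f"{stat}_{marker}" for stat, marker in wide.columns]
        feats = feats.join(wide, how="left")
    return feats


def run_all(
    patients,
    variant_sets,
    cna_profiles,
    ihc_profiles,
    config: AnalysisConfig | None = None,
    clinical_schema: dict[str, str] | None = None,
    modes: tuple[str, ...] = ("recurrence", "progression"),
    molecular_columns: list[str] | None = None,
    complete_case_variant: bool = True,
) -> dict[str, OutcomeModelResult]:
    """Run the outcome model for each endpoint mode on one cohort."""
    config = config or AnalysisConfig()
    feats = molecular_feature_table(
        patients, variant_sets, cna_profiles, ihc_profiles, config
    )
    return {
        mode: run_outcome_model(
            patients,
            feats,
            mode,
            config=config,
            clinical_schema=clinical_schema,
            molecular_columns=molecular_columns,
            complete_case_variant=complete_case_variant,
        )
        for mode in modes
    }
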