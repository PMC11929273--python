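# dcisith

Paired-sample intratumor heterogeneity metrics and outcome modeling for
two-region tumor studies — built around ductal carcinoma in situ (DCIS)
cohorts in which every patient contributes two geographically distinct
samples of the same lesion and is followed for non-invasive recurrence or
invasive progression.

The package answers two questions. First, **how much has a tumor diverged
internally?** From two samples per patient it computes somatic SNV burden
(union mutation count) and divergence (percent of union mutations private
to one sample, requiring a union of ≥ 5), copy-number burden (fraction of
genome with |corrected log2 ratio| > 0.3) and divergence (symmetric
difference over union of altered bins, bp-weighted), and three ordinal
immunohistochemistry statistics — mean intensity score, between-sample
Earth Mover's Distance, and the Cumulative Density Index of within-sample
staining uniformity.  Second, **which of these measurements predict
outcome?**  It builds endpoint-specific survival tables (recurrence,
progression, and two sensitivity variants), runs Cox proportional-hazards
models with standardized covariates (hazard ratios per 1 SD, rescalable to
natural units), selects variables by repeating 10-fold cross-validated
Cox-LASSO 100 times and keeping covariates selected in ≥ 90% of
repetitions, and stratifies patients by relative risk at the threshold
maximizing Youden's J, comparing groups with the log-rank test.

A seeded synthetic-cohort generator emulates the full data structure —
cohort-specific burden/divergence distributions, Dirichlet staining
profiles, clinical covariates with missingness, and Weibull
proportional-hazards event times — so every stage is testable end to end
without controlled-access patient data.  `docs/methods.md` documents the
models, defaults, and known limitations.

## Worked example

Simulate a 250-patient cohort, compute per-patient metrics, and fit both
endpoint models:

```bash
dcisith --seed 1 --out-dir demo simulate --n-patients 250
dcisith --seed 1 --out-dir demo run-all \
    --variants demo/variants.tsv --cna demo/cna_bins.tsv \
    --ihc demo/ihc.tsv --clinical demo/clinical.tsv
```

or from Python:

```python
from dcisith.simulate import reference_cohort_config, simulate_cohort
from dcisith.pipeline import run_all
from dcisith.survival import hr_rescale
from dcisith.types import AnalysisConfig

bundle = simulate_cohort(reference_cohort_config(n_patients=250, seed=3))
results = run_all(bundle.patients, bundle.variant_sets, bundle.cna_profiles,
                  bundle.ihc_profiles, AnalysisConfig(base_seed=3),
                  clinical_schema={"age": "numeric"})
rec = results["recurrence"]
print(rec.stability.selected)
print(hr_rescale(rec.cox, "snv_divergence", 10.0))
print(rec.stratification.km.pvalue)
```

On this seed the recurrence model selects `snv_divergence` (with a few
other cohort-informative measurements) and not `snv_burden`; the hazard
ratio rescales to about 1.29 per 10 percentage points of SNV divergence;
and the risk-stratified Kaplan-Meier groups separate at log-rank
p ≈ 8e-8.  The progression model selects `snv_burden` (HR ≈ 1.18 per 10
SNVs on this cohort).  Interpretation: time to non-invasive recurrence
tracks how *divergent* the two regions are, while time to progression
tracks the *total* mutation load — the endpoint-specific pattern the
generator plants and the pipeline recovers.

Each `run-all` invocation writes per-endpoint selection-frequency,
Cox-coefficient (forest-plot-ready HR/CI/p), and Kaplan-Meier curve and
at-risk tables as TSV, plus a JSON manifest embedding the resolved
configuration and seed.

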