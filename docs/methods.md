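# Methods

`dcisith` analyzes paired-sample tumor data: for every patient, two
geographically distinct samples of the same in-situ lesion are assayed for
somatic SNVs, bin-level copy number, and ordinal immunohistochemistry (IHC)
staining, and the patients are followed for non-invasive recurrence or
invasive progression.  This note describes the models and statistics the
package implements, the choices made where a design question was genuinely
open, and what the synthetic cohort generator does and does not emulate.

## Burden and divergence

**SNV burden** is the number of distinct somatic SNVs in the union of a
patient's two samples; a variant's identity is (chrom, 1-based pos, ref,
alt), exact match.  **SNV divergence** is the percentage of union variants
private to one sample, `100·(|A∪B| − |A∩B|)/|A∪B|`, reported only when the
union holds at least `min_union_snvs = 5` variants — divergence estimated
from a handful of mutations is dominated by calling noise, so it is an
explicit missing value, never zero.

**Copy-number burden** is the fraction of the considered genome altered:
bins whose corrected log2 ratio satisfies `|log2| > 0.3` (strict
inequality; a bin at exactly 0.3 is normal) are altered, and burden is the
bp-weighted fraction of altered among bins with a non-missing log2.  Bins
filtered upstream (NA log2) leave both numerator and denominator.
**Copy-number divergence** is the bp of the symmetric difference of the two
samples' altered-bin sets over the bp of their union, as a percentage;
bins missing in either sample are dropped from both.  Weighting by bin
width equals bin counting on a uniform grid but stays correct for ragged
chromosome-end bins.  By default a bin altered in both samples is shared
regardless of direction, since sharing is defined on the set of altered
regions; `direction_aware=True` treats a gain-in-one/loss-in-other bin as
discordant, which is biologically defensible, and is provided as a flag.
Bins are the region unit throughout, being the native resolution of the
consumed bin-level input.

For patients with an additional invasive sample, the in-situ-vs-invasive
divergence is the mean of the two pairwise comparisons against the
invasive sample; if only one comparison reaches the union-size requirement
the computable one is used (maximizing usable patients), and the output
records how many comparisons contributed.

## Ordinal IHC statistics

Staining profiles are histograms over ordered intensity categories
(4-level absence/low/medium/high, or binary absent/present).  Three
statistics summarize a patient-marker pair at three scales:

* **Intensity score** — weighted mean staining normalized to [0, 1].
  Medium staining is treated as about twice, and high staining about three
  times, as intense as low, giving weights (0, 1, 2, 3)/3; binary markers
  score as the stained fraction.  The weight vector is configurable.
* **Earth Mover's Distance (EMD)** — between-sample divergence: the
  minimum total mass-times-distance needed to turn one histogram into the
  other.  On ordered categories with unit spacing this is the sum of
  absolute CDF differences at the K−1 interior cut points (the tests
  verify this against a transport linear program to 1e-9).  By default the
  value is divided by K−1 so 4-level and binary markers share a [0, 1]
  scale.
* **Cumulative Density Index (CDI)** — within-sample uniformity:
  `1 − EMD(p, uniform)/EMD(extreme, uniform)` with unnormalized EMD, where
  `uniform` is the flat histogram and `extreme` a point mass at the first
  category (either extreme gives the same denominator by symmetry).  It is
  1 for a uniform profile and 0 for a point mass at an extreme category.
  This is the simplest construction matching both defining endpoints; the
  patient-level within-sample value is the mean of the two samples' CDIs.

## Cohort comparisons

Distribution comparisons across patient groups use rank tests: Mann-Whitney
U (exact when the pooled sample is ≤ 30 without ties, tie-corrected normal
approximation with continuity correction otherwise) for two groups, and
Kruskal-Wallis followed by Dunn's pooled-rank z-tests under the Holm-Šidák
step-down adjustment for three.  An exact binomial sign test serves paired
within-patient comparisons, ties discarded.

Copy-number *divergence* (one value per patient) is compared with one-way
ANOVA plus Tukey HSD.  Copy-number *burden* is a per-sample fraction with
two samples per patient, so cohorts are compared with a mixed-effects ANOVA
on the square-root-transformed fractions with a random intercept per
patient; the omnibus fixed-effect F uses between-patient denominator
degrees of freedom (n_patients − n_groups), and pairwise contrasts of the
estimated marginal means are adjusted with the studentized range.  For
balanced designs this inference has a closed form — the one-way ANOVA on
per-patient means — which is used directly (it is the exact REML solution
and makes the degenerate duplicated-samples case reduce to the one-value-
per-patient ANOVA identically); unbalanced designs fall back to an
iterative REML fit.

Cross-sectional discrimination between two patient groups proceeds in the
sequence: Random-Forest Gini-importance ranking of all candidate
measurements (complete cases, seeded, deterministic), a logistic model on
the top-ranked measurements, and AIC comparison of competing models after
refitting every model on the patients complete for all models' features —
AICs are only comparable on a common likelihood support.

## Endpoint construction and survival modeling

Patients carry one of three outcome states: censored at follow-up
(nonrecurrent), non-invasive recurrence, or invasive progression, each
with a time in months.  Four endpoint modes translate these into survival
tables: `recurrence` (progressors discarded), `progression` (recurrents
discarded), `any_recurrence` (both event types count), and
`progression_censor_recurrents` (recurrents censored at their recurrence
time).  Discarded patients are absent, not censored.  Median follow-up is
summarized by the reverse Kaplan-Meier method (KM of the censoring
distribution, event indicator flipped).

Cox models are partial-likelihood fits with Efron tie handling; Wald tests
give per-coefficient p-values, and a Schoenfeld-residual test per covariate
reports proportional-hazards violations alongside the fit (reported, not
enforced).  All covariates are standardized (z-scores, sample SD) so hazard
ratios are per 1 SD; `hr_rescale` converts to natural units
(HR_unit = exp(β·unit/SD_raw)).  Clinical covariates are reference-coded
(first sorted level dropped) before imputation — one-dummy-per-level coding
would make the final unpenalized refit rank-deficient — and missing
clinical values are mean-imputed (dummies by observed level proportions).
Molecular and phenotypic measurements are never imputed; their missing
values restrict the analysis to complete cases, and a no-imputation
sensitivity variant runs alongside.

**Variable selection** repeats cross-validated Cox-LASSO: in each of 100
repetitions a fresh 10-fold split is drawn (seeded `base_seed + r`), the
LASSO path is fit on each training split over a λ grid log-spaced from
λ_max (smallest all-zero penalty) down four decades (100 points by
default), λ* minimizes the summed held-out partial-likelihood deviance
(computed as the difference between full-data and training-split Breslow
log partial likelihoods at the training-split solution, the standard
grouped construction), and the covariates with nonzero full-data
coefficients at λ* are recorded.  Covariates selected in at least 90% of
repetitions form the selected set, refit unpenalized on all patients with
data for those variables.

A known operating characteristic, documented here because the test suite
measures it: the CV-deviance minimizer overselects when true effects are
strong.  Once the strong signals are in the model, decreasing λ keeps
improving the held-out deviance by relieving their shrinkage even as
small-coefficient noise variables enter, so λ* lands deep in the path and
weakly correlated covariates can hold nonzero coefficients at λ* for a
given dataset — and hence be selected in ~100% of repetitions, because
repetitions vary only the fold assignment, not the data.  The repetition
filter therefore prunes borderline variables reliably only when the signal
is weak enough that λ* itself is unstable.  This behavior is reproduced
exactly by independent Cox-LASSO CV implementations on identical data; the
end-to-end tests that expect exact support recovery under strong effects
record it as a limitation of the selection rule rather than of this
implementation.

**Risk stratification** scores each patient by risk relative to the
covariate-mean reference, `r_i = exp(Σ β_j x_ij)` on standardized
covariates, splits at the threshold maximizing Youden's J (sensitivity +
specificity − 1) against the observed binary outcomes — candidate
thresholds are midpoints between consecutive unique risks plus the two
trivial extremes, ties resolving to the smallest — and compares the two
groups' Kaplan-Meier curves with the log-rank test.  Using the binary
outcome indicator ignores censoring times; the threshold is therefore
optimistic in-sample and the resulting log-rank p describes separation on
the analysis set, not out-of-sample discrimination.

## Synthetic cohort generator

The generator exists so every pipeline stage is testable without patient
data; its default configuration reproduces the marginal structure of a
three-cohort longitudinal study by moment matching.  Per cohort
(nonrecurrent/recurrent/progressor, weights 99/69/56): SNV union burden is
negative binomial (means 13.4/19.2/39.7, SDs 18.2/26.4/46.2 — SD > mean
requires the overdispersed count family), divergences and per-sample CNA
burden are beta (SNV divergence 17.0/28.2/18.4 ± 13.8/25.5/19.3 %; CNA
burden 15.9/17.3/24.6 ± 15.0/14.8/17.1 %; CNA divergence 77.4/67.7/63.7 ±
16.4/23.4/21.7 %), and IHC profiles are Dirichlet per marker (ER and GLUT1
by default, with GLUT1 concentrations differing across cohorts).  Burden
and divergence are drawn independently; an observed correlation would need
an explicit joint model, which the generator does not claim.

Given a union burden U and divergence d, `round(U·d)` variants are private
(split evenly, odd remainder to sample 1) and the rest shared, so the
divergence metric recovers the realized private fraction exactly.  For
copy number, the union altered fraction is `u = f/(1 − d/2)` (f the
per-sample burden draw); the private bin count is Binomial(n_union, d)
rather than deterministic rounding, which would bias realized divergence
upward for low-burden patients; infeasible (f, d) pairs (u > 1) keep the
burden draw exact and shrink the divergence to its feasibility bound
2(1 − f).  Log2 ratios are emitted from truncated normals — altered bins
N(±0.5, 0.15) truncated beyond the 0.3 threshold, normal bins N(0, 0.05)
truncated inside it — so thresholding recovers the planted alteration sets
exactly; without truncation ~9% of altered bins would fall below threshold
and the generator's own ground truth would disagree with the metrics.
The grid defaults to 500 bins of 50 kb (a scaled-down genome; the metrics
are grid-size-agnostic).

Outcomes: by default the cohort label is drawn first (study weights or
fixed per-cohort sizes), features come from that cohort's distributions,
and the outcome follows the label — nonrecurrents censor at a follow-up
time drawn Uniform(60, 174) months (median 117), event cohorts draw a
Weibull proportional-hazards time (shape 1.3; scale 120 months for
recurrence, 100 for progression) with log-hazard shifted by configurable
coefficients on the standardized true features (defaults: +0.5/SD of SNV
divergence for recurrence, +0.5/SD of SNV burden for progression,
mirroring the divergence→recurrence / burden→progression pattern), and
truncated to the follow-up window since an observed event must precede the
follow-up horizon.  This mode matches the per-cohort moment anchors
exactly, which post-hoc labeling cannot.  The alternative `latent` mode
draws competing recurrence/progression times plus censoring for every
patient and labels post hoc from whichever comes first — the
observational design — at the cost of reshaping per-label feature
distributions.  Missingness injection (margin 10%, ER status 5% by
default) touches clinical covariates only, never outcomes.  A single
seeded generator drives every draw; identical seeds give byte-identical
output tables.

What passing tests on this generator do **not** show about real data: no
FFPE artifacts or caller error (variant identities are exact), no spatial
or clonal structure within samples, no burden-divergence dependence, no
informative censoring, and IHC profiles without spatial autocorrelation.
The generator validates the analysis machinery, not the biology.

## Numerical and problem-size choices

Exact Mann-Whitney switches to the asymptotic form at pooled n > 30.
The λ grid is 100 points over 4 decades by default; validation suites use
40 points (same decades), which moves λ* negligibly.  Calibration suites
run 2,000 null replicates per test (the Monte-Carlo SE of a rejection rate
is then ~0.005) and 2,000 replicates for Cox CI coverage; end-to-end
checks run 20 seeded cohorts of 250 patients and moment checks 2,000
patients per cohort, sizes at which the relevant standard errors are well
inside the asserted tolerances.  Degenerate inputs are explicit:
no-variance groups report a no-variance result rather than an error;
all-missing bins, empty unions, and all-tied pairs raise typed validation
errors.
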