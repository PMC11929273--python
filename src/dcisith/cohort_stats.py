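"""Cross-cohort comparison tests and cross-sectional discrimination.

Rank-based omnibus and pairwise tests (Mann-Whitney U; Kruskal-Wallis with
Dunn's post-hoc under Holm-Sidak adjustment), parametric alternatives
(one-way ANOVA with Tukey HSD; mixed-effects ANOVA with a per-patient random
intercept for sample-level fractions, square-root transformed), a paired
sign test, and the discrimination sequence used to separate two patient
groups cross-sectionally: Random-Forest Gini importance ranking, logistic
models on the top-ranked measurements, and AIC comparison on the common
complete-case subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .types import ValidationError

__all__ = [
    "GroupComparisonResult",
    "DiscriminatorResult",
    "mann_whitney",
    "kruskal_wallis_dunn",
    "paired_sign_test",
    "anova_tukey",
    "mixed_anova_sqrt",
    "rf_gini_ranking",
    "logistic_discriminator",
    "aic_compare",
]

_PAIRWISE_COLS = ["group_i", "group_j", "statistic", "raw_p", "adjusted_p", "method"]


@dataclass
class GroupComparisonResult:
    variable: str
    method: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None  # columns _PAIRWISE_COLS
    note: str = ""


@dataclass
class DiscriminatorResult:
    ranking: pd.DataFrame  # feature, importance (descending)
    coefficients: pd.DataFrame  # term, estimate, wald_p
    aic: float
    n_used: int
    flags: list[str] = field(default_factory=list)


def mann_whitney(
    values_a, values_b, exact_max_n: int = 30
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie-corrected variance."""
    n = values.size
    ranks = sps.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    groups = sorted(set(labels.tolist()))
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    size = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / size[gi] + 1.0 / size[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((gi, gj, z, p))
    df = pd.DataFrame(rows, columns=["group_i", "group_j", "statistic", "raw_p"])
    with np.errstate(divide="ignore"):  # raw_p == 1 is legitimate
        df["adjusted_p"] = multipletests(df["raw_p"], method="holm-sidak")[1]
    df["method"] = "dunn_holm_sidak"
    return df[_PAIRWISE_COLS]


def kruskal_wallis_dunn(values, group_labels, variable: str = "value") -> GroupComparisonResult:
    """Kruskal-Wallis omnibus test with Dunn's post-hoc (Holm-Sidak adjusted).

    The pairwise stage is reported only when there are more than two groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    h, p = sps.kruskal(*[values[labels == g] for g in groups])
    pairwise = _dunn_pairwise(values, labels) if len(groups) > 2 else None
    return GroupComparisonResult(
        variable=variable,
        method="kruskal_wallis_dunn",
        statistic=float(h),
        pvalue=float(p),
        pairwise=pairwise,
    )


def paired_sign_test(x, y) -> float:
    """Exact two-sided binomial sign test on paired differences; ties dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    d = x - y
    pos = int((d > 0).sum())
    neg = int((d < 0).sum())
    if pos + neg == 0:
        raise ValidationError("no informative pairs (all ties)")
    return float(sps.binomtest(pos, pos + neg, 0.5, alternative="two-sided").pvalue)


def anova_tukey(values, group_labels, variable: str = "value") -> GroupComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Degenerate inputs with zero within- and between-group variance are
    reported as a no-variance case (NaN statistic) rather than an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    samples = [values[labels == g] for g in groups]
    if any(s.size == 0 for s in samples):
        raise ValidationError("a group is empty")
    if np.ptp(values) == 0:
        return GroupComparisonResult(
            variable, "anova_tukey", float("nan"), float("nan"), None, "no variance"
        )
    f, p = sps.f_oneway(*samples)
    pairwise = None
    if len(groups) >= 2:
        hsd = sps.tukey_hsd(*samples)
        rows = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(
                    (
                        groups[i],
                        groups[j],
                        float(hsd.statistic[i, j]),
                        float("nan"),
                        float(hsd.pvalue[i, j]),
                        "tukey_hsd",
                    )
                )
        pairwise = pd.DataFrame(rows, columns=_PAIRWISE_COLS)
    return GroupComparisonResult(variable, "anova_tukey", float(f), float(p), pairwise)


def _patient_means_anova(
    df: pd.DataFrame, variable: str, pairwise: bool = True
) -> GroupComparisonResult:
    """Random-intercept fixed-effect inference via per-patient means.

    With a balanced design this is the exact REML solution: the cohort
    contrast lives entirely between patients, so the omnibus F and the
    Tukey-adjusted pairwise contrasts are those of a one-way ANOVA on the
    patient means (Tukey-Kramer standard errors for unequal group sizes).
    """
    pm = df.groupby("patient", as_index=False).agg(
        y=("y", "mean"), cohort=("cohort", "first")
    )
    groups = sorted(pm["cohort"].unique())
    k = len(groups)
    samples = [pm.loc[pm["cohort"] == g, "y"].to_numpy() for g in groups]
    n_i = {g: s.size for g, s in zip(groups, samples)}
    df_denom = pm.shape[0] - k
    if np.ptp(pm["y"].to_numpy()) == 0:
        return GroupComparisonResult(
            variable, "mixed_anova_sqrt", float("nan"), float("nan"), None, "no variance"
        )
    f, p = sps.f_oneway(*samples)
    if not pairwise:
        return GroupComparisonResult(variable, "mixed_anova_sqrt", float(f), float(p))
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_denom
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = samples[i].mean() - samples[j].mean()
            se = np.sqrt(mse * (1.0 / n_i[gi] + 1.0 / n_i[gj]))
            qstat = abs(diff) / (se / np.sqrt(2.0))
            adj = float(sps.studentized_range.sf(qstat, k, max(df_denom, 1)))
            raw = 2.0 * float(sps.t.sf(abs(diff) / se, max(df_denom, 1)))
            rows.append((gi, gj, diff / se, raw, min(adj, 1.0), "tukey_emm"))
    pairwise = pd.DataFrame(rows, columns=_PAIRWISE_COLS)
    return GroupComparisonResult(variable, "mixed_anova_sqrt", float(f), float(p), pairwise)


def mixed_anova_sqrt(
    values_per_sample,
    patient_ids,
    group_labels,
    variable: str = "value",
    pairwise: bool = True,
) -> GroupComparisonResult:
    """Mixed-effects ANOVA on square-root-transformed per-sample fractions.

    Fits sqrt(y) ~ cohort with a random intercept per patient, so the two
    samples of one patient are not treated as independent.  The omnibus
    fixed-effect test is an F with between-patient denominator degrees of
    freedom (n_patients - n_groups); pairwise contrasts of the estimated
    marginal means are adjusted with the studentized range (Tukey).

    For balanced designs (every patient contributes the same number of
    samples) the REML fixed-effect inference has a closed form: it is the
    one-way ANOVA on per-patient means, which is used directly.  Unbalanced
    designs fall back to an iterative REML fit.
    """
    y = np.asarray(values_per_sample, dtype=float)
    if np.any(y < 0):
        raise ValidationError("values must be non-negative for the sqrt transform")
    df = pd.DataFrame(
        {
            "y": np.sqrt(y),
            "patient": np.asarray(patient_ids).astype(str),
            "cohort": np.asarray(group_labels).astype(str),
        }
    )
    groups = sorted(df["cohort"].unique())
    k = len(groups)
    if k < 2:
        raise ValidationError("need at least two groups")
    n_pat = df["patient"].nunique()
    df_denom = n_pat - k
    if df["patient"].value_counts().nunique() == 1:
        return _patient_means_anova(df, variable, pairwise)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ C(cohort)", df, groups=df["patient"])
        for method in ("lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
    if fit is None:
        # Variance-component boundary: fall back to the patient-means form,
        # which stays exact under the random-intercept model.
        return _patient_means_anova(df, variable, pairwise)
    # Wald F on the k-1 cohort terms.
    names = list(fit.fe_params.index)
    idx = [i for i, nm in enumerate(names) if nm.startswith("C(cohort)")]
    beta = fit.fe_params.to_numpy()[idx]
    cov = fit.cov_params().to_numpy()[np.ix_(idx, idx)]
    q = len(idx)
    fstat = float(beta @ np.linalg.solve(cov, beta)) / q
    pval = float(sps.f.sf(fstat, q, df_denom))

    # Estimated marginal means per cohort and Tukey-adjusted pairwise contrasts.
    design = {g: np.zeros(len(names)) for g in groups}
    for g in groups:
        design[g][names.index("Intercept")] = 1.0
        term = f"C(cohort)[T.{g}]"
        if term in names:
            design[g][names.index(term)] = 1.0
    covfull = fit.cov_params().to_numpy()[: len(names), : len(names)]
    betafull = fit.fe_params.to_numpy()
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = design[groups[i]] - design[groups[j]]
            diff = float(c @ betafull)
            se = float(np.sqrt(c @ covfull @ c))
            qstat = abs(diff) / (se / np.sqrt(2.0))
            adj = float(sps.studentized_range.sf(qstat, k, max(df_denom, 1)))
            raw = 2.0 * float(sps.t.sf(abs(diff) / se, max(df_denom, 1)))
            rows.append((groups[i], groups[j], diff / se, raw, min(adj, 1.0), "tukey_emm"))
    pairwise = pd.DataFrame(rows, columns=_PAIRWISE_COLS)
    return GroupComparisonResult(
        variable, "mixed_anova_sqrt", fstat, pval, pairwise
    )


def rf_gini_ranking(
    features: pd.DataFrame, labels, n_trees: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Random-Forest mean-decrease-Gini importance ranking of features.

    Complete-case rows only; deterministic given the seed.  Returns a table
    of features sorted by descending importance.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = pd.DataFrame(features).copy()
    y = pd.Series(np.asarray(labels), index=X.index)
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X[mask], y[mask]
    if y.nunique() < 2:
        raise ValidationError("labels must contain two classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed
    )
    rf.fit(X.to_numpy(dtype=float), y.to_numpy())
    out = pd.DataFrame(
        {"feature": X.columns, "importance": rf.feature_importances_}
    ).sort_values("importance", ascending=False, kind="mergesort")
    return out.reset_index(drop=True)


def logistic_discriminator(
    features: pd.DataFrame, labels, ranking: pd.DataFrame | None = None
) -> DiscriminatorResult:
    """Maximum-likelihood logistic model on the chosen feature subset.

    Reports per-coefficient Wald p-values and the model AIC on the
    complete-case rows.  Perfect separation and rank deficiency are flagged
    rather than fatal.
    """
    X = pd.DataFrame(features).copy()
    y = pd.Series(np.asarray(labels), index=X.index)
    mask = X.notna().all(axis=1) & y.notna()
    X, y = X[mask], y[mask].astype(float)
    flags: list[str] = []
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        flags.append("rank_deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        try:
            fit = model.fit(disp=0)
        except Exception:
            flags.append("perfect_separation")
            fit = model.fit(method="bfgs", maxiter=500, disp=0)
    if not flags and np.any(np.abs(fit.params) > 20):
        flags.append("perfect_separation")
    coef = pd.DataFrame(
        {
            "term": fit.params.index,
            "estimate": fit.params.to_numpy(),
            "wald_p": fit.pvalues.to_numpy(),
        }
    )
    rank = (
        ranking
        if ranking is not None
        else pd.DataFrame({"feature": X.columns, "importance": np.nan})
    )
    return DiscriminatorResult(
        ranking=rank,
        coefficients=coef,
        aic=float(fit.aic),
        n_used=int(mask.sum()),
        flags=flags,
    )


def aic_compare(
    model_specs: dict[str, list[str]], features: pd.DataFrame, labels
) -> pd.DataFrame:
    """Refit every model on the shared complete-case subset and compare AICs.

    The intersection is over patients complete for the union of all models'
    features, so AICs are comparable.  Returns a table sorted by AIC with
    the difference to the best model.
    """
    X = pd.DataFrame(features)
    y = pd.Series(np.asarray(labels), index=X.index)
    all_cols = sorted({c for cols in model_specs.values() for c in cols})
    mask = X[all_cols].notna().all(axis=1) & y.notna()
    if not mask.any():
        raise ValidationError("no patients complete for all models")
    rows = []
    for name, cols in model_specs.items():
        res = logistic_discriminator(X.loc[mask, cols], y[mask])
        rows.append({"model": name, "n": res.n_used, "aic": res.aic})
    out = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out
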