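"""Endpoint construction, Cox modeling, LASSO stability selection, and
risk stratification for time-to-recurrence / time-to-progression analysis.

The cohort holds three patient classes: nonrecurrents (censored at their
follow-up time), recurrents (non-invasive recurrence at their event time),
and progressors (invasive progression; their recurrence time is the time to
clinical outcome).  Four endpoint modes translate these into a survival
table:

* ``recurrence`` - recurrents are events, progressors are discarded;
* ``progression`` - progressors are events, recurrents are discarded;
* ``any_recurrence`` - both recurrence types count as events;
* ``progression_censor_recurrents`` - progressors are events, recurrents
  are right-censored at their recurrence time.

Variable selection repeats ten-fold cross-validated Cox-LASSO (regularization
chosen at the minimum cross-validated partial-likelihood deviance) many times
with fresh fold assignments and keeps covariates whose selection frequency
reaches a threshold (defaults: 100 repetitions, 90%).  The selected set is
refit unpenalized; patients are stratified by relative risk against the
all-covariates-at-the-mean reference, at the threshold maximizing Youden's J
on the observed outcomes; groups are compared with the log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .types import (
    EVENT_NONE,
    EVENT_PROGRESSION,
    EVENT_RECURRENCE,
    AnalysisConfig,
    PatientRecord,
    ValidationError,
)

__all__ = [
    "SurvivalTable",
    "CoxResult",
    "StabilityResult",
    "KMResult",
    "StratificationResult",
    "OutcomeModelResult",
    "ENDPOINT_MODES",
    "prepare_endpoint",
    "reverse_km_median_followup",
    "mean_impute",
    "dummy_code",
    "standardize",
    "cox_fit",
    "hr_rescale",
    "cox_lasso_stability",
    "relative_risk",
    "youden_threshold",
    "km_logrank",
    "build_covariates",
    "run_outcome_model",
]

ENDPOINT_MODES = (
    "recurrence",
    "progression",
    "any_recurrence",
    "progression_censor_recurrents",
)


@dataclass
class SurvivalTable:
    """Analysis-ready endpoint table plus the ids excluded by the mode."""

    mode: str
    data: pd.DataFrame  # patient_id, time, event
    excluded: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())


@dataclass
class CoxResult:
    summary: pd.DataFrame  # indexed by covariate: coef, hr, hr_lower, hr_upper, wald_p, ph_p
    n: int
    n_events: int
    log_likelihood: float
    standardization: pd.DataFrame | None = None  # mean, sd per covariate (raw scale)
    model: object | None = None


@dataclass
class StabilityResult:
    selection_frequency: pd.Series  # per covariate, in [0, 1]
    selected: list[str]
    freq_threshold: float
    reps: int
    folds: int
    base_seed: int
    alphas: np.ndarray
    chosen_alphas: np.ndarray  # one per repetition


@dataclass
class KMResult:
    statistic: float
    pvalue: float
    medians: dict[str, float]  # inf = unreached
    curves: pd.DataFrame  # group, time, survival
    at_risk: pd.DataFrame  # group, time, n_at_risk


@dataclass
class StratificationResult:
    risks: pd.Series  # per patient relative risk
    threshold: float
    youden_j: float
    groups: pd.Series  # 'low' / 'high' per patient
    km: KMResult


@dataclass
class OutcomeModelResult:
    mode: str
    table: SurvivalTable
    stability: StabilityResult
    cox: CoxResult | None
    stratification: StratificationResult | None
    complete_case_stability: StabilityResult | None = None
    complete_case_cox: CoxResult | None = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Endpoint construction and follow-up summary


def prepare_endpoint(patients: list[PatientRecord], mode: str) -> SurvivalTable:
    """Translate cohort labels into (time, event) rows for one endpoint."""
    if mode not in ENDPOINT_MODES:
        raise ValidationError(f"unknown endpoint mode {mode!r}")
    rows, excluded = [], []
    for pt in patients:
        if pt.outcome_time is None or not pt.outcome_time > 0:
            raise ValidationError(
                f"patient {pt.patient_id}: outcome_time required for endpoints"
            )
        ev = pt.outcome_event
        if ev == EVENT_NONE:
            rows.append((pt.patient_id, pt.outcome_time, 0))
        elif ev == EVENT_RECURRENCE:
            if mode in ("recurrence", "any_recurrence"):
                rows.append((pt.patient_id, pt.outcome_time, 1))
            elif mode == "progression_censor_recurrents":
                rows.append((pt.patient_id, pt.outcome_time, 0))
            else:  # progression: discard
                excluded.append(pt.patient_id)
        elif ev == EVENT_PROGRESSION:
            if mode == "recurrence":
                excluded.append(pt.patient_id)
            else:
                rows.append((pt.patient_id, pt.outcome_time, 1))
        else:
            raise ValidationError(f"unknown outcome_event {ev!r}")
    data = pd.DataFrame(rows, columns=["patient_id", "time", "event"])
    return SurvivalTable(mode=mode, data=data, excluded=excluded)


def reverse_km_median_followup(times, event_indicators) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Kaplan-Meier median of the censoring distribution (event indicator
    flipped); returns inf when the median is unreached, in which case the
    largest observed time is a lower bound.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_indicators, dtype=int)
    km = KaplanMeierFitter()
    km.fit(times, 1 - events)
    return float(km.median_survival_time_)


# ---------------------------------------------------------------------------
# Covariate preparation


def dummy_code(cov: pd.DataFrame, categorical: list[str]) -> pd.DataFrame:
    """Reference-code categorical columns (first sorted level dropped).

    Missing values propagate as NaN across a column's dummies so imputation
    can fill them with observed level proportions.
    """
    out = cov.copy()
    for col in categorical:
        if col not in out.columns:
            continue
        levels = sorted(x for x in out[col].dropna().unique())
        for lev in levels[1:]:
            name = f"{col}_{lev}"
            out[name] = (out[col] == lev).astype(float)
            out.loc[out[col].isna(), name] = np.nan
        out = out.drop(columns=[col])
    return out


def mean_impute(
    cov: pd.DataFrame,
    clinical_columns: list[str],
    molecular_columns: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Replace missing clinical entries with the observed column mean.

    Dummy-coded categorical columns are imputed by observed level
    proportions (their column means).  Molecular (genetic/phenotypic)
    columns are never imputed; passing one in the clinical list is an error.
    """
    overlap = set(clinical_columns) & set(molecular_columns)
    if overlap:
        raise ValidationError(
            f"molecular columns may not be imputed: {sorted(overlap)}"
        )
    out = cov.copy()
    for col in clinical_columns:
        if col not in out.columns:
            continue
        s = out[col].astype(float)
        if s.isna().all():
            raise ValidationError(f"column {col!r} is entirely missing")
        out[col] = s.fillna(s.mean())
    return out


def standardize(cov: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise z-scores (sample SD, ddof=1) plus the scaling metadata.

    Zero-variance columns are dropped with a warning.  The metadata (raw
    mean/SD per column) supports rescaling hazard ratios to natural units.
    """
    means = cov.mean()
    sds = cov.std(ddof=1)
    keep = sds > 0
    dropped = [c for c in cov.columns if not keep[c]]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
    z = (cov.loc[:, keep] - means[keep]) / sds[keep]
    meta = pd.DataFrame({"mean": means[keep], "sd": sds[keep]})
    return z, meta


# ---------------------------------------------------------------------------
# Cox model fitting


def cox_fit(
    table: SurvivalTable,
    covariates: pd.DataFrame,
    standardization: pd.DataFrame | None = None,
) -> CoxResult:
    """Partial-likelihood Cox fit (Efron ties) with Wald p-values.

    A Schoenfeld-residual proportional-hazards check per covariate is
    reported alongside (``ph_p``); violations are flagged by the caller,
    not enforced here.
    """
    df = table.data.merge(
        covariates, left_on="patient_id", right_index=True, how="inner"
    ).dropna()
    if df["event"].sum() < 1:
        raise ValidationError("no events in the analysis table")
    cph = CoxPHFitter()
    try:
        cph.fit(
            df.drop(columns=["patient_id"]), duration_col="time", event_col="event"
        )
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise ValidationError(
            f"Cox model failed to converge on {len(df)} rows "
            f"({int(df['event'].sum())} events): {exc}"
        ) from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ph = proportional_hazard_test(
            cph, df.drop(columns=["patient_id"]), time_transform="rank"
        )
    ph_p = ph.summary["p"]
    if isinstance(ph_p.index, pd.MultiIndex):
        ph_p = ph_p.groupby(level=0).min()
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "wald_p": s["p"],
            "ph_p": ph_p.reindex(s.index),
        }
    )
    return CoxResult(
        summary=summary,
        n=len(df),
        n_events=int(df["event"].sum()),
        log_likelihood=float(cph.log_likelihood_),
        standardization=standardization,
        model=cph,
    )


def hr_rescale(result: CoxResult, covariate: str, unit: float) -> float:
    """Hazard ratio per ``unit`` of a covariate on its raw scale.

    The model was fit on z-scores, so HR_unit = exp(beta_sd * unit / sd_raw).
    """
    if covariate not in result.summary.index:
        raise ValidationError(f"covariate {covariate!r} not in the model")
    if result.standardization is None or covariate not in result.standardization.index:
        raise ValidationError(f"no standardization metadata for {covariate!r}")
    beta = float(result.summary.loc[covariate, "coef"])
    sd_raw = float(result.standardization.loc[covariate, "sd"])
    return float(np.exp(beta * unit / sd_raw))


# ---------------------------------------------------------------------------
# Cox-LASSO stability selection


def _breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Breslow log partial likelihood for each column of a linear-predictor
    matrix.  Used only as the cross-validation deviance criterion."""
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order].astype(bool)
    eta = eta[order]
    shift = eta.max(axis=0, keepdims=True)
    ex = np.exp(eta - shift)
    # reverse cumulative sum -> risk-set sums at each position
    risk = np.cumsum(ex[::-1], axis=0)[::-1]
    # ties: an event at time t uses the risk set of the first index with time t
    first_idx = np.searchsorted(t, t, side="left")
    log_risk = np.log(risk[first_idx]) + shift
    return (eta[e] - log_risk[e]).sum(axis=0)


def _coxnet_path(X: np.ndarray, time: np.ndarray, event: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """LASSO coefficient path over a fixed alpha grid; (p, L) array.

    The underlying solver may stop the path early; remaining columns are
    padded with the last fitted solution.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event.astype(bool), time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=alphas, normalize=False, fit_baseline_model=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coef = np.asarray(model.coef_)
    L = len(alphas)
    if coef.shape[1] < L:
        pad = np.repeat(coef[:, -1:], L - coef.shape[1], axis=1)
        coef = np.hstack([coef, pad])
    return coef


def _alpha_grid(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_alphas: int,
    decades: float,
) -> np.ndarray:
    """Log-spaced grid from the all-zero regularization strength downward."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event.astype(bool), time)
    probe = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=3, alpha_min_ratio=0.5, normalize=False,
        fit_baseline_model=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probe.fit(X, y)
    alpha_max = float(probe.alphas_[0])
    return np.geomspace(alpha_max, alpha_max * 10.0 ** (-decades), n_alphas)


def cox_lasso_stability(
    table: SurvivalTable,
    covariates: pd.DataFrame,
    reps: int = 100,
    folds: int = 10,
    freq_threshold: float = 0.9,
    base_seed: int = 0,
    n_alphas: int = 100,
    alpha_decades: float = 4.0,
) -> StabilityResult:
    """Repeated cross-validated Cox-LASSO variable selection.

    Each repetition r draws a fresh fold assignment (seeded ``base_seed + r``),
    fits the LASSO path on each training split, picks the regularization
    strength minimizing the summed held-out partial-likelihood deviance
    (difference of full-data and training-split Breslow log partial
    likelihoods at the training-split solution), and records which covariates
    have a nonzero coefficient in the full-data path at that strength.  The
    selected set holds covariates whose selection frequency over repetitions
    reaches ``freq_threshold``.
    """
    df = table.data.merge(
        covariates, left_on="patient_id", right_index=True, how="inner"
    ).dropna()
    cols = list(covariates.columns)
    X = df[cols].to_numpy(dtype=float)
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    n = len(df)
    if event.sum() < folds:
        raise ValidationError(
            f"{int(event.sum())} events < {folds} folds; cannot cross-validate"
        )
    alphas = _alpha_grid(X, time, event, n_alphas, alpha_decades)
    full_path = _coxnet_path(X, time, event, alphas)  # (p, L)

    counts = np.zeros(len(cols))
    chosen = np.empty(reps)
    for r in range(reps):
        rng = np.random.default_rng(base_seed + r)
        assign = rng.permutation(np.arange(n) % folds)
        dev = np.zeros(len(alphas))
        for k in range(folds):
            tr = assign != k
            coef = _coxnet_path(X[tr], time[tr], event[tr], alphas)
            ll_full = _breslow_loglik(X @ coef, time, event)
            ll_train = _breslow_loglik(X[tr] @ coef, time[tr], event[tr])
            dev += -2.0 * (ll_full - ll_train)
        best = int(np.argmin(dev))
        chosen[r] = alphas[best]
        counts += full_path[:, best] != 0
    freq = pd.Series(counts / reps, index=cols)
    selected = [c for c in cols if freq[c] >= freq_threshold]
    return StabilityResult(
        selection_frequency=freq,
        selected=selected,
        freq_threshold=freq_threshold,
        reps=reps,
        folds=folds,
        base_seed=base_seed,
        alphas=alphas,
        chosen_alphas=chosen,
    )


# ---------------------------------------------------------------------------
# Risk stratification


def relative_risk(result: CoxResult, covariates: pd.DataFrame) -> pd.Series:
    """Per-patient risk relative to a reference patient at covariate means.

    Covariates are standardized (mean 0), so the reference linear predictor
    is 0 and the reference risk is 1.  Patients with a missing covariate are
    excluded with a warning.
    """
    covs = list(result.summary.index)
    missing = [c for c in covs if c not in covariates.columns]
    if missing:
        raise ValidationError(f"covariates missing from the matrix: {missing}")
    X = covariates[covs]
    incomplete = X.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"excluding {int(incomplete.sum())} patients with missing covariates",
            stacklevel=2,
        )
        X = X[~incomplete]
    beta = result.summary["coef"].to_numpy()
    return pd.Series(np.exp(X.to_numpy() @ beta), index=X.index, name="relative_risk")


def youden_threshold(risks, event_indicators) -> tuple[float, float]:
    """Threshold on risk scores maximizing Youden's J on observed outcomes.

    Candidates are midpoints between consecutive sorted unique risks plus
    the two trivial extremes (everyone high / everyone low, which pin J at
    0); "high" (risk > t) predicts an event; ties in J resolve to the
    smallest threshold.  Returns (threshold, J).
    """
    r = np.asarray(risks, dtype=float)
    e = np.asarray(event_indicators, dtype=int)
    if e.sum() == 0 or e.sum() == e.size:
        raise ValidationError("need at least one event and one non-event")
    uniq = np.unique(r)
    if uniq.size < 2:
        raise ValidationError("no separating threshold: all risks identical")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    half = (uniq[1] - uniq[0]) / 2.0
    cands = np.concatenate([[uniq[0] - half], mids, [uniq[-1] + (uniq[-1] - uniq[-2]) / 2.0]])
    pos, neg = e.sum(), (1 - e).sum()
    best_t, best_j = None, -np.inf
    for t in cands:
        pred = r > t
        sens = (pred & (e == 1)).sum() / pos
        spec = (~pred & (e == 0)).sum() / neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t), float(best_j)


def km_logrank(
    table: SurvivalTable, groups: pd.Series, at_risk_times=None
) -> KMResult:
    """Kaplan-Meier curves and log-rank comparison of patient groups.

    ``groups`` is indexed by patient_id.  Medians are the first time the
    product-limit estimate drops to 0.5 or below (inf when unreached);
    at-risk counts are evaluated on a common time grid.
    """
    df = table.data.set_index("patient_id").join(groups.rename("group"), how="inner")
    labels = sorted(df["group"].dropna().unique())
    if len(labels) < 2:
        raise ValidationError("need at least two non-empty groups")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    medians: dict[str, float] = {}
    curves, at_risk_rows = [], []
    if at_risk_times is None:
        at_risk_times = np.linspace(0, df["time"].max(), 7)
    for g in labels:
        sub = df[df["group"] == g]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(g))
        medians[str(g)] = float(km.median_survival_time_)
        sf = km.survival_function_
        curves.append(
            pd.DataFrame(
                {"group": str(g), "time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
        for t in at_risk_times:
            at_risk_rows.append(
                {"group": str(g), "time": float(t), "n_at_risk": int((sub["time"] >= t).sum())}
            )
    return KMResult(
        statistic=float(res.test_statistic),
        pvalue=float(res.p_value),
        medians=medians,
        curves=pd.concat(curves, ignore_index=True),
        at_risk=pd.DataFrame(at_risk_rows),
    )


# ---------------------------------------------------------------------------
# End-to-end outcome model


def build_covariates(
    patients: list[PatientRecord],
    molecular_metrics: pd.DataFrame,
    clinical_schema: dict[str, str] | None = None,
    molecular_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Assemble the raw (un-imputed) covariate matrix, indexed by patient.

    Base clinical covariates (treatment, ER status, surgical margin) are
    combined with schema-declared extras and the molecular metric columns.
    Returns (matrix, clinical column names, molecular column names) after
    dummy coding, before imputation/standardization.
    """
    clinical_schema = clinical_schema or {}
    rows = {}
    for pt in patients:
        row: dict[str, object] = {
            "treatment": pt.treatment,
            "er_status": pt.er_status if pt.er_status != "unknown" else None,
            "surgical_margin_mm": (
                np.nan if pt.surgical_margin_mm is None else pt.surgical_margin_mm
            ),
        }
        for name in clinical_schema:
            row[name] = pt.covariates.get(name, np.nan)
        rows[pt.patient_id] = row
    clin = pd.DataFrame.from_dict(rows, orient="index")
    categorical = ["treatment", "er_status"] + [
        n for n, kind in clinical_schema.items() if kind == "categorical"
    ]
    clin = dummy_code(clin, categorical)
    clinical_cols = list(clin.columns)

    mol = molecular_metrics.copy()
    if molecular_columns is not None:
        mol = mol[molecular_columns]
    if "patient_id" in mol.columns:
        mol = mol.set_index("patient_id")
    mol_cols = list(mol.columns)
    cov = clin.join(mol, how="left")
    return cov.astype(float), clinical_cols, mol_cols


def run_outcome_model(
    patients: list[PatientRecord],
    molecular_metrics: pd.DataFrame,
    mode: str,
    config: AnalysisConfig | None = None,
    clinical_schema: dict[str, str] | None = None,
    molecular_columns: list[str] | None = None,
    complete_case_variant: bool = True,
) -> OutcomeModelResult:
    """Full endpoint model: selection, refit, stratification, log-rank.

    Pipeline: endpoint construction -> dummy coding -> mean imputation of
    clinical covariates -> complete-case restriction on molecular metrics ->
    standardization -> repeated-CV Cox-LASSO stability selection ->
    unpenalized Cox refit on the selected set -> relative risk -> Youden
    threshold -> Kaplan-Meier / log-rank.  A no-imputation (complete-case)
    sensitivity variant is run alongside unless disabled.
    """
    config = config or AnalysisConfig()
    notes: list[str] = []
    table = prepare_endpoint(patients, mode)
    cov_raw, clinical_cols, mol_cols = build_covariates(
        patients, molecular_metrics, clinical_schema, molecular_columns
    )
    cov_raw = cov_raw.loc[cov_raw.index.intersection(table.data["patient_id"])]

    def _select_and_fit(cov: pd.DataFrame, seed_offset: int):
        complete = cov.dropna()
        if complete.empty:
            raise ValidationError("no patients with complete covariate data")
        z, meta = standardize(complete)
        stability = cox_lasso_stability(
            table,
            z,
            reps=config.lasso_reps,
            folds=config.cv_folds,
            freq_threshold=config.selection_freq_threshold,
            base_seed=config.base_seed + seed_offset,
            n_alphas=config.lasso_n_alphas,
            alpha_decades=config.lasso_alpha_decades,
        )
        if not stability.selected:
            return stability, None, None, meta
        # Final fit uses all patients with data for the selected variables.
        z_sel, meta_sel = standardize(cov[stability.selected].dropna())
        cox = cox_fit(table, z_sel, standardization=meta_sel)
        risks = relative_risk(cox, z_sel)
        merged = table.data.set_index("patient_id").join(risks, how="inner")
        try:
            thr, j = youden_threshold(merged["relative_risk"], merged["event"])
        except ValidationError as exc:
            notes.append(f"stratification skipped: {exc}")
            return stability, cox, None, meta_sel
        grp = pd.Series(
            np.where(merged["relative_risk"] > thr, "high", "low"),
            index=merged.index,
            name="group",
        )
        km = km_logrank(table, grp)
        strat = StratificationResult(
            risks=risks, threshold=thr, youden_j=j, groups=grp, km=km
        )
        return stability, cox, strat, meta_sel

    imputed = mean_impute(cov_raw, clinical_cols, tuple(mol_cols))
    stability, cox, strat, _ = _select_and_fit(imputed, seed_offset=0)
    if cox is None:
        notes.append("selected set empty; stratification skipped")

    cc_stab = cc_cox = None
    if complete_case_variant:
        try:
            cc_stab, cc_cox, _, _ = _select_and_fit(cov_raw, seed_offset=0)
        except ValidationError as exc:
            notes.append(f"complete-case variant unavailable: {exc}")
    return OutcomeModelResult(
        mode=mode,
        table=table,
        stability=stability,
        cox=cox,
        stratification=strat,
        complete_case_stability=cc_stab,
        complete_case_cox=cc_cox,
        notes=notes,
    )
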