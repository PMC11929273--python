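"""Endpoint construction, Cox machinery, stability selection, stratification."""

import math

import numpy as np
import pandas as pd
import pytest

from dcisith.survival import (
    SurvivalTable,
    cox_fit,
    cox_lasso_stability,
    hr_rescale,
    km_logrank,
    mean_impute,
    dummy_code,
    prepare_endpoint,
    relative_risk,
    reverse_km_median_followup,
    run_outcome_model,
    standardize,
    youden_threshold,
)
from dcisith.types import AnalysisConfig, PatientRecord, ValidationError

from conftest import brute_force_youden


def _rows(table):
    return set(
        table.data[["patient_id", "time", "event"]].itertuples(index=False, name=None)
    )


class TestPrepareEndpoint:
    def _mini(self):
        return [
            PatientRecord("N", "nonrecurrent", ("a", "b"), outcome_time=80.0),
            PatientRecord(
                "R", "recurrent", ("c", "d"), outcome_time=30.0,
                outcome_event="dcis_recurrence",
            ),
            PatientRecord(
                "G", "progressor", ("e", "f"), outcome_time=50.0,
                outcome_event="progression",
            ),
        ]

    def test_progression_discards_recurrents(self):
        t = prepare_endpoint(self._mini(), "progression")
        assert _rows(t) == {("N", 80.0, 0), ("G", 50.0, 1)}
        assert t.excluded == ["R"]

    def test_progression_censor_recurrents(self):
        t = prepare_endpoint(self._mini(), "progression_censor_recurrents")
        assert _rows(t) == {("N", 80.0, 0), ("R", 30.0, 0), ("G", 50.0, 1)}
        assert t.excluded == []

    def test_any_recurrence_unions_events(self):
        t = prepare_endpoint(self._mini(), "any_recurrence")
        assert _rows(t) == {("N", 80.0, 0), ("R", 30.0, 1), ("G", 50.0, 1)}

    def test_recurrence_discards_progressors(self):
        t = prepare_endpoint(self._mini(), "recurrence")
        assert _rows(t) == {("N", 80.0, 0), ("R", 30.0, 1)}
        assert t.excluded == ["G"]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            prepare_endpoint(self._mini(), "overall")

    def test_conservation_across_modes(self, nine_patient_cohort):
        ids = {p.patient_id for p in nine_patient_cohort}
        for mode in ("recurrence", "progression"):
            t = prepare_endpoint(nine_patient_cohort, mode)
            assert set(t.data["patient_id"]) | set(t.excluded) == ids
            assert set(t.data["patient_id"]) & set(t.excluded) == set()


class TestReverseKm:
    def test_all_censored_at_same_time(self):
        assert reverse_km_median_followup([60, 60, 60], [0, 0, 0]) == 60

    def test_no_censoring_unreached(self):
        assert math.isinf(reverse_km_median_followup([10, 20, 30], [1, 1, 1]))

    def test_recovers_censoring_distribution_median(self):
        rng = np.random.default_rng(20)
        n = 600
        c = rng.uniform(60, 174, n)  # median 117
        t_event = rng.exponential(400, n)
        t = np.minimum(c, t_event)
        e = (t_event <= c).astype(int)
        got = reverse_km_median_followup(t, e)
        assert got == pytest.approx(117, rel=0.08)


class TestCovariatePrep:
    def test_mean_impute_column(self):
        cov = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        out = mean_impute(cov, ["a"])
        assert out["a"].tolist() == [1.0, 2.0, 3.0]

    def test_no_missingness_identity(self):
        cov = pd.DataFrame({"a": [1.0, 2.0]})
        pd.testing.assert_frame_equal(mean_impute(cov, ["a"]), cov)

    def test_molecular_guard(self):
        cov = pd.DataFrame({"snv_burden": [1.0, np.nan]})
        with pytest.raises(ValidationError, match="molecular"):
            mean_impute(cov, ["snv_burden"], molecular_columns=("snv_burden",))

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError, match="entirely missing"):
            mean_impute(pd.DataFrame({"a": [np.nan, np.nan]}), ["a"])

    def test_dummy_code_propagates_missingness(self):
        cov = pd.DataFrame({"t": ["x", "y", None, "z"]})
        out = dummy_code(cov, ["t"])
        assert set(out.columns) == {"t_y", "t_z"}  # reference level dropped
        assert out.loc[2].isna().all()

    def test_standardize_closed_form(self):
        z, meta = standardize(pd.DataFrame({"a": [0.0, 10.0]}))
        assert z["a"].tolist() == pytest.approx([-0.7071067, 0.7071067])
        assert meta.loc["a", "sd"] == pytest.approx(np.std([0, 10], ddof=1))

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _ = standardize(pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 1.0]}))
        assert list(z.columns) == ["b"]


def _sim_survival(n, beta, seed, p=1, censor=(30.0, 200.0)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    lph = X @ np.full(p, beta) if p == 1 else X @ np.r_[beta, np.zeros(p - 1)]
    T = 100 * rng.exponential(size=n) ** (1 / 1.3) * np.exp(-lph / 1.3)
    C = rng.uniform(*censor, n)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    df = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)], "time": t, "event": e})
    X = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)], index=df["patient_id"])
    Xz = (X - X.mean()) / X.std(ddof=1)
    return SurvivalTable("recurrence", df), Xz


class TestCoxFit:
    def test_duplicating_rows_leaves_beta_essentially_unchanged(self):
        # exact invariance holds for Breslow ties; with Efron handling the
        # duplicated (now tied) events perturb the estimate only at O(1e-3)
        table, X = _sim_survival(80, 0.5, 21)
        res1 = cox_fit(table, X)
        dup = SurvivalTable(
            table.mode, pd.concat([table.data] * 2, ignore_index=True)
        )
        res2 = cox_fit(dup, X)
        assert res2.summary.loc["x0", "coef"] == pytest.approx(
            res1.summary.loc["x0", "coef"], abs=0.02
        )

    def test_no_events_rejected(self):
        table, X = _sim_survival(30, 0.0, 22)
        table.data["event"] = 0
        with pytest.raises(ValidationError):
            cox_fit(table, X)

    def test_recovers_generating_coefficient(self):
        # Weibull PH with beta per SD; Wald CI should cover at n = 400
        table, X = _sim_survival(400, 0.5, 23)
        res = cox_fit(table, X)
        assert res.summary.loc["x0", "hr_lower"] < np.exp(0.5) < res.summary.loc["x0", "hr_upper"]
        assert res.summary.loc["x0", "wald_p"] < 0.01
        assert {"ph_p"} <= set(res.summary.columns)

    def test_hr_rescale_closed_form(self):
        table, X = _sim_survival(120, 0.5, 24)
        meta = pd.DataFrame({"mean": [5.0], "sd": [20.0]}, index=["x0"])
        res = cox_fit(table, X, standardization=meta)
        beta = res.summary.loc["x0", "coef"]
        assert hr_rescale(res, "x0", 10.0) == pytest.approx(np.exp(beta * 10 / 20))
        assert hr_rescale(res, "x0", 20.0) == pytest.approx(np.exp(beta))
        assert hr_rescale(res, "x0", 0.0) == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            hr_rescale(res, "nope", 1.0)


class TestRelativeRisk:
    def test_reference_patient_risk_one(self):
        table, X = _sim_survival(100, 0.5, 25)
        res = cox_fit(table, X)
        risks = relative_risk(res, X)
        beta = res.summary.loc["x0", "coef"]
        assert np.exp(np.log(risks).mean()) == pytest.approx(
            np.exp(beta * X["x0"].mean()), abs=1e-6
        )
        # a patient exactly at the mean has risk 1
        X0 = pd.DataFrame({"x0": [0.0]}, index=["ref"])
        assert relative_risk(res, X0).iloc[0] == pytest.approx(1.0)

    def test_one_sd_patient(self):
        table, X = _sim_survival(100, 0.5, 26)
        res = cox_fit(table, X)
        res.summary.loc["x0", "coef"] = np.log(2.0)
        X1 = pd.DataFrame({"x0": [1.0]}, index=["p"])
        assert relative_risk(res, X1).iloc[0] == pytest.approx(2.0)

    def test_missing_covariates_excluded_with_warning(self):
        table, X = _sim_survival(50, 0.5, 27)
        res = cox_fit(table, X)
        X2 = X.copy()
        X2.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="excluding"):
            risks = relative_risk(res, X2)
        assert len(risks) == len(X2) - 1


class TestYouden:
    def test_perfect_separation(self):
        thr, j = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5) and j == pytest.approx(1.0)

    def test_anti_informative_tie_rule(self):
        # J = 0 is attainable only at the trivial extremes; the smallest
        # maximizing threshold (everyone predicted high) is returned
        thr, j = youden_threshold([0.1, 0.9], [1, 0])
        assert j == pytest.approx(0.0)
        assert thr < 0.1

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(28)
        for _ in range(30):
            risks = rng.choice(np.round(rng.random(12), 2), 40)
            events = rng.integers(0, 2, 40)
            if events.sum() in (0, 40) or len(np.unique(risks)) < 2:
                continue
            thr, j = youden_threshold(risks, events)
            _, j_oracle = brute_force_youden(risks, events)
            assert j == pytest.approx(j_oracle)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            youden_threshold([0.5, 0.5], [0, 1])
        with pytest.raises(ValidationError):
            youden_threshold([0.1, 0.9], [1, 1])


class TestKmLogrank:
    def test_identical_groups_null(self):
        table, _ = _sim_survival(40, 0.0, 29)
        dup = SurvivalTable(
            table.mode,
            pd.concat(
                [
                    table.data.assign(patient_id=table.data["patient_id"] + "_a"),
                    table.data.assign(patient_id=table.data["patient_id"] + "_b"),
                ],
                ignore_index=True,
            ),
        )
        groups = pd.Series(
            ["g1"] * 40 + ["g2"] * 40,
            index=dup.data["patient_id"],
        )
        res = km_logrank(dup, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_six_patient_logrank(self):
        # events at distinct times 1..4 in group A, censoring later in B
        data = pd.DataFrame(
            {
                "patient_id": list("abcdef"),
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 1, 1, 0, 0],
            }
        )
        groups = pd.Series(["A"] * 4 + ["B"] * 2, index=data["patient_id"])
        # hypergeometric ledger: at t=1 O-E = 1-4/6; t=2: 1-3/5; t=3: 1-2/4; t=4: 1-1/3
        o_minus_e = (1 - 4 / 6) + (1 - 3 / 5) + (1 - 2 / 4) + (1 - 1 / 3)
        var = (
            (4 / 6) * (2 / 6)
            + (3 / 5) * (2 / 5)
            + (2 / 4) * (2 / 4)
            + (1 / 3) * (2 / 3)
        )
        expected = o_minus_e**2 / var
        res = km_logrank(SurvivalTable("recurrence", data), groups)
        assert res.statistic == pytest.approx(expected)
        assert res.medians["A"] == pytest.approx(2.0)

    def test_no_events_flat_curves(self):
        data = pd.DataFrame(
            {"patient_id": list("abcd"), "time": [5.0, 6, 7, 8], "event": [0, 0, 0, 0]}
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=data["patient_id"])
        res = km_logrank(SurvivalTable("recurrence", data), groups)
        assert all(math.isinf(m) for m in res.medians.values())
        assert (res.curves["survival"] == 1.0).all()

    def test_single_group_rejected(self):
        data = pd.DataFrame({"patient_id": ["a", "b"], "time": [1.0, 2], "event": [1, 0]})
        with pytest.raises(ValidationError):
            km_logrank(
                SurvivalTable("recurrence", data),
                pd.Series(["g", "g"], index=data["patient_id"]),
            )


class TestStabilitySelection:
    def test_single_rep_equals_single_run(self):
        table, X = _sim_survival(150, 0.8, 30, p=4)
        res = cox_lasso_stability(
            table, X, reps=1, folds=5, freq_threshold=0.9, base_seed=0, n_alphas=30
        )
        assert set(res.selected) == set(
            res.selection_frequency[res.selection_frequency >= 0.9].index
        )
        assert res.selection_frequency.isin([0.0, 1.0]).all()

    def test_bit_reproducible_given_seed(self):
        table, X = _sim_survival(150, 0.8, 31, p=4)
        r1 = cox_lasso_stability(table, X, reps=5, folds=5, base_seed=7, n_alphas=30)
        r2 = cox_lasso_stability(table, X, reps=5, folds=5, base_seed=7, n_alphas=30)
        pd.testing.assert_series_equal(r1.selection_frequency, r2.selection_frequency)
        assert np.array_equal(r1.chosen_alphas, r2.chosen_alphas)

    def test_strong_signal_always_selected(self):
        table, X = _sim_survival(250, 0.9, 32, p=6)
        res = cox_lasso_stability(table, X, reps=10, folds=10, base_seed=0, n_alphas=40)
        assert res.selection_frequency["x0"] >= 0.9
        assert "x0" in res.selected

    def test_fewer_events_than_folds_rejected(self):
        table, X = _sim_survival(30, 0.0, 33)
        table.data.loc[table.data.index[:27], "event"] = 0
        with pytest.raises(ValidationError, match="folds"):
            cox_lasso_stability(table, X, reps=1, folds=10)


class TestRunOutcomeModel:
    def _cohort_frame(self, nine_patient_cohort):
        rng = np.random.default_rng(34)
        feats = pd.DataFrame(
            {"snv_burden": rng.normal(20, 5, 9), "snv_divergence": rng.normal(30, 8, 9)},
            index=[p.patient_id for p in nine_patient_cohort],
        )
        return feats

    def test_complete_data_variants_identical(self, nine_patient_cohort):
        # with no missingness, the imputed and complete-case pipelines agree
        rng = np.random.default_rng(35)
        patients = []
        for i in range(40):
            cohort = ["nonrecurrent", "recurrent"][i % 2]
            patients.append(
                PatientRecord(
                    f"P{i}",
                    cohort,
                    (f"P{i}a", f"P{i}b"),
                    outcome_time=float(rng.uniform(20, 120)),
                    outcome_event="none" if cohort == "nonrecurrent" else "dcis_recurrence",
                    treatment="mastectomy",
                    er_status="pos" if i % 3 else "neg",
                    surgical_margin_mm=float(rng.gamma(2, 1.5)),
                )
            )
        feats = pd.DataFrame(
            {"snv_burden": rng.normal(20, 5, 40)},
            index=[p.patient_id for p in patients],
        )
        cfg = AnalysisConfig(lasso_reps=3, cv_folds=5, lasso_n_alphas=25, base_seed=0)
        res = run_outcome_model(patients, feats, "recurrence", cfg)
        pd.testing.assert_series_equal(
            res.stability.selection_frequency,
            res.complete_case_stability.selection_frequency,
        )

    def test_empty_selection_reported(self, nine_patient_cohort):
        feats = self._cohort_frame(nine_patient_cohort)
        cfg = AnalysisConfig(lasso_reps=2, cv_folds=3, lasso_n_alphas=20, base_seed=1)
        res = run_outcome_model(
            nine_patient_cohort, feats, "recurrence", cfg, complete_case_variant=False
        )
        if not res.stability.selected:
            assert res.cox is None and res.stratification is None
            assert any("empty" in n for n in res.notes)
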