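"""Stepwise selection, by-subject splitting, and SVM kernel comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cardiowalk import models as md
from cardiowalk import synthdata as sd
from cardiowalk.errors import ConfigurationError, InsufficientDataError


def known_truth_table(seed, noise_sd=40.0, n_noise=3):
    """Cohort whose outcome is affine in chronotropic response and effort."""
    config = sd.CohortConfig(
        rng_seed=seed, outcome_noise_sd=noise_sd, patient_effect_sd=0.0,
        coef_chronotropic=2.0, coef_effort=20.0,
    )
    truth = sd.simulate_cohort_truth(config)
    table = sd.truth_to_feature_table(truth)
    rng = np.random.default_rng(10_000 + seed)
    for j in range(n_noise):
        table[f"noise{j}"] = rng.normal(size=len(table))
    return config, truth, table


CANDIDATES = ["chronotropic_response", "effort_total", "noise0", "noise1", "noise2"]


class TestStepwise:
    def test_recovers_true_predictors_and_coefficients(self):
        config, truth, table = known_truth_table(seed=0)
        report = md.fit_stepwise_linear(table, candidates=CANDIDATES)
        assert set(report.selected_features) == {"chronotropic_response", "effort_total"}
        # coefficients within 3 simulation standard errors of the design values
        assert report.coefficients["chronotropic_response"] == pytest.approx(2.0, abs=0.5)
        assert report.coefficients["effort_total"] == pytest.approx(20.0, abs=3.0)
        signal = 2.0 * truth["chronotropic_true"] + 20.0 * truth["effort_scale_true"]
        design_r2 = signal.var() / (signal.var() + 40.0**2)
        assert report.r_squared == pytest.approx(design_r2, abs=0.05)
        assert report.rmse > 0

    def test_duplicated_predictor_enters_once(self):
        _, _, table = known_truth_table(seed=1, n_noise=0)
        table["cr_copy"] = table["chronotropic_response"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = md.fit_stepwise_linear(
                table, candidates=["chronotropic_response", "cr_copy", "effort_total"]
            )
        assert ("chronotropic_response" in report.selected_features) != (
            "cr_copy" in report.selected_features
        )

    def test_rows_with_missing_outcome_excluded(self):
        _, _, table = known_truth_table(seed=2, n_noise=0)
        table.loc[:9, "six_mwd_measured"] = np.nan
        report = md.fit_stepwise_linear(table, candidates=["chronotropic_response"])
        assert report.n_rows == len(table) - 10

    def test_too_few_rows_rejected(self):
        _, _, table = known_truth_table(seed=3, n_noise=0)
        with pytest.raises(InsufficientDataError):
            md.fit_stepwise_linear(table.head(5), candidates=["chronotropic_response"])


class TestSplit:
    def test_default_cohort_split_counts(self, feature_table):
        train, test = md.split_by_subject(feature_table, 0.8, seed=0)
        assert len(train) == 71 and len(test) == 18

    def test_reproducible_and_partitioning(self, feature_table):
        a = md.split_by_subject(feature_table, 0.8, seed=7)
        b = md.split_by_subject(feature_table, 0.8, seed=7)
        assert a == b
        train, test = a
        patients = set(feature_table["patient_id"])
        assert set(train) | set(test) == patients
        assert not set(train) & set(test)

    def test_bad_fraction_rejected(self, feature_table):
        with pytest.raises(ConfigurationError):
            md.split_by_subject(feature_table, 1.2, seed=0)


class TestSVM:
    def test_linear_kernel_recovers_linear_map(self):
        config = sd.CohortConfig(
            rng_seed=3, outcome_noise_sd=0.0, patient_effect_sd=0.0, coef_effort=0.0
        )
        table = sd.truth_to_feature_table(sd.simulate_cohort_truth(config))
        train_ids, test_ids = md.split_by_subject(table, 0.8, seed=2)
        pred = md.fit_svm(
            table[table.patient_id.isin(train_ids)], ["chronotropic_response"], "linear"
        )
        test = table[table.patient_id.isin(test_ids)]
        mae = np.mean(np.abs(pred.predict(test) - test["six_mwd_measured"]))
        assert mae < 5.0

    def test_train_rows_inside_epsilon_tube(self):
        config = sd.CohortConfig(
            rng_seed=4, outcome_noise_sd=0.0, patient_effect_sd=0.0, coef_effort=0.0
        )
        table = sd.truth_to_feature_table(sd.simulate_cohort_truth(config))
        pred = md.fit_svm(table, ["chronotropic_response"], "linear")
        resid = np.abs(pred.predict(table) - table["six_mwd_measured"])
        assert np.max(resid) <= pred.epsilon * 1.05 + 1e-6

    def test_duplicated_rows_leave_predictor_stable(self):
        _, _, table = known_truth_table(seed=5, n_noise=0)
        doubled = pd.concat([table, table], ignore_index=True)
        doubled["session_index"] = np.arange(len(doubled))  # keep keys unique
        p1 = md.fit_svm(table, ["chronotropic_response", "effort_total"], "linear")
        p2 = md.fit_svm(doubled, ["chronotropic_response", "effort_total"], "linear")
        probe = table.head(50)
        np.testing.assert_allclose(p1.predict(probe), p2.predict(probe), atol=2.0)

    def test_constant_feature_dropped_with_warning(self):
        _, _, table = known_truth_table(seed=6, n_noise=0)
        table["flat"] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            pred = md.fit_svm(table, ["chronotropic_response", "flat"], "linear")
        assert pred.feature_names == ["chronotropic_response"]

    def test_standardization_uses_train_statistics_only(self):
        _, _, table = known_truth_table(seed=7, n_noise=0)
        train_ids, test_ids = md.split_by_subject(table, 0.8, seed=1)
        tr = table[table.patient_id.isin(train_ids)]
        te = table[table.patient_id.isin(test_ids)].copy()
        pred = md.fit_svm(tr, ["chronotropic_response"], "linear")
        base = pred.predict(te)
        te_shift = te.copy()
        te_shift["chronotropic_response"] += 10.0
        # shifting test features changes predictions...
        assert not np.allclose(pred.predict(te_shift), base)
        # ...but never the train-side standardization or the fitted model
        pred2 = md.fit_svm(tr, ["chronotropic_response"], "linear")
        np.testing.assert_array_equal(pred.scaler.mean_, pred2.scaler.mean_)
        np.testing.assert_allclose(pred2.predict(te), base)


class TestKernelComparison:
    def test_grid_has_all_cells_and_disjoint_splits(self, feature_table):
        report = md.run_kernel_comparison(feature_table, n_repeats=2, seed=0)
        assert len(report.cells) == 6 * 5
        assert not report.cells["failed"].any()
        for rep, test_ids in report.test_patients.items():
            assert len(test_ids) == 18

    def test_adding_chronotropic_to_effort_reduces_mae(self):
        # both channels carry independent signal by construction
        _, _, table = known_truth_table(seed=8, noise_sd=10.0, n_noise=0)
        report = md.run_kernel_comparison(
            table,
            feature_sets={
                "effort": ["effort_total"],
                "effort+cr": ["effort_total", "chronotropic_response"],
            },
            kernels=("rbf",),
            n_repeats=5,
            seed=3,
        )
        assert (
            report.cell("effort+cr", "rbf").mae_mean
            < report.cell("effort", "rbf").mae_mean
        )

    def test_rbf_beats_linear_on_saturating_cohort(self):
        config = sd.CohortConfig(rng_seed=11)
        table = sd.apply_saturating_outcome(
            sd.truth_to_feature_table(sd.simulate_cohort_truth(config)), seed=11
        )
        report = md.run_kernel_comparison(
            table,
            feature_sets={"effort": ["effort_total"]},
            kernels=("rbf", "linear"),
            n_repeats=5,
            seed=5,
        )
        per = report.per_repeat.pivot(index="repeat", columns="kernel", values="mae")
        assert (per["rbf"] < per["linear"]).sum() >= 4
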