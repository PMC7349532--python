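"""Biomarker extraction: RR cleaning, local HR, HR parameters, effort."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiowalk import features as ft
from cardiowalk import synthdata as sd
from cardiowalk.errors import InsufficientDataError
from cardiowalk.session_io import PhaseTimes

from conftest import make_noise_free_params

RECOVERY_LOG = math.log(1.0 / (1.0 - ft.RECOVERY_FRACTION))  # ln(1/0.334)


def dense_local_hr_oracle(r_peaks, t_range, bin_width, dt=0.0001):
    """Brute-force reference: sample the RR step function on a dense grid."""
    p = np.asarray(r_peaks)
    rates = 60.0 / np.diff(p)
    grid = np.arange(t_range[0] + dt / 2, t_range[1], dt)
    idx = np.clip(np.searchsorted(p, grid, side="right") - 1, 0, len(rates) - 1)
    hr = rates[idx]
    n_bins = int(round((t_range[1] - t_range[0]) / bin_width))
    per_bin = len(grid) // n_bins
    return hr[: per_bin * n_bins].reshape(n_bins, per_bin).mean(axis=1)


class TestCleanRR:
    def test_regular_rr_untouched(self):
        peaks = np.arange(0.0, 30.0, 1.0)
        cleaned, n = ft.clean_rr(peaks)
        assert n == 0
        np.testing.assert_array_equal(cleaned, peaks)

    def test_single_ectopic_excised_exactly(self):
        peaks = np.arange(0.0, 21.0, 1.0)
        peaks[10] = 9.6  # early beat: 0.6 s / 1.4 s interval pair
        cleaned, n = ft.clean_rr(peaks)
        assert n == 1
        assert 9.6 not in cleaned
        np.testing.assert_array_equal(cleaned, np.delete(peaks, 10))

    def test_idempotent(self):
        peaks = np.arange(0.0, 21.0, 1.0)
        peaks[10] = 9.6
        once, _ = ft.clean_rr(peaks)
        twice, n2 = ft.clean_rr(once)
        assert n2 == 0
        np.testing.assert_array_equal(once, twice)

    def test_isolated_long_interval_left_alone(self):
        # a dropout produces one long interval with no beat to remove
        peaks = np.delete(np.arange(0.0, 30.0, 1.0), 15)
        cleaned, n = ft.clean_rr(peaks)
        assert n == 0 and len(cleaned) == len(peaks)

    def test_too_few_beats(self):
        with pytest.raises(InsufficientDataError):
            ft.clean_rr(np.array([0.0, 1.0]))


class TestLocalHR:
    @pytest.mark.parametrize("rr,expected", [(1.0, 60.0), (0.5, 120.0)])
    def test_constant_rr_exact(self, rr, expected):
        peaks = np.arange(0.0, 960.0 + rr, rr)
        local = ft.compute_local_hr(peaks)
        assert len(local.hr) == 6400
        np.testing.assert_allclose(local.hr, expected, atol=1e-9)

    def test_alternating_rr_matches_dense_integration(self):
        rr = np.tile([0.5, 1.0], 40)
        peaks = np.concatenate([[0.0], np.cumsum(rr)])
        t_range = (0.0, 54.0)
        local = ft.compute_local_hr(peaks, t_range)
        oracle = dense_local_hr_oracle(peaks, t_range, local.bin_width)
        assert np.max(np.abs(local.hr - oracle)) < 0.1

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_random_rr_matches_dense_integration(self, seed):
        rng = np.random.default_rng(seed)
        rr = rng.uniform(0.4, 1.6, size=80)
        peaks = np.concatenate([[0.0], np.cumsum(rr)])
        t_range = (0.0, float(int(peaks[-1] / 0.15) * 0.15))
        local = ft.compute_local_hr(peaks, t_range)
        oracle = dense_local_hr_oracle(peaks, t_range, local.bin_width)
        assert np.max(np.abs(local.hr - oracle)) < 0.1

    def test_too_few_beats(self):
        with pytest.raises(InsufficientDataError):
            ft.compute_local_hr(np.array([100.0]))


class TestHRFeatures:
    def test_constant_hr(self):
        peaks = np.arange(0.0, 961.0, 60.0 / 70.0)
        h = ft.compute_hr_features(ft.compute_local_hr(peaks))
        assert h.hr_rest == pytest.approx(70.0, abs=1e-6)
        assert h.hr_max == pytest.approx(70.0, abs=1e-6)
        assert h.hr_avg == pytest.approx(70.0, abs=1e-6)
        assert h.chronotropic_response == pytest.approx(0.0, abs=1e-6)
        assert h.time_to_recuperation == 0.0 and h.recuperation_reached

    def test_simulated_session_chronotropic(self):
        # plateau effectively reached well before the last 2 min of the walk
        params = make_noise_free_params(rise_tau=30.0)
        peaks = sd.simulate_r_peaks(sd.simulate_hr_profile(params), params, seed=0)
        h = ft.compute_hr_features(ft.compute_local_hr(peaks))
        assert h.chronotropic_response == pytest.approx(50.0, abs=0.5)
        assert 0.0 <= h.time_to_hr_max <= 360.0

    @pytest.mark.parametrize("tau", [30.0, 60.0, 120.0])
    def test_recuperation_matches_exponential_closed_form(self, tau):
        params = make_noise_free_params(rise_tau=30.0, recovery_tau=tau)
        peaks = sd.simulate_r_peaks(sd.simulate_hr_profile(params), params, seed=1)
        h = ft.compute_hr_features(ft.compute_local_hr(peaks))
        expected = tau * RECOVERY_LOG - ft.RECUPERATION_DELAY
        tol = max(1.0, 2.0 * ft.DEFAULT_BIN_WIDTH)
        assert h.time_to_recuperation == pytest.approx(expected, abs=tol)

    def test_recuperation_not_reached_is_flagged(self):
        # recovery so slow the threshold is never crossed before record end
        params = make_noise_free_params(rise_tau=30.0, recovery_tau=2000.0)
        peaks = sd.simulate_r_peaks(sd.simulate_hr_profile(params), params, seed=2)
        h = ft.compute_hr_features(ft.compute_local_hr(peaks))
        assert not h.recuperation_reached
        assert math.isnan(h.time_to_recuperation)

    def test_monotone_in_plateau(self):
        crs = []
        for plateau in (100.0, 115.0, 130.0, 145.0):
            params = make_noise_free_params(hr_plateau=plateau, rise_tau=30.0)
            peaks = sd.simulate_r_peaks(sd.simulate_hr_profile(params), params, seed=3)
            h = ft.compute_hr_features(ft.compute_local_hr(peaks))
            crs.append(h.chronotropic_response)
        assert np.all(np.diff(crs) > 0)


class TestEffort:
    def test_unit_samples_literal_sum(self):
        accel = pd.DataFrame(
            {"t": np.arange(10) / 32.0, "x": 1.0, "y": 0.0, "z": 0.0}
        )
        assert ft.compute_effort(accel, (0.0, 1.0), demean=False) == 10.0

    def test_zero_signal(self):
        accel = pd.DataFrame({"t": np.arange(10) / 32.0, "x": 0.0, "y": 0.0, "z": 0.0})
        assert ft.compute_effort(accel, (0.0, 1.0), demean=False) == 0.0

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        n = 3840
        accel = pd.DataFrame(
            {
                "t": np.arange(n) / 32.0,
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "z": rng.normal(size=n),
            }
        )
        fast = ft.compute_effort(accel, (0.0, 120.0), demean=False)
        slow = sum(
            accel.x[k] ** 2 + accel.y[k] ** 2 + accel.z[k] ** 2 for k in range(n)
        )
        assert fast == pytest.approx(slow, rel=1e-9)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(1)
        accel = pd.DataFrame(
            {"t": np.arange(64) / 32.0, "x": rng.normal(size=64), "y": 0.0, "z": 1.0}
        )
        shuffled = accel.sample(frac=1.0, random_state=2).reset_index(drop=True)
        a = ft.compute_effort(accel, (0.0, 2.0), demean=False)
        b = ft.compute_effort(shuffled, (0.0, 2.0), demean=False)
        assert a == pytest.approx(b, rel=1e-12)

    def test_windowed_efforts_sum_to_total(self, noise_free_session):
        fv = ft.extract_features(noise_free_session)
        total = fv.effort_win1 + fv.effort_win2 + fv.effort_win3
        assert total == pytest.approx(fv.effort_total, rel=1e-12)

    def test_empty_window_rejected(self):
        accel = pd.DataFrame({"t": [0.0], "x": [0.0], "y": [0.0], "z": [0.0]})
        with pytest.raises(InsufficientDataError):
            ft.compute_effort(accel, (10.0, 11.0))


class TestExtractFeatures:
    def test_noise_free_session_recovers_truth(self, noise_free_session):
        fv = ft.extract_features(noise_free_session)
        assert fv.hr_rest == pytest.approx(70.0, abs=1.0)
        assert fv.hr_max == pytest.approx(120.0, abs=1.0)
        assert fv.chronotropic_response == pytest.approx(50.0, abs=1.0)
        assert fv.n_artifacts_removed == 0
        assert fv.six_mwd_measured == 420.0

    def test_chronotropic_identity(self, small_cohort):
        _, recordings, _ = small_cohort
        for rec in recordings[:10]:
            fv = ft.extract_features(rec)
            assert fv.chronotropic_response == pytest.approx(
                fv.hr_max - fv.hr_rest, abs=1e-12
            )

    def test_deterministic(self, noise_free_session):
        assert ft.extract_features(noise_free_session) == ft.extract_features(
            noise_free_session
        )

    def test_cohort_extraction_table(self, small_cohort):
        _, recordings, _ = small_cohort
        table = ft.extract_cohort(recordings)
        assert len(table) == len(recordings)
        assert list(table.columns) == ft.FEATURE_COLUMNS
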