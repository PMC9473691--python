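import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_roi_mean
from nmquant import AcquisitionMeta, MovieStack, StimulusWindow
from nmquant.assays import CellRecord
from nmquant.kinetics import (
    KineticsResult,
    ROISpec,
    Trace,
    aggregate_neuromast,
    classify_activity,
    compute_kinetics,
    estimate_baseline_noise,
    extract_trace,
    resting_intensity,
    um_to_pixels,
)
from nmquant.movie_prep import prep_pipeline, project_z
from nmquant.synthetic import make_movie_truth, simulate_functional_movie


class TestRoiGeometry:
    def test_presynaptic_roi_is_12_pixels(self):
        assert um_to_pixels(3.3, 268.0) == 12

    def test_bundle_roi_is_6_pixels(self):
        assert um_to_pixels(1.7, 268.0) == 6

    def test_one_pixel_unit_case(self):
        assert um_to_pixels(0.268, 268.0) == 1

    def test_minimum_is_one_pixel(self):
        assert um_to_pixels(0.01, 268.0) == 1

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            um_to_pixels(0.0, 268.0)
        with pytest.raises(ValueError):
            um_to_pixels(3.3, -1.0)

    @given(
        d1=st.floats(min_value=0.1, max_value=20.0),
        d2=st.floats(min_value=0.1, max_value=20.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_nondecreasing_in_diameter(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert um_to_pixels(lo, 268.0) <= um_to_pixels(hi, 268.0)


def _flat_movie(frame, n_t=3):
    data = np.broadcast_to(frame, (n_t, 1, *frame.shape)).copy()
    meta = AcquisitionMeta(n_planes=1, frame_rate_hz=10.0)
    return MovieStack(data, meta)


class TestExtractTrace:
    def test_uniform_frame_gives_frame_value(self):
        movie = _flat_movie(np.full((32, 32), 7.5))
        roi = ROISpec((16.0, 16.0), 3.3)
        trace = extract_trace(movie, roi)
        np.testing.assert_allclose(trace.values, 7.5)

    def test_half_and_half_roi_averages_to_midpoint(self):
        frame = np.zeros((33, 33))
        frame[:, 17:] = 10.0  # split through pixel column 16.5
        movie = _flat_movie(frame)
        roi = ROISpec((16.0, 16.5), 3.3)  # centered on the boundary
        trace = extract_trace(movie, roi)
        oracle = brute_force_roi_mean(frame, (16.0, 16.5), roi.diameter_px)
        assert trace.values[0] == pytest.approx(oracle, abs=1e-12)
        assert trace.values[0] == pytest.approx(5.0)

    def test_roi_at_border_rejected(self):
        movie = _flat_movie(np.ones((32, 32)))
        with pytest.raises(ValueError, match="outside"):
            extract_trace(movie, ROISpec((0.0, 16.0), 3.3))

    @pytest.mark.parametrize("center", [(10.0, 10.0), (15.5, 20.0), (24.3, 9.7)])
    @pytest.mark.parametrize("diameter_um", [1.7, 3.3])
    def test_matches_brute_force_enumeration_exactly(self, center, diameter_um):
        rng = np.random.default_rng(42)
        frame = rng.uniform(0, 100, size=(36, 36))
        movie = _flat_movie(frame, n_t=1)
        roi = ROISpec(center, diameter_um)
        trace = extract_trace(movie, roi)
        oracle = brute_force_roi_mean(frame, center, roi.diameter_px)
        assert trace.values[0] == pytest.approx(oracle, abs=0)


class TestComputeKinetics:
    @staticmethod
    def _transient_trace(peak=1.0, rise_s=0.5, halflife=1.0, f0=100.0,
                         onset=2.0, dt=0.1, total=10.0):
        t = np.arange(0.0, total, dt)
        dff = np.zeros_like(t)
        t_peak = onset + rise_s
        rising = (t >= onset) & (t <= t_peak)
        dff[rising] = peak * (t[rising] - onset) / rise_s
        decay = t > t_peak
        dff[decay] = peak * np.exp2(-(t[decay] - t_peak) / halflife)
        stim = StimulusWindow(onset_s=onset, duration_s=0.5)
        return Trace(f0 * (1 + dff), t, kind="raw", stimulus=stim), stim, f0

    def test_closed_form_transient_metrics(self):
        trace, stim, f0 = self._transient_trace()
        res = compute_kinetics(trace, stim, f0)
        assert res.peak_dff == pytest.approx(1.0, abs=1e-12)
        assert res.duration_s == pytest.approx(0.5, abs=1e-12)
        assert res.slope_per_s == pytest.approx(2.0, abs=1e-9)
        assert res.halflife_s == pytest.approx(1.0, abs=1e-3)

    def test_pure_exponential_fit_is_machine_precise(self):
        t = np.arange(0.0, 8.0, 0.05)
        y = 2.0 * np.exp(-np.log(2.0) * t)
        stim = StimulusWindow(onset_s=0.0, duration_s=0.5)
        trace = Trace(100.0 * (1 + y), t, kind="raw",
                      stimulus=stim)
        res = compute_kinetics(trace, stim, 100.0)
        assert res.halflife_s == pytest.approx(1.0, rel=1e-8)
        assert res.r2_decay == pytest.approx(1.0, abs=1e-12)

    def test_peak_at_final_sample_suppresses_halflife(self):
        t = np.arange(0.0, 3.0, 0.1)
        stim = StimulusWindow(onset_s=1.0, duration_s=0.5)
        trace = Trace(100.0 + t * 10, t, kind="raw", stimulus=stim)
        res = compute_kinetics(trace, stim, 100.0)
        assert res.peak_at_end
        assert res.halflife_s is None

    def test_delta_trace_divided_by_f0(self):
        trace, stim, f0 = self._transient_trace()
        delta = Trace(trace.values - f0, trace.times_s, kind="delta",
                      stimulus=stim)
        res = compute_kinetics(delta, stim, f0)
        assert res.peak_dff == pytest.approx(1.0, abs=1e-12)

    def test_noisy_halflife_recovery_median_error_below_10_percent(self):
        """Full movie pipeline at 5% baseline noise, many seeds: the median
        relative half-life error stays below 10%."""
        errors = []
        for seed in range(50):
            truth = make_movie_truth(
                n_cells=1, n_active=1, n_volumes=100, shape=(48, 48),
                seed=seed, noise=(10.0, 0.0),  # sd = 5% of F0=200
            )
            movie, truth = simulate_functional_movie(truth)
            series, projected, _ = prep_pipeline(movie, truth.stimulus,
                                                 register=False)
            cell = truth.cells[0]
            roi = ROISpec(cell.center, 3.3)
            trace = extract_trace(projected, roi)
            trace.stimulus = truth.stimulus
            f0 = float(series.F0[roi.mask(series.F0.shape)].mean())
            res = compute_kinetics(trace, truth.stimulus, f0)
            if res.halflife_s is not None:
                errors.append(abs(res.halflife_s - cell.decay_halflife_s))
        assert len(errors) >= 45
        assert np.median(errors) < 0.10 * 1.0

    def test_estimated_vs_true_peak_regression_near_identity(self):
        """100 active cells with peaks uniform on (0.2, 2.0) at σ_dff=0.02:
        the estimated-vs-true regression has slope 1 ± 0.02 and intercept
        within ±0.01."""
        truth = make_movie_truth(
            n_cells=100, n_active=100, n_volumes=100, shape=(260, 260),
            seed=123, peak_dff=(0.2, 2.0), noise=(4.0, 0.0),  # σ_dff=0.02
        )
        movie, truth = simulate_functional_movie(truth)
        series, projected, _ = prep_pipeline(movie, truth.stimulus,
                                             register=False)
        est, true = [], []
        for cell in truth.cells:
            roi = ROISpec(cell.center, 3.3)
            trace = extract_trace(projected, roi)
            f0 = float(series.F0[roi.mask(series.F0.shape)].mean())
            res = compute_kinetics(trace, truth.stimulus, f0)
            est.append(res.peak_dff)
            true.append(cell.peak_dff)
        slope, intercept = np.polyfit(true, est, 1)
        assert slope == pytest.approx(1.0, abs=0.02)
        assert intercept == pytest.approx(0.0, abs=0.01)

    def test_peak_error_decreases_with_noise(self):
        """Mean |peak error| over seeds decreases as noise decreases."""
        mean_err = []
        for noise_sd in (16.0, 4.0, 1.0):
            errs = []
            for seed in range(10):
                truth = make_movie_truth(
                    n_cells=1, n_active=1, n_volumes=60, shape=(48, 48),
                    seed=seed, noise=(noise_sd, 0.0),
                )
                movie, truth = simulate_functional_movie(truth)
                series, projected, _ = prep_pipeline(movie, truth.stimulus,
                                                     register=False)
                cell = truth.cells[0]
                roi = ROISpec(cell.center, 3.3)
                trace = extract_trace(projected, roi)
                f0 = float(series.F0[roi.mask(series.F0.shape)].mean())
                res = compute_kinetics(trace, truth.stimulus, f0)
                errs.append(abs(res.peak_dff - cell.peak_dff))
            mean_err.append(np.mean(errs))
        assert mean_err[0] > mean_err[1] > mean_err[2]


class TestRestingIntensity:
    def test_constant_trace(self):
        t = np.arange(0.0, 3.0, 0.1)
        trace = Trace(np.full_like(t, 42.0), t)
        assert resting_intensity(trace, 2.0) == pytest.approx(42.0)

    def test_ramp_mean(self):
        t = np.arange(20) * 0.1
        trace = Trace(np.arange(20.0), t)
        assert resting_intensity(trace, 2.0) == pytest.approx(9.5)

    def test_window_longer_than_trace_rejected(self):
        t = np.arange(5) * 0.1
        trace = Trace(np.ones(5), t)
        with pytest.raises(ValueError):
            resting_intensity(trace, 2.0)

    def test_delta_trace_rejected(self):
        t = np.arange(20) * 0.1
        trace = Trace(np.ones(20), t, kind="delta")
        with pytest.raises(ValueError, match="raw"):
            resting_intensity(trace)


class TestActivityClassification:
    def test_zero_peak_is_inactive(self):
        res = KineticsResult(0.0, 0.0, np.nan, None)
        assert not classify_activity(res, 0.05)

    def test_ten_sigma_peak_is_active(self):
        res = KineticsResult(0.5, 0.5, 1.0, None)
        assert classify_activity(res, 0.05, k=3)

    def test_simulated_classification_is_perfect_across_seeds(self):
        """Active cells (peak 0.5) vs inactive at 5% pixel noise: the
        sustained-exceedance criterion separates them perfectly, 20 seeds."""
        correct = total = 0
        for seed in range(20):
            truth = make_movie_truth(
                n_cells=4, n_active=2, n_volumes=80, shape=(96, 96),
                seed=seed, peak_dff=0.5, noise=(10.0, 0.0),
            )
            movie, truth = simulate_functional_movie(truth)
            series, projected, _ = prep_pipeline(movie, truth.stimulus,
                                                 register=False)
            for cell in truth.cells:
                roi = ROISpec(cell.center, 3.3)
                trace = extract_trace(projected, roi)
                trace.stimulus = truth.stimulus
                f0 = float(series.F0[roi.mask(series.F0.shape)].mean())
                res = compute_kinetics(trace, truth.stimulus, f0)
                noise = estimate_baseline_noise(trace, f0, truth.stimulus)
                dff = (trace.values - f0) / f0
                post = dff[trace.times_s >= truth.stimulus.onset_s]
                total += 1
                pred = classify_activity(res, noise, dff_post_onset=post,
                                         min_sustained=3)
                if pred == cell.is_active:
                    correct += 1
        assert correct == total


class TestAggregate:
    def _cell(self, i, peak, active=True):
        rec = CellRecord(id=f"c{i}")
        res = KineticsResult(peak, 0.5, peak / 0.5, 1.0, active=active)
        return rec, res

    def test_single_active_cell_summary_equals_its_metrics(self):
        summary = aggregate_neuromast([self._cell(0, 0.4)])
        assert summary.peak_dff == pytest.approx(0.4)
        assert summary.n_selected == 1

    def test_mean_of_two_peaks(self):
        cells = [self._cell(0, 0.2), self._cell(1, 0.4)]
        summary = aggregate_neuromast(cells)
        assert summary.peak_dff == pytest.approx(0.3)

    def test_inactive_cells_excluded_in_active_only_mode(self):
        cells = [self._cell(0, 0.2), self._cell(1, 0.9, active=False)]
        summary = aggregate_neuromast(cells)
        assert summary.selected_ids == ("c0",)

    def test_no_active_cells_yields_flagged_empty_summary(self):
        cells = [self._cell(0, 0.1, active=False)]
        summary = aggregate_neuromast(cells)
        assert summary.empty
        assert np.isnan(summary.peak_dff)

    def test_random_subset_is_deterministic_under_seed(self):
        cells = [self._cell(i, 0.1 * i) for i in range(10)]
        s1 = aggregate_neuromast(cells, "random_subset", n=4, seed=99)
        s2 = aggregate_neuromast(cells, "random_subset", n=4, seed=99)
        assert s1.selected_ids == s2.selected_ids
        assert s1.n_selected == 4
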