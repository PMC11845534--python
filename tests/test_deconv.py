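"""Time-expanded regression: spline basis, design structure, fitting,
reconstruction, and overlap correction."""

import numpy as np
import pandas as pd
import pytest

from fixerp.core import ContinuousEEG
from fixerp.deconv import (DeconvSpec, ErpWaveform, baseline_correct,
                           build_design, epoch_average, fit, load_fit,
                           reconstruct_erp, save_fit, spline_basis)
from fixerp.synth import NoiseParams, default_kernels, render_eeg, sample_scanpath

from conftest import make_events


INTERCEPT_ONLY = dict(include_steps=False, include_saccades=False,
                      include_aoi=False, include_spline=False)


class TestSplineBasis:
    def test_partition_of_unity(self, rng):
        a = rng.gamma(2, 2.5, 300)
        sb = spline_basis(a, 5)
        np.testing.assert_allclose(sb.raw(a).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_contribution_at_reference(self, rng):
        a = rng.gamma(2, 2.5, 300)
        sb = spline_basis(a, 5)
        assert np.abs(sb.transform(np.array([sb.reference]))).max() == 0.0

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            spline_basis(np.array([1.0, 1.0, 2.0, 2.0]), 5)

    def test_smooth_function_recovery(self, rng):
        """Least-squares on the basis recovers a known smooth curve."""
        a = rng.gamma(2, 2.5, 500)
        f = lambda a: np.sin(a / 3.0) + 0.1 * a
        y = f(a) + rng.normal(0, 0.05, len(a))
        sb = spline_basis(a, 5)
        X = np.column_stack([np.ones(len(a)), sb.transform(a)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        grid = np.quantile(a, np.linspace(0.05, 0.95, 50))
        pred = np.column_stack([np.ones(50), sb.transform(grid)]) @ beta
        pred_c = pred - pred.mean()
        true_c = f(grid) - f(grid).mean()
        rmse = np.sqrt(np.mean((pred_c - true_c) ** 2))
        assert rmse < 0.10 * np.ptp(true_c)


class TestBuildDesign:
    def test_single_event_intercept_stick(self):
        spec = DeconvSpec(rate=250.0, fix_window_ms=(-100.0, 300.0),
                          **INTERCEPT_ONLY)
        events = make_events([("fixation", 200, 300.0, "Environment",
                               np.nan, np.nan)])
        design = build_design(events, spec, 1000)
        n_lags = len(spec.fix_lags)
        assert design.X.nnz == n_lags
        assert np.all(design.X.data == 1.0)
        rows = design.X.tocoo().row
        assert rows.min() == 200 + spec.fix_lags[0]
        assert rows.max() == 200 + spec.fix_lags[-1]

    def test_separated_events_are_block_diagonal(self):
        spec = DeconvSpec(rate=250.0, fix_window_ms=(-100.0, 300.0),
                          **INTERCEPT_ONLY)
        events = make_events([
            ("fixation", 200, 300.0, "Environment", np.nan, np.nan),
            ("fixation", 600, 300.0, "Environment", np.nan, np.nan)])
        design = build_design(events, spec, 1200)
        counts = np.diff(design.X.indptr)      # nonzeros per sample row
        assert counts.max() == 1

    def test_overlap_rows_have_two_entries(self):
        spec = DeconvSpec(rate=250.0, fix_window_ms=(0.0, 100.0),
                          **INTERCEPT_ONLY)
        events = make_events([
            ("fixation", 200, 300.0, "Environment", np.nan, np.nan),
            ("fixation", 210, 300.0, "Environment", np.nan, np.nan)])
        design = build_design(events, spec, 1000)
        counts = np.diff(design.X.indptr)
        # windows are 26 lags; overlap = 26 - 10 = 16 shared samples
        assert (counts == 2).sum() == 16

    def test_out_of_bounds_event_dropped(self):
        spec = DeconvSpec(rate=250.0, fix_window_ms=(-100.0, 300.0),
                          **INTERCEPT_ONLY)
        events = make_events([
            ("fixation", 5, 300.0, "Environment", np.nan, np.nan),
            ("fixation", 500, 300.0, "Environment", np.nan, np.nan)])
        design = build_design(events, spec, 1000)
        assert design.n_fixations == 1
        assert design.n_dropped == 1

    def test_missing_prior_excluded_with_spline(self, rng):
        spec = DeconvSpec(rate=250.0, fix_window_ms=(-100.0, 300.0),
                          include_steps=False, n_spline=3)
        rows = [("fixation", 200 + 150 * i, 300.0, "Environment", np.nan,
                 float(a)) for i, a in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])]
        rows.append(("fixation", 1200, 300.0, "Environment", np.nan, np.nan))
        design = build_design(make_events(rows), spec, 2000)
        assert design.n_fixations == 5


class TestFit:
    def test_noise_free_isolated_events_exact(self):
        """Recovered intercept kernel equals the generator kernel."""
        kernels = default_kernels()
        onsets = np.arange(500, 10000, 800)
        events = make_events([("fixation", o, 300.0, "Environment",
                               np.nan, 3.0) for o in onsets])
        eeg = render_eeg(events, kernels, noise=None, rate=250.0,
                         duration_s=44.0)
        spec = DeconvSpec(rate=250.0, **INTERCEPT_ONLY)
        design = build_design(events, spec, eeg.n_samples)
        result = fit(eeg, design)
        truth = kernels.fixation_response(result.fix_lags_ms, "Environment", 3.0)
        assert np.abs(result.block("fix_intercept") - truth).max() < 1e-6

    def test_averaging_equivalence_with_noise(self, rng):
        """Isolated events: regression ERP == naive epoch average (OLS)."""
        spec = DeconvSpec(rate=250.0, fix_window_ms=(-100.0, 300.0),
                          **INTERCEPT_ONLY)
        for _ in range(5):
            n = 12_000
            onsets = np.arange(300, n - 300, 450)
            events = make_events([("fixation", int(o), 200.0, "Environment",
                                   np.nan, np.nan) for o in onsets])
            eeg = ContinuousEEG(rng.normal(0, 3, (2, n)), 250.0, ("Oz", "Pz"))
            design = build_design(events, spec, n)
            result = fit(eeg, design)
            avg = epoch_average(eeg, onsets, spec.fix_window_ms)
            assert np.abs(result.block("fix_intercept") - avg.values).max() < 1e-8

    def test_lsmr_matches_direct(self, rng):
        spec = DeconvSpec(rate=250.0, fix_window_ms=(-100.0, 300.0),
                          **INTERCEPT_ONLY)
        onsets = np.arange(300, 8000, 220)
        events = make_events([("fixation", int(o), 200.0, "Environment",
                               np.nan, np.nan) for o in onsets])
        eeg = ContinuousEEG(rng.normal(0, 3, (1, 9000)), 250.0, ("Oz",))
        design = build_design(events, spec, 9000)
        direct = fit(eeg, design, solver="direct")
        lsmr = fit(eeg, design, solver="lsmr")
        assert np.abs(direct.coef - lsmr.coef).max() < 1e-6

    def test_rank_deficient_flagged(self, rng):
        """A condition with no events leaves all-zero columns."""
        spec = DeconvSpec(rate=250.0, fix_window_ms=(-100.0, 300.0),
                          include_steps=False, include_spline=False)
        events = make_events([("fixation", 300, 200.0, "Environment",
                               np.nan, np.nan)])
        eeg = ContinuousEEG(rng.normal(0, 1, (1, 1000)), 250.0, ("Oz",))
        design = build_design(events, spec, 1000)
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            result = fit(eeg, design)
        assert result.diagnostics["rank_deficient"]

    def test_overlap_correction_beats_averaging(self):
        """Deconvolution recovers kernels better than naive averaging."""
        from fixerp.core import bandpass
        from fixerp.synth import bandpassed_fixation_response
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(1000 + seed)
            events = sample_scanpath(150.0, rng=rng, rate=250.0)
            kernels = default_kernels()
            eeg = render_eeg(events, kernels,
                             noise=NoiseParams(pink_sd=3.0, white_sd=1.0),
                             rate=250.0, rng=rng)
            eeg = bandpass(eeg, 1.0, 30.0)
            spec = DeconvSpec(rate=250.0)
            design = build_design(events, spec, eeg.n_samples)
            result = fit(eeg, design)
            recon = reconstruct_erp(result, "Environment",
                                    amplitude=result.reference_amplitude)
            fix = events[(events["event_type"] == "fixation")
                         & np.isfinite(events["prior_saccade_amplitude"])]
            env = fix[fix["aoi"] == "Environment"]
            naive = baseline_correct(epoch_average(
                eeg, env["onset_sample"].to_numpy(), spec.fix_window_ms))
            truth = baseline_correct(ErpWaveform(
                bandpassed_fixation_response(
                    kernels, recon.lags_ms, 250.0, "Environment",
                    result.reference_amplitude),
                recon.lags_ms, eeg.channel_names))
            rmse_deconv = np.sqrt(np.mean((recon.values - truth.values) ** 2))
            rmse_naive = np.sqrt(np.mean((naive.values - truth.values) ** 2))
            wins += rmse_deconv < rmse_naive
        assert wins >= 2

    def test_amplitude_spline_surface_matches_gain(self):
        """Fitted lambda gain curve is monotone and tracks the truth."""
        rng = np.random.default_rng(77)
        events = sample_scanpath(120.0, rng=rng, rate=250.0)
        kernels = default_kernels()
        eeg = render_eeg(events, kernels, noise=None, rate=250.0)
        spec = DeconvSpec(rate=250.0, include_steps=True)
        design = build_design(events, spec, eeg.n_samples)
        result = fit(eeg, design)

        amps = events.loc[events["event_type"] == "fixation",
                          "prior_saccade_amplitude"].dropna()
        grid = np.quantile(amps, np.linspace(0.05, 0.95, 25))
        oz = list(eeg.channel_names).index("Oz")
        p1_lag = np.argmin(np.abs(result.fix_lags_ms - 90.0))
        fitted = []
        for a in grid:
            erp = reconstruct_erp(result, "Environment", amplitude=float(a))
            fitted.append(erp.values[oz, p1_lag])
        fitted = np.array(fitted)
        truth = kernels.gain(grid)
        assert np.corrcoef(fitted, truth)[0, 1] >= 0.9
        # monotone up to small numerical wiggle
        assert np.sum(np.diff(fitted) < -1e-3) <= 2


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    events = sample_scanpath(60.0, rng=rng, rate=250.0)
    kernels = default_kernels(delta_realistic=0.30)
    eeg = render_eeg(events, kernels, noise=None, rate=250.0)
    spec = DeconvSpec(rate=250.0)
    design = build_design(events, spec, eeg.n_samples)
    return fit(eeg, design)


class TestReconstruct:

    def test_environment_is_intercept(self, fitted):
        erp = reconstruct_erp(fitted, "Environment")
        expected = baseline_correct(ErpWaveform(
            fitted.block("fix_intercept"), fitted.fix_lags_ms,
            fitted.channel_names))
        np.testing.assert_allclose(erp.values, expected.values, atol=1e-12)

    def test_condition_difference_is_dummy_trace(self, fitted):
        env = reconstruct_erp(fitted, "Environment")
        real = reconstruct_erp(fitted, "LM-Realistic")
        dummy = baseline_correct(ErpWaveform(
            fitted.block("fix_realistic"), fitted.fix_lags_ms,
            fitted.channel_names))
        np.testing.assert_allclose(real.values - env.values, dummy.values,
                                   atol=1e-10)

    def test_unknown_condition_rejected(self, fitted):
        with pytest.raises(ValueError, match="unknown condition"):
            reconstruct_erp(fitted, "LM-Cartoon")

    def test_round_trip_persistence(self, fitted, tmp_path):
        save_fit(tmp_path / "fit.h5", fitted)
        back = load_fit(tmp_path / "fit.h5")
        np.testing.assert_array_equal(back.coef, fitted.coef)
        a = reconstruct_erp(fitted, "LM-Abstract", amplitude=3.0)
        b = reconstruct_erp(back, "LM-Abstract", amplitude=3.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestBaselineCorrect:
    def test_constant_waveform_zeroed(self):
        erp = ErpWaveform(np.full(100, 2.5), np.linspace(-200, 196, 100))
        out = baseline_correct(erp)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        erp = ErpWaveform(rng.normal(size=100), np.linspace(-200, 196, 100))
        once = baseline_correct(erp)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_hand_example(self):
        erp = ErpWaveform(np.array([1.0, 1.0, 2.0, 2.0]),
                          np.array([-100.0, -50.0, 50.0, 100.0]))
        out = baseline_correct(erp, window=(-100.0, -50.0))
        np.testing.assert_allclose(out.values, [0.0, 0.0, 1.0, 1.0])

    def test_window_outside_lags_rejected(self):
        erp = ErpWaveform(np.zeros(10), np.linspace(0, 90, 10))
        with pytest.raises(ValueError, match="outside"):
            baseline_correct(erp, window=(-200.0, 0.0))
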