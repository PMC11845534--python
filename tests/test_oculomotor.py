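"""Adaptive velocity-based saccade detection and fixation processing."""

import numpy as np
import pandas as pd
import pytest

from fixerp.core import GazeStream
from fixerp.oculomotor import (DetectionParams, VelocityTrace, assign_aoi,
                               attach_prior_saccade, compute_velocity,
                               derive_fixations, detect_events,
                               detect_saccades, filter_fixations)
from fixerp.oculomotor import _median_sd
from fixerp.synth import (NoiseParams, ScanpathParams, render_gaze,
                          sample_scanpath)


def make_gaze(x, y=None, rate=200.0, aoi=None):
    n = len(x)
    y = np.zeros(n) if y is None else np.asarray(y, float)
    aoi = np.array(["none"] * n, dtype=object) if aoi is None else aoi
    return GazeStream(np.arange(n) / rate, np.asarray(x, float), y, aoi, rate)


def brute_force_saccades(crit_mask, min_samples):
    """Independent run scanner: enumerate every maximal suprathreshold run."""
    runs = []
    i = 0
    n = len(crit_mask)
    while i < n:
        if crit_mask[i]:
            j = i
            while j < n and crit_mask[j]:
                j += 1
            if j - i >= min_samples:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


class TestVelocity:
    def test_linear_ramp_velocity(self):
        rate = 200.0
        t = np.arange(400) / rate
        jitter = np.random.default_rng(0).normal(0, 0.002, (2, 400))
        gaze = make_gaze(10.0 * t + jitter[0], y=jitter[1])
        vel = compute_velocity(gaze)
        np.testing.assert_allclose(vel.vx[10:-10], 10.0, atol=0.8)

    def test_median_sd_against_brute_force(self):
        v = np.array([0.0, 0.0, 0.0, 30.0, 30.0, 0.0, 0.0, 0.0])
        # independent oracle: medians by explicit sort
        med = sorted(v)[len(v) // 2 - 1:len(v) // 2 + 1]
        med = sum(med) / 2
        med_sq = sorted(v * v)[len(v) // 2 - 1:len(v) // 2 + 1]
        med_sq = sum(med_sq) / 2
        expected = np.sqrt(med_sq - med ** 2)
        assert _median_sd(v) == pytest.approx(expected)

    def test_constant_position_degenerate(self):
        gaze = make_gaze(np.full(100, 2.0))
        with pytest.raises(ValueError, match="degenerate"):
            compute_velocity(gaze)

    def test_gap_neighbourhood_is_nan(self):
        walk = np.random.default_rng(0).normal(0, 0.1, (2, 200)).cumsum(axis=1)
        walk[0, 100] = np.nan
        gaze = make_gaze(walk[0], y=walk[1])
        vel = compute_velocity(gaze)
        assert np.isnan(vel.vx[98:103]).all()


class TestDetectSaccades:
    def make_trace(self, crit, rate=200.0):
        """Velocity trace whose criterion equals the given boolean burst."""
        n = len(crit)
        vx = np.where(crit, 50.0, 0.5)
        vy = np.zeros(n)
        x = np.cumsum(vx) / rate
        return VelocityTrace(vx, vy, eta_x=10.0, eta_y=10.0, rate=rate,
                             x=x, y=np.zeros(n), t=np.arange(n) / rate)

    def test_six_sample_burst_is_one_saccade(self):
        crit = np.zeros(100, dtype=bool)
        crit[40:46] = True
        out = detect_saccades(self.make_trace(crit))
        assert len(out) == 1
        assert out.iloc[0]["start_index"] == 40
        assert out.iloc[0]["duration_ms"] == pytest.approx(6 / 200 * 1000)

    def test_three_sample_burst_rejected(self):
        crit = np.zeros(100, dtype=bool)
        crit[40:43] = True
        assert len(detect_saccades(self.make_trace(crit))) == 0

    def test_amplitude_is_endpoint_displacement(self):
        crit = np.zeros(100, dtype=bool)
        crit[40:46] = True
        trace = self.make_trace(crit)
        out = detect_saccades(trace)
        expected = trace.x[46] - trace.x[40]
        assert out.iloc[0]["amplitude"] == pytest.approx(expected)

    def test_oracle_equivalence_on_random_traces(self):
        """Exact match with an independent brute-force run scanner."""
        rng = np.random.default_rng(99)
        params = DetectionParams()
        for _ in range(100):
            n = 300
            vx = rng.normal(0, 5, n) + rng.choice([0, 40], n, p=[0.9, 0.1])
            vy = rng.normal(0, 5, n)
            trace = VelocityTrace(vx, vy, eta_x=15.0, eta_y=15.0, rate=200.0,
                                  x=np.cumsum(vx) / 200, y=np.cumsum(vy) / 200,
                                  t=np.arange(n) / 200.0)
            crit = (vx / 15.0) ** 2 + (vy / 15.0) ** 2 > 1.0
            expected = brute_force_saccades(crit, params.min_saccade_samples)
            got = detect_saccades(trace, params)
            assert len(got) == len(expected)
            for (start, stop), row in zip(expected, got.itertuples()):
                assert (row.start_index, row.stop_index) == (start, stop)


class TestDeriveFixations:
    def saccades_at(self, spans, gaze):
        rows = [dict(event_type="saccade", onset_sample=a, duration_ms=0.0,
                     aoi="none", amplitude=1.0, peak_velocity=100.0,
                     prior_saccade_amplitude=np.nan,
                     start_index=a, stop_index=b) for a, b in spans]
        return pd.DataFrame(rows)

    def test_two_saccades_three_fixations(self):
        gaze = make_gaze(np.zeros(100) + np.arange(100) * 0.001)
        fix = derive_fixations(self.saccades_at([(30, 35), (60, 66)], gaze), gaze)
        assert len(fix) == 3
        assert list(fix["start_index"]) == [0, 35, 66]

    def test_saccade_at_stream_start_no_leading_fixation(self):
        gaze = make_gaze(np.arange(100) * 0.001)
        fix = derive_fixations(self.saccades_at([(0, 6)], gaze), gaze)
        assert len(fix) == 1
        assert fix.iloc[0]["start_index"] == 6

    def test_gap_splits_fixation(self):
        x = np.arange(100) * 0.001
        x[50:53] = np.nan
        gaze = make_gaze(x)
        fix = derive_fixations(self.saccades_at([(10, 15)], gaze), gaze)
        assert len(fix) == 3                    # [0,10), [15,50), [53,100)
        assert list(fix["start_index"]) == [0, 15, 53]


class TestFilterFixations:
    def test_inclusive_bounds(self):
        durations = [100.0, 150.0, 300.0, 2000.0, 2500.0]
        fix = pd.DataFrame({"duration_ms": durations})
        kept = filter_fixations(fix)
        assert list(kept["duration_ms"]) == [150.0, 300.0, 2000.0]

    def test_empty_table(self):
        fix = pd.DataFrame({"duration_ms": []})
        assert len(filter_fixations(fix)) == 0

    def test_all_within_bounds_identity(self):
        fix = pd.DataFrame({"duration_ms": [300.0] * 5})
        assert len(filter_fixations(fix)) == 5

    def test_never_increases_rows(self, rng):
        fix = pd.DataFrame({"duration_ms": rng.uniform(0, 3000, 50)})
        assert len(filter_fixations(fix)) <= 50


class TestAssignAoi:
    def fixture(self, labels):
        n = len(labels)
        gaze = make_gaze(np.zeros(n) + np.arange(n) * 1e-3,
                         aoi=np.array(labels, dtype=object))
        fix = pd.DataFrame([dict(event_type="fixation", onset_sample=0,
                                 duration_ms=n / 200 * 1000, aoi="none",
                                 amplitude=np.nan, peak_velocity=np.nan,
                                 prior_saccade_amplitude=np.nan,
                                 start_index=0, stop_index=n)])
        return fix, gaze

    def test_unanimous(self):
        fix, gaze = self.fixture(["LM-Realistic"] * 10)
        assert assign_aoi(fix, gaze).iloc[0]["aoi"] == "LM-Realistic"

    def test_majority(self):
        fix, gaze = self.fixture(["Environment"] * 6 + ["LM-Abstract"] * 4)
        assert assign_aoi(fix, gaze).iloc[0]["aoi"] == "Environment"

    def test_tie_breaks_to_environment(self):
        fix, gaze = self.fixture(["LM-Abstract"] * 5 + ["Environment"] * 5)
        assert assign_aoi(fix, gaze).iloc[0]["aoi"] == "Environment"

    def test_none_excluded_from_vote(self):
        fix, gaze = self.fixture(["none"] * 7 + ["LM-Abstract"] * 3)
        assert assign_aoi(fix, gaze).iloc[0]["aoi"] == "LM-Abstract"

    def test_unlabelled_fixation_dropped(self):
        fix, gaze = self.fixture(["none"] * 10)
        assert len(assign_aoi(fix, gaze)) == 0

    def test_preserves_onsets_durations(self):
        fix, gaze = self.fixture(["Environment"] * 10)
        out = assign_aoi(fix, gaze)
        assert out.iloc[0]["onset_sample"] == fix.iloc[0]["onset_sample"]
        assert out.iloc[0]["duration_ms"] == fix.iloc[0]["duration_ms"]


class TestAttachPrior:
    def test_prior_amplitude_attached(self):
        saccades = pd.DataFrame([dict(event_type="saccade", onset_sample=100,
                                      duration_ms=30.0, aoi="none",
                                      amplitude=4.0, peak_velocity=200.0,
                                      prior_saccade_amplitude=np.nan)])
        fix = pd.DataFrame([dict(event_type="fixation", onset_sample=110,
                                 duration_ms=300.0, aoi="Environment",
                                 amplitude=np.nan, peak_velocity=np.nan,
                                 prior_saccade_amplitude=np.nan)])
        out = attach_prior_saccade(fix, saccades)
        assert out.iloc[0]["prior_saccade_amplitude"] == 4.0

    def test_first_fixation_missing(self):
        saccades = pd.DataFrame([dict(event_type="saccade", onset_sample=500,
                                      duration_ms=30.0, aoi="none",
                                      amplitude=4.0, peak_velocity=200.0,
                                      prior_saccade_amplitude=np.nan)])
        fix = pd.DataFrame([dict(event_type="fixation", onset_sample=100,
                                 duration_ms=300.0, aoi="Environment",
                                 amplitude=np.nan, peak_velocity=np.nan,
                                 prior_saccade_amplitude=np.nan)])
        out = attach_prior_saccade(fix, saccades)
        assert np.isnan(out.iloc[0]["prior_saccade_amplitude"])


class TestEndToEndDetection:
    def test_ground_truth_recovery_noise_free(self):
        """Detected onsets and priors match the generator on clean gaze."""
        rng = np.random.default_rng(21)
        truth = sample_scanpath(60.0, ScanpathParams(), rng, rate=200.0)
        gaze = render_gaze(truth, 0.0, 200.0, rng,
                           noise=NoiseParams(pink_sd=0.0, white_sd=0.0,
                                             gaze_noise_deg=0.03),
                           eeg_rate=200.0)
        events = detect_events(gaze)

        det_fix = events[events["event_type"] == "fixation"]
        true_fix = truth[(truth["event_type"] == "fixation")
                         & (truth["prior_saccade_amplitude"] >= 1.0)
                         & (truth["duration_ms"].between(150, 2000))]
        # match each true fixation to nearest detected onset
        det_on = det_fix["onset_sample"].to_numpy()
        hits = 0
        prior_ok = 0
        for row in true_fix.itertuples():
            j = np.argmin(np.abs(det_on - row.onset_sample))
            if abs(det_on[j] - row.onset_sample) <= 2:
                hits += 1
                det_prior = det_fix.iloc[j]["prior_saccade_amplitude"]
                if np.isfinite(det_prior) and abs(
                        det_prior - row.prior_saccade_amplitude) \
                        <= 0.2 * row.prior_saccade_amplitude + 0.1:
                    prior_ok += 1
        assert hits >= 0.95 * len(true_fix)
        assert prior_ok >= 0.90 * hits

    def test_detected_aoi_matches_truth(self):
        rng = np.random.default_rng(22)
        truth = sample_scanpath(30.0, ScanpathParams(), rng, rate=200.0)
        gaze = render_gaze(truth, 0.0, 200.0, rng,
                           noise=NoiseParams(pink_sd=0.0, white_sd=0.0,
                                             gaze_noise_deg=0.03),
                           eeg_rate=200.0)
        events = detect_events(gaze)
        det_fix = events[events["event_type"] == "fixation"]
        true_fix = truth[truth["event_type"] == "fixation"]
        det_on = det_fix["onset_sample"].to_numpy()
        agree = total = 0
        for row in true_fix.itertuples():
            j = np.argmin(np.abs(det_on - row.onset_sample))
            if abs(det_on[j] - row.onset_sample) <= 2:
                total += 1
                agree += det_fix.iloc[j]["aoi"] == row.aoi
        assert total > 0
        assert agree / total >= 0.95
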