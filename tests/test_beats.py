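"""Beat detection, quality screening, window selection and averaging."""

import numpy as np
import pytest

from scgcti.beats import (BeatSeries, NoUsableBeatsError, detect_q_points,
                          detect_r_peaks, ensemble_average, flag_beat_quality,
                          select_window)
from scgcti.synth import SynthConfig, generate_record


class TestRDetection:
    def test_all_r_recovered_no_extras_on_clean_ecg(self, clean_record):
        rec, truth = clean_record
        series = detect_r_peaks(rec.ecg, rec.sampling_rate)
        assert series.n_beats == len(truth.r_times)
        tol = 1000.0 / rec.sampling_rate + 1e-9
        assert np.max(np.abs(series.r_times - truth.r_times)) <= tol

    def test_flat_signal_yields_zero_beats(self):
        series = detect_r_peaks(np.zeros(1000), 200.0)
        assert series.n_beats == 0

    def test_sensitivity_and_precision_above_99pct_with_noise(self):
        """Additive ECG noise at 10% of R amplitude over 300 beats."""
        cfg = SynthConfig(duration=260.0, mean_rr=857.0, rr_sd=40.0,
                          noise_sd=0.0, resp_mod_depth=0.0, seed=21)
        rec, truth = generate_record(cfg)
        rng = np.random.default_rng(99)
        ecg = rec.ecg + rng.normal(0.0, 0.10, rec.n_samples)
        series = detect_r_peaks(ecg, rec.sampling_rate)
        assert len(truth.r_times) >= 300
        tol = 2.5 * 1000.0 / rec.sampling_rate
        hits = sum(np.min(np.abs(series.r_times - r)) <= tol
                   for r in truth.r_times)
        sensitivity = hits / len(truth.r_times)
        precision = hits / series.n_beats
        assert sensitivity >= 0.99 and precision >= 0.99

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(100), 200.0)


class TestQDetection:
    def test_q_recovered_20ms_before_r(self, clean_record):
        rec, truth = clean_record
        q = detect_q_points(rec.ecg, truth.r_times, rec.sampling_rate)
        offsets = truth.r_times[1:-1] - q[1:-1]
        assert np.all(np.abs(offsets - 20.0) <= 2.0)

    def test_truncated_window_gives_missing_q(self):
        ecg = np.zeros(400)
        q = detect_q_points(ecg, np.array([30.0, 500.0]), 200.0)
        assert np.isnan(q[0]) and np.isfinite(q[1])


class TestQuality:
    def test_constant_rr_all_good(self):
        series = BeatSeries(r_times=np.arange(10) * 1000.0)
        flagged = flag_beat_quality(series, np.zeros(20000), 1000.0)
        assert flagged.quality == ["good"] * 10

    def test_ectopic_flags_match_ground_truth(self):
        cfg = SynthConfig(duration=120.0, mean_rr=900.0, rr_sd=20.0,
                          ectopic_rate=0.1, noise_sd=0.02, seed=31)
        rec, truth = generate_record(cfg)
        from scgcti.beats import detect_r_peaks
        series = detect_r_peaks(rec.ecg, rec.sampling_rate)
        assert series.n_beats == len(truth.r_times)
        flagged = flag_beat_quality(series, rec.scg, rec.sampling_rate)
        pred = [q == "ectopic" for q in flagged.quality]
        true = [lab == "ectopic" for lab in truth.beat_labels]
        agree = np.mean([p == t for p, t in zip(pred, true)])
        assert agree >= 0.95

    def test_noise_burst_beat_flagged_noisy(self):
        r_times = np.arange(10) * 1000.0 + 500.0
        fs = 1000.0
        rng = np.random.default_rng(0)
        scg = rng.normal(0.0, 1.0, 11000)
        i = int(r_times[4])
        scg[i - 100:i + 600] += rng.normal(0.0, 10.0, 700)
        flagged = flag_beat_quality(BeatSeries(r_times=r_times), scg, fs)
        assert flagged.quality[4] == "noisy"
        assert flagged.quality.count("noisy") == 1


class TestWindowSelection:
    def test_all_good_run_selected_from_start(self):
        s = BeatSeries(r_times=np.arange(10) * 1000.0)
        w = select_window(s)
        assert np.array_equal(w.beat_indices, np.arange(10))
        assert not w.single_beat

    def test_alternating_ectopy_engages_single_beat_fallback(self):
        q = ["good", "ectopic"] * 5
        s = BeatSeries(r_times=np.arange(10) * 1000.0, quality=q)
        w = select_window(s)
        assert w.single_beat and len(w.beat_indices) == 1
        assert s.quality[w.beat_indices[0]] == "good"

    def test_all_noisy_raises(self):
        s = BeatSeries(r_times=np.arange(5) * 1000.0, quality=["noisy"] * 5)
        with pytest.raises(NoUsableBeatsError):
            select_window(s)


class TestEnsembleAverage:
    fs = 1000.0

    def _series(self, n, rr=1000.0, offset=500.0):
        return BeatSeries(r_times=np.arange(n) * rr + offset)

    def test_identical_beats_average_to_single_beat(self, clean_record):
        rec, truth = clean_record
        series = BeatSeries(r_times=truth.r_times)
        avg = ensemble_average(rec.scg, series, rec.sampling_rate,
                               beat_indices=np.arange(1, 10))
        r = int(round(truth.r_times[5] / 1000.0 * rec.sampling_rate))
        lo = r + int(round(-100e-3 * rec.sampling_rate))
        single = rec.scg[lo:lo + len(avg.samples)]
        assert np.allclose(avg.samples, single, atol=1e-6)

    def test_noise_reduction_scales_as_sqrt_k(self):
        """Residual noise SD of a 6-beat average is sigma/sqrt(6) within 25%."""
        rng = np.random.default_rng(42)
        sigma = 1.0
        scg = rng.normal(0.0, sigma, 8000)
        series = self._series(6, offset=700.0)
        avg = ensemble_average(scg, series, self.fs, window_ms=(-100.0, 400.0))
        est = np.nanstd(avg.samples[:500])
        assert abs(est - sigma / np.sqrt(6)) < 0.25 * sigma / np.sqrt(6)

    def test_single_beat_average_equals_that_beat(self):
        scg = np.random.default_rng(3).standard_normal(3000)
        series = self._series(2, offset=800.0)
        avg = ensemble_average(scg, series, self.fs, beat_indices=[1])
        assert avg.n_beats_used == 1 and avg.single_beat
        lo = 1800 - 100
        assert np.allclose(avg.samples, scg[lo:lo + len(avg.samples)])

    def test_permutation_invariance(self):
        scg = np.random.default_rng(4).standard_normal(9000)
        series = self._series(8, offset=600.0)
        a = ensemble_average(scg, series, self.fs, beat_indices=[1, 3, 5])
        b = ensemble_average(scg, series, self.fs, beat_indices=[5, 1, 3])
        assert np.allclose(a.samples, b.samples, equal_nan=True)

    def test_window_outside_record_for_all_beats_errors(self):
        series = BeatSeries(r_times=np.array([50000.0]))
        with pytest.raises(ValueError):
            ensemble_average(np.zeros(100), series, self.fs)

    def test_edge_truncated_beats_excluded_samplewise(self):
        scg = np.ones(2000)
        series = self._series(2, offset=50.0)   # first beat window cut at start
        avg = ensemble_average(scg, series, self.fs)
        assert np.allclose(avg.samples[np.isfinite(avg.samples)], 1.0)
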