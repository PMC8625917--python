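"""R-peak detection, RR series, rhythm alarms and HRV metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoecg.rhythm import (AlarmEvent, PeakTrain, RRSeries, classify_rhythm,
                           detect_r_peaks, hrv_metrics, rr_intervals)
from neoecg.synth import SyntheticSpec, generate_ecg
from .conftest import match_counts


def _train(times):
    times = np.asarray(times, dtype=float)
    return PeakTrain(indices=(times * 250).astype(int), times=times,
                     amplitudes=np.ones(times.size), reference_peak=1.0)


def _series(rr, start=2.0):
    rr = np.asarray(rr, dtype=float)
    times = start + np.concatenate([[0.0], np.cumsum(rr)])
    return rr_intervals(_train(times))


class TestDetect:
    def test_recovers_all_peaks_on_clean_ecg(self):
        sig, truth = generate_ecg(SyntheticSpec(duration=10.0, seed=9))
        train, _ = detect_r_peaks(sig.samples, sig.fs)
        truth_after = truth.peak_times[truth.peak_times >= 2.2]
        matched, fp = match_counts(train.times, truth_after, sig.fs)
        assert matched == truth_after.size
        assert fp == 0

    def test_subthreshold_candidate_rejected(self):
        """A 0.65 bump is below 70% of a 1.0 reference and must not count."""
        fs = 250.0
        x = np.zeros(2500)
        for t, amp in [(2.2, 1.0), (4.0, 0.65), (6.0, 1.0)]:
            x[int(t * fs)] = amp
        train, _ = detect_r_peaks(x, fs)
        assert np.allclose(sorted(train.times), [2.2, 6.0])

    def test_warmup_peaks_excluded(self):
        sig, truth = generate_ecg(SyntheticSpec(duration=10.0, seed=2))
        assert (truth.peak_times < 2.0).any()
        train, _ = detect_r_peaks(sig.samples, sig.fs)
        assert (train.times >= 2.0).all()

    def test_flat_signal_yields_empty_train(self):
        train, _ = detect_r_peaks(np.zeros(1000), 250.0)
        assert len(train) == 0

    def test_negative_fs_raises(self):
        with pytest.raises(ValueError, match="positive"):
            detect_r_peaks(np.zeros(1000), -1.0)

    def test_refractory_suppresses_double_detection(self):
        fs = 250.0
        x = np.zeros(2500)
        x[600] = 1.0   # 2.4 s
        x[620] = 0.95  # 80 ms later: inside the 0.2 s refractory window
        x[800] = 1.0
        train, _ = detect_r_peaks(x, fs)
        assert 620 not in train.indices
        assert {600, 800} <= set(train.indices)

    def test_time_shift_equivariance(self):
        sig, _ = generate_ecg(SyntheticSpec(duration=10.0, seed=4))
        m = 100
        base, _ = detect_r_peaks(sig.samples, sig.fs)
        shifted, _ = detect_r_peaks(np.concatenate([sig.samples[:m][::-1],
                                                    sig.samples]), sig.fs)
        # peaks after warm-up in both: shifted indices move by m
        common = [i + m for i in base.indices if (i + m) / sig.fs >= 2.0]
        assert set(common) <= set(shifted.indices)

    def test_inverted_lead_via_flag(self):
        sig, truth = generate_ecg(SyntheticSpec(duration=10.0, seed=3))
        train, _ = detect_r_peaks(-sig.samples, sig.fs, invert=True)
        truth_after = truth.peak_times[truth.peak_times >= 2.2]
        matched, _ = match_counts(train.times, truth_after, sig.fs)
        assert matched == truth_after.size


class TestRRIntervals:
    def test_equal_intervals(self):
        rr = rr_intervals(_train([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(rr.rr, [0.5, 0.5])
        np.testing.assert_allclose(rr.relative_rr[1:], [0.0], atol=1e-12)

    def test_hand_worked_relative_rr(self):
        rr = _series([0.5, 0.6])
        assert rr.relative_rr[1] == pytest.approx(2 * 0.1 / 1.1, abs=1e-9)

    def test_fewer_than_two_peaks_gives_empty_series(self):
        rr = rr_intervals(_train([1.0]))
        assert len(rr) == 0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.05, 3.0), min_size=2, max_size=30))
    def test_relative_rr_bounded_and_antisymmetric(self, rrs):
        series = _series(rrs)
        rel = series.relative_rr[1:]
        assert np.all(rel > -2.0) and np.all(rel < 2.0)
        swapped = _series(rrs[:2][::-1])
        assert swapped.relative_rr[1] == pytest.approx(-series.relative_rr[1],
                                                       abs=1e-12)


class TestClassify:
    def test_single_long_interval_alarms(self):
        alarms, _ = classify_rhythm(_series([0.45, 0.67, 0.50]))
        assert len(alarms) == 1
        assert alarms[0].kind == "bradycardia"
        np.testing.assert_allclose(alarms[0].rr_values, [0.67], atol=1e-9)

    def test_boundary_interval_is_not_bradycardia(self):
        series = RRSeries(rr=np.array([0.60]), relative_rr=np.array([np.nan]),
                          interval_end_times=np.array([2.6]))
        alarms, _ = classify_rhythm(series)
        assert alarms == []

    def test_two_short_beats_trigger_tachycardia(self):
        alarms, _ = classify_rhythm(_series([0.40, 0.41]))
        assert len(alarms) == 1
        assert alarms[0].kind == "tachycardia"
        np.testing.assert_allclose(alarms[0].rr_values, [0.40, 0.41], atol=1e-9)

    def test_single_short_interval_is_not_tachycardia(self):
        alarms, _ = classify_rhythm(_series([0.40, 0.50, 0.40]))
        assert alarms == []

    def test_consecutive_long_run_is_one_event(self):
        alarms, _ = classify_rhythm(_series([0.5, 0.7, 0.8, 0.7, 0.5]))
        assert len(alarms) == 1
        np.testing.assert_allclose(alarms[0].rr_values, [0.7, 0.8, 0.7], atol=1e-9)

    def test_two_beat_confirmation_mode(self):
        series = _series([0.5, 0.7, 0.5, 0.7, 0.8])
        default, _ = classify_rhythm(series)
        confirmed, _ = classify_rhythm(series, brady_two_beat=True)
        assert len(default) == 2
        assert len(confirmed) == 1
        np.testing.assert_allclose(confirmed[0].rr_values, [0.7, 0.8], atol=1e-9)

    def test_irregularity_flags_follow_relative_band(self):
        series = _series([0.40, 0.40, 0.55])  # jump of ~31.6% relative RR
        _, flags = classify_rhythm(series)
        assert flags.tolist() == [False, False, True]

    def test_alarm_json_round_trip(self):
        import json
        ev = AlarmEvent("bradycardia", 12.5, [0.67], 3)
        rec = json.loads(ev.to_json())
        assert rec == {"kind": "bradycardia", "onset_time_s": 12.5,
                       "rr_values_s": [0.67], "block_index": 3}


class TestHrvMetrics:
    def test_constant_series_has_zero_variability(self):
        m = hrv_metrics(_series([0.5] * 10))
        assert m["rmssd"] == 0.0
        assert m["sdnn"] == 0.0

    def test_hand_worked_rmssd(self):
        m = hrv_metrics(_series([0.67, 0.68, 0.67]))
        assert m["rmssd"] == pytest.approx(10.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        rrs = rng.uniform(0.3, 0.8, size=500)
        series = _series(rrs)
        m = hrv_metrics(series, sdann_window=5.0)

        diffs = [rrs[i + 1] - rrs[i] for i in range(len(rrs) - 1)]
        rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5 * 1000
        mean = sum(rrs) / len(rrs)
        sdnn = (sum((v - mean) ** 2 for v in rrs) / (len(rrs) - 1)) ** 0.5 * 1000
        ends = series.interval_end_times
        windows = {}
        for v, e in zip(rrs, ends):
            windows.setdefault(int(e // 5.0), []).append(v)
        wmeans = [sum(vs) / len(vs) for _, vs in sorted(windows.items())]
        gm = sum(wmeans) / len(wmeans)
        sdann = (sum((w - gm) ** 2 for w in wmeans) / (len(wmeans) - 1)) ** 0.5 * 1000

        assert m["rmssd"] == pytest.approx(rmssd, abs=1e-9)
        assert m["sdnn"] == pytest.approx(sdnn, abs=1e-9)
        assert m["sdann"] == pytest.approx(sdann, abs=1e-9)

    def test_insufficient_data_reported_as_nan(self):
        m = hrv_metrics(_series([0.5]))
        assert np.isnan(m["rmssd"]) and np.isnan(m["sdnn"]) and np.isnan(m["sdann"])
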