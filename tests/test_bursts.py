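"""Beta-burst detection, per-event metrics and binning."""

import numpy as np
import pandas as pd
import pytest

from stopburst import bursts, simulate, timefreq


def _times(sfreq=1024.0, start=-500.0, end=1000.0):
    n = int(round((end - start) / 1000.0 * sfreq))
    return start + np.arange(n) / sfreq * 1000.0


def _tf_of(signal, sfreq=1024.0):
    t = _times(sfreq)
    return timefreq.tf_power(signal[None, :, None], sfreq, t), t


class TestThreshold:
    def test_constant_power_threshold_is_twice(self):
        p = np.full((15, 100), 3.0)
        valid = np.ones_like(p, bool)
        assert bursts.burst_threshold(p, valid) == 6.0

    def test_median_of_small_set(self):
        p = np.array([[1.0, 1.0, 1.0, 3.0]])
        valid = np.ones_like(p, bool)
        assert bursts.burst_threshold(p, valid) == 2.0

    def test_threshold_scales_with_power(self, rng):
        p = rng.random((15, 200))
        valid = np.ones_like(p, bool)
        t1 = bursts.burst_threshold(p, valid)
        assert bursts.burst_threshold(7.3 * p, valid) == pytest.approx(
            7.3 * t1, rel=1e-12)

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            bursts.burst_threshold(np.ones((2, 2)),
                                   np.zeros((2, 2), bool))


class TestDetect:
    def test_constant_map_no_bursts(self):
        p = np.ones((15, 100))
        valid = np.ones_like(p, bool)
        thr = bursts.burst_threshold(p, valid)
        ev = bursts.detect_bursts(p, thr, valid, np.arange(100.0),
                                  np.arange(15.0) + 15, 1024.0)
        assert len(ev) == 0

    def test_single_kernel_recovered(self):
        t = _times()
        sig = simulate.burst_kernel(t, 500.0, 20.0, 5.0)
        tf, _ = _tf_of(sig)
        # oracle: argmax of the noiseless map
        pmap = tf.power[0, :, :, 0]
        fi, ti = np.unravel_index(np.argmax(np.where(tf.valid, pmap, -1)),
                                  pmap.shape)
        thr = 0.5 * pmap.max()
        ev = bursts.detect_bursts(pmap, thr, tf.valid, t, tf.frequencies,
                                  1024.0)
        assert len(ev) == 1
        assert ev["peak_time_ms"][0] == pytest.approx(t[ti])
        assert ev["peak_freq_hz"][0] == tf.frequencies[fi]
        assert abs(ev["peak_time_ms"][0] - 500.0) <= 10.0
        assert abs(ev["peak_freq_hz"][0] - 20.0) <= 1.0

    def test_two_kernels_in_time_order(self):
        t = _times()
        sig = simulate.burst_kernel(t, 300.0, 20.0, 5.0) + \
            simulate.burst_kernel(t, 700.0, 20.0, 5.0)
        tf, _ = _tf_of(sig)
        pmap = tf.power[0, :, :, 0]
        ev = bursts.detect_bursts(pmap, 0.4 * pmap.max(), tf.valid, t,
                                  tf.frequencies, 1024.0)
        assert len(ev) == 2
        assert abs(ev["peak_time_ms"][0] - 300.0) <= 10.0
        assert abs(ev["peak_time_ms"][1] - 700.0) <= 10.0

    def test_scale_invariance_of_detected_set(self, rng):
        t = _times()
        sig = rng.standard_normal(len(t)) + \
            simulate.burst_kernel(t, 400.0, 22.0, 4.0)
        tf, _ = _tf_of(sig)
        pmap = tf.power[0, :, :, 0]
        valid = tf.valid

        def detected(scale):
            thr = bursts.burst_threshold(scale * pmap, valid)
            return bursts.detect_bursts(scale * pmap, thr, valid, t,
                                        tf.frequencies, 1024.0)

        e1, e2 = detected(1.0), detected(13.7)
        assert len(e1) == len(e2)
        np.testing.assert_allclose(e1["peak_time_ms"], e2["peak_time_ms"])
        np.testing.assert_allclose(e1["peak_freq_hz"], e2["peak_freq_hz"])
        # volume homogeneity: every volume scales by exactly c
        np.testing.assert_allclose(13.7 * e1["volume"], e2["volume"],
                                   rtol=1e-9)


class TestMetrics:
    def _single_region(self, values, thr, sfreq=1024.0):
        """A 1-frequency map whose suprathreshold region is `values`."""
        p = np.concatenate([[0.0], values, [0.0]])[None, :]
        valid = np.ones_like(p, bool)
        t = np.arange(p.shape[1]) / sfreq * 1000.0
        return bursts.detect_bursts(p, thr, valid, t, np.array([20.0]),
                                    sfreq)

    def test_volume_constant_excess(self):
        # k samples exceeding threshold by v: volume = k * v * dt
        k, v, thr = 5, 1.5, 2.0
        ev = self._single_region(np.full(k, thr + v), thr)
        dt = 1000.0 / 1024.0
        assert ev["volume"][0] == pytest.approx(k * v * dt, rel=1e-12)

    def test_volume_additive_over_frequencies(self):
        thr = 1.0
        p = np.zeros((2, 10))
        p[0, 3:6] = 2.5
        p[1, 3:6] = 3.5
        valid = np.ones_like(p, bool)
        t = np.arange(10) / 1024.0 * 1000.0
        ev = bursts.detect_bursts(p, thr, valid, t,
                                  np.array([20.0, 21.0]), 1024.0)
        dt = 1000.0 / 1024.0
        assert len(ev) == 1
        assert ev["volume"][0] == pytest.approx((3 * 1.5 + 3 * 2.5) * dt)

    def test_amplitude_is_peak_minus_threshold(self):
        ev = self._single_region(np.array([2.5, 3.0, 2.5]), 2.0)
        assert ev["amplitude"][0] == pytest.approx(1.0)

    def test_duration_48_samples(self):
        ev = self._single_region(np.full(48, 3.0), 2.0)
        assert ev["duration_ms"][0] == pytest.approx(46.875)

    def test_duration_single_sample(self):
        ev = self._single_region(np.array([3.0]), 2.0)
        assert ev["duration_ms"][0] == pytest.approx(1000.0 / 1024.0)


class TestReferenceTimes:
    def test_stop_reference_and_window(self):
        ref, ok = bursts.reference_time_stop(600.0, 210.0)
        assert ref == 810.0 and ok
        assert bursts.bin_edges(ref)[0] == pytest.approx(497.5)

    def test_ssd_cap_is_strict(self):
        assert bursts.reference_time_stop(750.0, 200.0)[1] is False
        assert bursts.reference_time_stop(700.0, 200.0)[1] is True

    def test_missing_ssrt_rejected(self):
        with pytest.raises(ValueError):
            bursts.reference_time_stop(600.0, float("nan"))

    def test_go_reference_is_earliest_lift(self):
        assert bursts.reference_time_go(835.0, 820.0) == 820.0
        assert bursts.reference_time_go(800.0, 800.0) == 800.0

    def test_go_missing_lift_rejected(self):
        with pytest.raises(ValueError):
            bursts.reference_time_go(float("nan"), 820.0)


class TestBinning:
    def test_bin_assignment_conventions(self):
        ref = 800.0
        assert bursts.assign_bin(795.0, ref) == 9     # 5 ms before ref
        assert bursts.assign_bin(488.0, ref) == 0     # 312 ms before ref
        # interior edge -> later bin (left-closed)
        assert bursts.assign_bin(800.0 - 31.25, ref) == 9
        assert bursts.assign_bin(800.0, ref) == -1    # at reference: outside
        assert bursts.assign_bin(400.0, ref) == -1    # before window

    def test_rate_sum_matches_in_window_events(self, rng):
        ref = 700.0
        t = _times()
        peaks = rng.uniform(300.0, 750.0, size=30)
        events = pd.DataFrame({
            "peak_time_ms": peaks,
            "volume": np.ones(30), "amplitude": np.ones(30),
            "duration_ms": np.ones(30)})
        db = np.zeros((15, len(t)))
        valid = np.ones_like(db, bool)
        row = bursts.bin_trial_features(events, db, valid, t, ref)
        in_window = ((peaks >= ref - 312.5) & (peaks < ref)).sum()
        assert row["rate"].sum() == in_window
        # rate = 0 implies zero volume in that cell
        zero_bins = row[row["rate"] == 0]
        assert (zero_bins["volume"] == 0).all()

    def test_window_outside_valid_region_excluded(self):
        t = _times()
        db = np.zeros((15, len(t)))
        valid = np.zeros_like(db, bool)
        valid[:, 600:] = True
        events = pd.DataFrame(columns=["peak_time_ms", "volume",
                                       "amplitude", "duration_ms"])
        # reference early enough that the window touches invalid samples
        assert bursts.bin_trial_features(events, db, valid, t, 200.0) is None

    def test_binned_power_is_mean_db(self):
        t = _times()
        db = np.full((15, len(t)), 1.5)
        valid = np.ones_like(db, bool)
        events = pd.DataFrame(columns=["peak_time_ms", "volume",
                                       "amplitude", "duration_ms"])
        row = bursts.bin_trial_features(events, db, valid, t, 800.0)
        np.testing.assert_allclose(row["power"], 1.5)


class TestRecovery:
    def test_injected_bursts_recovered(self):
        """>=90% of strong injected events found within +/-15 ms / +/-2 Hz."""
        sfreq = 1024.0
        t = _times(sfreq)
        rng = np.random.default_rng(2)
        n_trials = 40
        found, total = 0, 0
        sig = np.empty((1, len(t), n_trials))
        inj = []
        for j in range(n_trials):
            t0 = rng.uniform(100.0, 600.0)
            f0 = rng.choice([17.0, 20.0, 24.0])
            noise = simulate.one_over_f_noise(1, len(t), sfreq, 1.0, 1.0,
                                              rng)[0]
            sig[0, :, j] = noise + simulate.burst_kernel(t, t0, f0, 4.0)
            inj.append((t0, f0))
        tf = timefreq.tf_power(sig, sfreq, t)
        for j, (t0, f0) in enumerate(inj):
            pmap = tf.power[0, :, :, j]
            thr = bursts.burst_threshold(pmap, tf.valid)
            ev = bursts.detect_bursts(pmap, thr, tf.valid, t,
                                      tf.frequencies, sfreq)
            total += 1
            hit = ((np.abs(ev["peak_time_ms"] - t0) <= 15.0)
                   & (np.abs(ev["peak_freq_hz"] - f0) <= 2.0)).any()
            found += bool(hit)
        assert found / total >= 0.9
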