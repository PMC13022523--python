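"""EMG preprocessing, burst detection/classification and CancelTime."""

import numpy as np
import pandas as pd
import pytest

from stopburst import emg, simulate

SFREQ = 1024.0
TIMES = np.arange(1024) / SFREQ * 1000.0


def _noise_trace(rng, sd=2.5):
    return sd * rng.standard_normal(len(TIMES))


class TestPreprocess:
    def test_rectification_of_negative_constant(self):
        out = emg.preprocess_emg(np.full(100, -5.0), SFREQ)
        np.testing.assert_allclose(out, 5.0)

    def test_zero_in_zero_out(self):
        assert np.all(emg.preprocess_emg(np.zeros(100), SFREQ) == 0)

    def test_impulse_spreads_over_window(self):
        x = np.zeros(200)
        x[100] = 10.0
        out = emg.preprocess_emg(x, SFREQ, smooth_ms=10.0)
        win = int(round(10.0 / 1000.0 * SFREQ))
        assert out.max() == pytest.approx(10.0 / win)
        assert (out > 0).sum() == win


class TestBaselineExclusion:
    @pytest.mark.parametrize("level,dropped", [(31.0, True), (30.0, False),
                                               (5.0, False)])
    def test_rms_rule_strict(self, level, dropped):
        trace = np.full(len(TIMES), level)
        assert emg.exclude_high_baseline(trace, TIMES) is dropped


class TestDetect:
    def _trace_with_runs(self, runs, level=100.0):
        """Baseline noise + rectangular suprathreshold runs (ms spans)."""
        rng = np.random.default_rng(0)
        tr = np.abs(_noise_trace(rng, 1.0))
        for lo, hi in runs:
            tr[(TIMES >= lo) & (TIMES <= hi)] = level
        return tr

    def test_gap_below_15ms_merged(self):
        tr = self._trace_with_runs([(500, 520), (530, 560)])
        b = emg.detect_emg_bursts(tr, TIMES, SFREQ)
        assert len(b) == 1
        assert b["onset_ms"][0] == pytest.approx(500, abs=2)
        assert b["offset_ms"][0] == pytest.approx(560, abs=2)

    def test_gap_above_15ms_kept_separate(self):
        tr = self._trace_with_runs([(500, 520), (545, 560)])
        b = emg.detect_emg_bursts(tr, TIMES, SFREQ)
        assert len(b) == 2

    def test_run_shorter_than_5ms_discarded(self):
        tr = self._trace_with_runs([(500, 503)])
        b = emg.detect_emg_bursts(tr, TIMES, SFREQ)
        assert len(b) == 0

    def test_merge_closure_property(self, rng):
        """All output bursts are pairwise separated by >= 15 ms."""
        for _ in range(20):
            spans = np.sort(rng.uniform(450, 950, size=8))
            runs = [(spans[i], spans[i] + rng.uniform(2, 30))
                    for i in range(0, 8, 2)]
            tr = self._trace_with_runs(runs)
            b = emg.detect_emg_bursts(tr, TIMES, SFREQ)
            gaps = b["onset_ms"].to_numpy()[1:] - b["offset_ms"].to_numpy()[:-1]
            assert np.all(gaps >= 15.0 - 1e-9)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            emg.detect_emg_bursts(np.ones(len(TIMES)), TIMES, SFREQ)


class TestRefine:
    def test_step_onset_found_within_window(self):
        rng = np.random.default_rng(1)
        tr = np.abs(_noise_trace(rng, 1.0))
        m, s, _ = emg.baseline_stats(tr, TIMES)
        tr[TIMES >= 600.0] = m + 20 * s
        on, off = emg.refine_onset_single_threshold(
            tr, TIMES, SFREQ, 610.0, 900.0, m, s)
        assert on <= 610.0                       # never later than coarse
        assert abs(on - 600.0) <= 25.0

    def test_flat_trace_falls_back_to_coarse(self):
        tr = np.zeros(len(TIMES))
        on, off = emg.refine_onset_single_threshold(
            tr, TIMES, SFREQ, 600.0, 700.0, 0.0, 1.0)
        assert on == 600.0 and off == 700.0


class TestClassify:
    def _bursts(self, onsets_peaks):
        return pd.DataFrame([{"onset_ms": o, "offset_ms": o + 40,
                              "peak_time_ms": p, "peak_amplitude": 50.0}
                             for o, p in onsets_peaks])

    def test_go_main_is_last_before_release(self):
        b = self._bursts([(600, 620), (790, 810)])
        out = emg.classify_bursts(b, "Go", 820.0, False, 830.0, 20.0)
        assert list(out["cls"]) == ["premature", "main"]

    def test_go_partition_and_single_main(self):
        b = self._bursts([(500, 510), (600, 620), (790, 810), (900, 930)])
        out = emg.classify_bursts(b, "Go", 820.0, False, 830.0, 20.0)
        assert (out["cls"] == "main").sum() == 1
        before = out[out["onset_ms"] < 820.0]
        assert set(before["cls"]) <= {"main", "premature"}

    def test_stop_partial_window(self):
        b = self._bursts([(780, 800)])
        out = emg.classify_bursts(b, "Stop", None, True, 830.0, 20.0)
        assert out["cls"][0] == "partial"      # window [770, 890]

    def test_stop_outside_window_unclassified(self):
        b = self._bursts([(680, 700)])
        out = emg.classify_bursts(b, "Stop", None, True, 830.0, 20.0)
        assert out["cls"][0] == "unclassified"

    def test_go_lift_without_emg_flagged(self):
        b = self._bursts([(900, 920)])
        out = emg.classify_bursts(b, "Go", 820.0, False, 830.0, 20.0)
        assert (out["flag"] == "lift_without_emg").all()


class TestCancelTime:
    def test_difference(self):
        ct, neg = emg.cancel_time(700.0, 560.0)
        assert ct == 140.0 and not neg

    def test_negative_flagged(self):
        ct, neg = emg.cancel_time(540.0, 560.0)
        assert ct == -20.0 and neg


class TestIncidence:
    def _table(self, trial_classes):
        rows = [{"trial": t, "cls": c} for t, c in trial_classes]
        return pd.DataFrame(rows, columns=["trial", "cls"])

    def _trials(self, n):
        return pd.DataFrame({"trial": range(n), "type": ["Go"] * n,
                             "stop_success": [np.nan] * n})

    def test_fraction(self):
        table = self._table([(0, "premature"), (3, "premature")])
        assert emg.burst_incidence(table, self._trials(10), "premature",
                                   "Go") == 20.0

    def test_zero_and_full(self):
        empty = self._table([])
        assert emg.burst_incidence(empty, self._trials(5), "premature",
                                   "Go") == 0.0
        full = self._table([(t, "premature") for t in range(5)])
        assert emg.burst_incidence(full, self._trials(5), "premature",
                                   "Go") == 100.0

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            emg.burst_incidence(self._table([]), self._trials(0),
                                "premature", "Go")


class TestRecovery:
    def test_injected_bursts_and_cancel_time(self):
        """Strong injected bursts are all found; CancelTime matches the
        ground-truth peak - SSD within the smoothing tolerance."""
        rng = np.random.default_rng(4)
        noise_sd = 2.5
        n_ok, n_tot, ct_ok = 0, 0, 0
        for _ in range(40):
            ssd = rng.uniform(500, 650)
            peak = ssd + rng.normal(140.0, 10.0)
            raw = simulate.generate_emg_trace(
                TIMES, noise_sd, [(peak, 60.0, 15.0, rng.uniform(0, 6.28))],
                rng)
            tr = emg.preprocess_emg(raw, SFREQ)
            b = emg.detect_emg_bursts(tr, TIMES, SFREQ)
            n_tot += 1
            if len(b) == 1:
                n_ok += 1
                ct, _ = emg.cancel_time(b["peak_time_ms"][0], ssd)
                if abs(ct - (peak - ssd)) <= 5.0:
                    ct_ok += 1
        assert n_ok / n_tot >= 0.95
        assert ct_ok / n_ok >= 0.95
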