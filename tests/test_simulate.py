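"""Synthetic data generator: determinism, superposition, staircase, logs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from stopburst import simulate
from stopburst.config import ConfigError, InjectedBurstSpec, SimulationConfig


class TestDeterminism:
    def test_same_config_same_seed_identical(self, small_sim_config):
        d1 = simulate.generate_dataset(small_sim_config)
        d2 = simulate.generate_dataset(small_sim_config)
        pid = list(d1.eeg)[0]
        np.testing.assert_array_equal(d1.eeg[pid].data, d2.eeg[pid].data)
        np.testing.assert_array_equal(d1.emg[pid].data, d2.emg[pid].data)
        pd.testing.assert_frame_equal(d1.trials, d2.trials)
        pd.testing.assert_frame_equal(d1.ground_truth.eeg_bursts,
                                      d2.ground_truth.eeg_bursts)

    def test_participants_independently_regenerable(self, small_sim_config):
        full = simulate.generate_dataset(small_sim_config)
        ep, _, tr, _ = simulate.generate_participant(small_sim_config, 1)
        pid = tr["participant"].iloc[0]
        np.testing.assert_array_equal(full.eeg[pid].data, ep.data)

    def test_zero_rate_gives_empty_burst_log(self, small_sim_config):
        cfg = dataclasses.replace(
            small_sim_config,
            burst_spec=[dataclasses.replace(small_sim_config.burst_spec[0],
                                            rate=0.0)])
        d = simulate.generate_dataset(cfg)
        assert len(d.ground_truth.eeg_bursts) == 0


class TestTrialStructure:
    def test_counts_and_ratio(self):
        cfg = SimulationConfig(n_participants=2, n_go_trials=320,
                               n_stop_trials=160, burst_spec=[],
                               random_seed=1)
        trials = simulate.generate_behavior(
            cfg, np.random.default_rng(0), "P01")
        assert len(trials) == 480
        assert (trials["type"] == "Go").mean() == pytest.approx(2 / 3)

    def test_every_stop_trial_has_ssd(self, small_sim_config):
        d = simulate.generate_dataset(small_sim_config)
        stop = d.trials[d.trials["type"] == "Stop"]
        assert stop["ssd_ms"].notna().all()
        assert d.trials.loc[d.trials["type"] == "Go", "ssd_ms"].isna().all()

    def test_invalid_counts_rejected(self):
        cfg = SimulationConfig(n_go_trials=0)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_burst_frequency_outside_beta_rejected(self):
        with pytest.raises(ConfigError):
            InjectedBurstSpec(channels=("Cz",), frequency=35.0).validate()


class TestEEGGeneration:
    def test_zero_events_zero_noise_is_silence(self):
        t = np.arange(512) / 1024.0 * 1000.0
        out = simulate.generate_eeg_epoch(3, t, 1024.0, 1.0, 0.0, [],
                                          np.random.default_rng(0))
        assert np.all(out == 0)

    def test_kernel_peak_near_requested_time(self):
        t = -500.0 + np.arange(1536) / 1024.0 * 1000.0
        out = simulate.generate_eeg_epoch(
            1, t, 1024.0, 1.0, 0.0, [(0, 500.0, 20.0, 5.0, 0.0)],
            np.random.default_rng(0))
        env_peak = t[np.argmax(np.abs(out[0]))]
        assert abs(env_peak - 500.0) <= 25.0

    def test_superposition(self):
        t = -500.0 + np.arange(1536) / 1024.0 * 1000.0
        a = [(0, 300.0, 18.0, 2.0, 0.0)]
        b = [(0, 700.0, 25.0, 3.0, 0.5)]
        args = (1, t, 1024.0, 1.0, 0.0)
        rng = np.random.default_rng
        ta = simulate.generate_eeg_epoch(*args, a, rng(0))
        tb = simulate.generate_eeg_epoch(*args, b, rng(0))
        tab = simulate.generate_eeg_epoch(*args, a + b, rng(0))
        np.testing.assert_allclose(tab, ta + tb, atol=1e-12)

    def test_event_outside_epoch_rejected(self):
        t = np.arange(512) / 1024.0 * 1000.0
        with pytest.raises(ValueError, match="outside epoch"):
            simulate.generate_eeg_epoch(1, t, 1024.0, 1.0, 1.0,
                                        [(0, 2000.0, 20.0, 1.0, 0.0)],
                                        np.random.default_rng(0))

    def test_ground_truth_marginal_counts(self, small_sim_config):
        d = simulate.generate_dataset(small_sim_config)
        log = d.ground_truth.eeg_bursts
        spec = small_sim_config.burst_spec[0]
        # every logged event is on a channel the spec lists
        assert set(log["channel"]) <= set(spec.channels)
        # expected count: rate x trials x participants per channel
        n_trials = len(d.trials)
        expected = spec.rate * n_trials
        for ch in spec.channels:
            n = (log["channel"] == ch).sum()
            assert n == pytest.approx(expected,
                                      abs=4 * np.sqrt(expected) + 1)


class TestEMGGeneration:
    def test_noise_rms_matches_sd(self):
        t = np.arange(1024) / 1024.0 * 1000.0
        tr = simulate.generate_emg_trace(t, 1.0, [],
                                         np.random.default_rng(1))
        rms = np.sqrt((tr ** 2).mean())
        assert rms == pytest.approx(1.0, rel=0.2)

    def test_burst_peak_recorded_at_requested_time(self, small_sim_config):
        d = simulate.generate_dataset(small_sim_config)
        log = d.ground_truth.emg_bursts
        mains = log[log["cls"] == "main"]
        merged = mains.merge(d.trials, on=["participant", "trial"])
        # main bursts peak at the recorded lift-time of their hand
        for hand in ("left", "right"):
            sub = merged[merged["hand"] == hand]
            np.testing.assert_allclose(sub["peak_ms"],
                                       sub[f"lift_{hand}_ms"], atol=1e-9)

    def test_width_must_be_positive(self):
        t = np.arange(100) / 1024.0 * 1000.0
        with pytest.raises(ValueError, match="width"):
            simulate.generate_emg_trace(t, 0.0, [(50.0, 1.0, 0.0, 0.0)],
                                        np.random.default_rng(0))


class TestStaircase:
    def test_update_rule(self):
        assert simulate.staircase_update(500.0, True, 25.0, (100, 775)) == 525.0
        assert simulate.staircase_update(500.0, False, 25.0, (100, 775)) == 475.0
        assert simulate.staircase_update(770.0, True, 25.0, (100, 775)) == 775.0

    def test_ssd_sequence_follows_rule(self, behavior_config):
        trials = simulate.generate_behavior(
            behavior_config, np.random.default_rng(5), "P01")
        stop = trials[trials["type"] == "Stop"].reset_index(drop=True)
        step = behavior_config.staircase_step
        lo, hi = behavior_config.staircase_bounds
        for k in range(len(stop) - 1):
            expect = stop.loc[k, "ssd_ms"] + \
                (step if stop.loc[k, "stop_success"] else -step)
            assert stop.loc[k + 1, "ssd_ms"] == np.clip(expect, lo, hi)

    def test_convergence_to_50_percent(self):
        cfg = SimulationConfig(n_participants=1, n_go_trials=1000,
                               n_stop_trials=500, burst_spec=[],
                               random_seed=11)
        trials = simulate.generate_behavior(cfg, np.random.default_rng(11))
        rate = trials.loc[trials["type"] == "Stop",
                          "stop_success"].astype(bool).mean()
        assert abs(rate - 0.5) <= 0.05

    def test_lift_times_exact_with_zero_sd(self):
        cfg = SimulationConfig(n_participants=1, n_go_trials=10,
                               n_stop_trials=5, lift_sd=0.0,
                               lift_mean_offset=35.0, burst_spec=[],
                               random_seed=0)
        with pytest.MonkeyPatch.context() as mp:
            mp.setattr(simulate, "HAND_JITTER_SD", 0.0)
            trials = simulate.generate_behavior(cfg,
                                                np.random.default_rng(0))
        go = trials[trials["type"] == "Go"]
        np.testing.assert_allclose(go["lift_left_ms"], 835.0)
        np.testing.assert_allclose(go["lift_right_ms"], 835.0)
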