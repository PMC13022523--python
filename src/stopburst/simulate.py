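"""Synthetic EEG / EMG / behavior generator with a ground-truth record.

Everything the analysis assumes is emulated with known ground truth:

* EEG epochs = 1/f^alpha background noise plus real Morlet-kernel transients
  injected at chosen channels, latencies (relative to each trial's reference
  time) and beta frequencies, with condition-dependent rates.
* EMG epochs = baseline white noise plus Gaussian-envelope bursts carrying a
  150 Hz sinusoidal carrier (so rectification and smoothing are exercised):
  a main burst generating the lift, optional premature bursts on Go trials
  and partial bursts on successful Stop trials.
* Behavior: per-hand lift-times drawn around the 800 ms target, stop-trial
  outcomes from an independent-race rule against a known true SSRT, and a
  staircased SSD sequence converging to ~50% stop success.

One global seed spawns per-participant child seeds, so any participant can
be regenerated independently and the whole dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from . import timefreq

HANDS = ("left", "right")
#: SD (ms) of the per-hand jitter around the common bimanual lift-time.
HAND_JITTER_SD = 4.0


@dataclass
class EpochSet:
    """Epoched multichannel EEG: channels x samples x trials."""

    data: np.ndarray
    channels: list[str]
    positions: np.ndarray              # (n_ch, 2)
    sfreq: float
    times_ms: np.ndarray               # per-sample, relative to indicator rise

    def __post_init__(self):
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")


@dataclass
class EMGEpochs:
    """Per-trial EMG: trials x hands x samples, uV."""

    data: np.ndarray
    sfreq: float
    times_ms: np.ndarray
    hands: tuple[str, ...] = HANDS


@dataclass
class GroundTruth:
    """What was injected, for recovery checks downstream."""

    eeg_bursts: pd.DataFrame           # participant, trial, channel, time_ms, frequency, amplitude
    emg_bursts: pd.DataFrame           # participant, trial, hand, cls, peak_ms, amplitude, width_ms
    true_ssrt: float
    reference_ms: pd.DataFrame         # participant, trial, reference_ms


@dataclass
class SimulatedDataset:
    eeg: dict[str, EpochSet]
    emg: dict[str, EMGEpochs]
    trials: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# low-level signal generators
# ---------------------------------------------------------------------------

def one_over_f_noise(n_channels: int, n_samples: int, sfreq: float,
                     exponent: float, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha background noise, shaped in the frequency domain and scaled
    to the requested time-domain SD per channel."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    x_sd = x.std(axis=1, keepdims=True)
    x_sd[x_sd == 0] = 1.0
    return x / x_sd * sd


def burst_kernel(times_ms: np.ndarray, time_ms: float, frequency: float,
                 amplitude: float, phase: float = 0.0) -> np.ndarray:
    """Real Morlet-shaped transient: Gaussian envelope x cosine carrier.

    The envelope SD matches the analysis wavelet at that frequency
    (sigma_t = n_cycles / (2 pi f), cycles interpolated from the beta cycle
    vector), so injected events look exactly like what the decomposition is
    tuned to find.
    """
    n_cycles = float(np.interp(frequency, timefreq.beta_frequencies(),
                               timefreq.beta_cycles()))
    sigma_ms = n_cycles / (2.0 * np.pi * frequency) * 1000.0
    dt = times_ms - time_ms
    return amplitude * np.exp(-dt ** 2 / (2 * sigma_ms ** 2)) * \
        np.cos(2 * np.pi * frequency * dt / 1000.0 + phase)


def generate_eeg_epoch(n_channels: int, times_ms: np.ndarray, sfreq: float,
                       background_exponent: float, background_sd: float,
                       events: list[tuple], rng: np.random.Generator
                       ) -> np.ndarray:
    """One trial of synthetic EEG: noise + linear superposition of events.

    ``events`` is a list of (channel_index, time_ms, frequency_hz,
    amplitude, phase). Event times must lie inside the epoch.
    """
    trace = one_over_f_noise(n_channels, len(times_ms), sfreq,
                             background_exponent, background_sd, rng)
    for ch, t0, f, a, phase in events:
        if not times_ms[0] <= t0 <= times_ms[-1]:
            raise ValueError(f"event at {t0} ms outside epoch "
                             f"[{times_ms[0]}, {times_ms[-1]}] ms")
        trace[ch] += burst_kernel(times_ms, t0, f, a, phase)
    return trace


def generate_emg_trace(times_ms: np.ndarray, noise_sd: float,
                       bursts: list[tuple], rng: np.random.Generator,
                       carrier_freq: float = 150.0) -> np.ndarray:
    """One EMG trace: white noise + Gaussian-envelope carrier bursts.

    ``bursts`` is a list of (peak_ms, amplitude_uv, width_ms, phase); width
    is the envelope SD. The carrier sits inside the 50-450 Hz band the
    recording hardware passes.
    """
    trace = noise_sd * rng.standard_normal(len(times_ms)) if noise_sd > 0 \
        else np.zeros(len(times_ms))
    for peak, amp, width, phase in bursts:
        if width <= 0:
            raise ValueError("burst width must be positive")
        dt = times_ms - peak
        trace += amp * np.exp(-dt ** 2 / (2 * width ** 2)) * \
            np.sin(2 * np.pi * carrier_freq * dt / 1000.0 + phase)
    return trace


def calibrate_burst_amplitude(target_ratio: float, frequency: float,
                              config: SimulationConfig,
                              n_probe: int = 8, seed: int = 12345) -> float:
    """Amplitude (in background-SD units) at which an injected kernel's peak
    wavelet power is ``target_ratio`` times the median beta power of the
    background noise.

    Computed from first principles at run time: the unit-amplitude kernel's
    peak power on a noiseless epoch, and the background median over a few
    probe epochs with a fixed probe seed. Power scales with amplitude^2.
    """
    times = epoch_times(config)
    rng = np.random.default_rng(seed)
    bg = one_over_f_noise(n_probe, len(times), config.sampling_rate,
                          config.background_exponent, config.background_sd,
                          rng)
    tf_bg = timefreq.tf_power(bg[:, :, None], config.sampling_rate, times)
    med = np.median(tf_bg.power[:, tf_bg.valid, :])
    kern = burst_kernel(times, float(times[len(times) // 2]), frequency, 1.0)
    tf_k = timefreq.tf_power(kern[None, :, None], config.sampling_rate, times)
    peak = tf_k.power[0][tf_k.valid].max()
    return float(np.sqrt(target_ratio * med / peak))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def staircase_update(ssd: float, success: bool, step: float,
                     bounds: tuple[float, float]) -> float:
    """Adaptive SSD rule: success makes the next Stop harder (+step, the
    indicators stop later), failure easier (-step)."""
    nxt = ssd + step if success else ssd - step
    return float(np.clip(nxt, *bounds))


def generate_behavior(config: SimulationConfig, rng: np.random.Generator,
                      participant: str = "P01") -> pd.DataFrame:
    """One participant's trial table.

    Go and Stop trials are interleaved in random order. Lift-times are a
    common bimanual component Normal(target + offset, lift_sd) plus small
    per-hand jitter. Stop outcome follows an independent race: the stop
    process (SSD + true SSRT) beats the earliest would-be lift, or not.
    Successful Stops have no lift-times; failed Stops record them.
    """
    if config.n_go_trials <= 0 or config.n_stop_trials <= 0:
        raise ConfigError("trial counts must be positive")
    n = config.n_go_trials + config.n_stop_trials
    types = np.array(["Go"] * config.n_go_trials + ["Stop"] * config.n_stop_trials)
    rng.shuffle(types)
    ssd = config.staircase_start_ssd
    rows = []
    for i, tt in enumerate(types):
        common = rng.normal(config.target_time + config.lift_mean_offset,
                            config.lift_sd)
        left = common + rng.normal(0, HAND_JITTER_SD)
        right = common + rng.normal(0, HAND_JITTER_SD)
        if tt == "Go":
            rows.append((participant, i, "Go", left, right, np.nan, np.nan))
        else:
            success = min(left, right) > ssd + config.true_ssrt
            rows.append((participant, i, "Stop",
                         np.nan if success else left,
                         np.nan if success else right,
                         ssd, success))
            ssd = staircase_update(ssd, success, config.staircase_step,
                                   config.staircase_bounds)
    df = pd.DataFrame(rows, columns=["participant", "trial", "type",
                                     "lift_left_ms", "lift_right_ms",
                                     "ssd_ms", "stop_success"])
    df["stop_success"] = df["stop_success"].astype("boolean")
    return df


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def epoch_times(config: SimulationConfig) -> np.ndarray:
    n = int(round((config.epoch_end - config.epoch_start)
                  / 1000.0 * config.sampling_rate))
    return config.epoch_start + np.arange(n) / config.sampling_rate * 1000.0


def emg_times(config: SimulationConfig) -> np.ndarray:
    """EMG epochs span 0-1000 ms from the indicator rise."""
    n = int(round(1.0 * config.sampling_rate))
    return np.arange(n) / config.sampling_rate * 1000.0


def trial_reference(row: pd.Series, true_ssrt: float) -> float:
    """The per-trial time the analysis window ends at: earliest lift on Go
    (and failed-Stop) trials, SSD + SSRT on successful Stops."""
    if row["type"] == "Stop" and row["stop_success"]:
        return float(row["ssd_ms"] + true_ssrt)
    return float(np.nanmin([row["lift_left_ms"], row["lift_right_ms"]]))


def generate_participant(config: SimulationConfig, index: int,
                         participant: str | None = None
                         ) -> tuple[EpochSet, EMGEpochs, pd.DataFrame, GroundTruth]:
    """Generate one participant (EEG, EMG, behavior, ground truth).

    ``index`` selects the participant's child seed from the global seed, so
    participants are independent and individually reproducible.
    """
    config.validate()
    # stateless child seed: participants are regenerable independently
    child = np.random.SeedSequence(config.random_seed, spawn_key=(index,))
    rng = np.random.default_rng(child)
    pid = participant or f"P{index + 1:02d}"

    trials = generate_behavior(config, rng, pid)
    times = epoch_times(config)
    t_emg = emg_times(config)
    channels = list(config.channel_layout)
    positions = np.array([config.channel_layout[c] for c in channels], float)
    ch_index = {c: i for i, c in enumerate(channels)}
    n_trials = len(trials)

    eeg = np.empty((len(channels), len(times), n_trials))
    emg = np.empty((n_trials, len(HANDS), len(t_emg)))
    eeg_log, emg_log, refs = [], [], []
    es = config.emg_spec

    for i, (_, row) in enumerate(trials.iterrows()):
        ref = trial_reference(row, config.true_ssrt)
        refs.append((pid, row["trial"], ref))
        cond = "Stop" if row["type"] == "Stop" else "Go"

        # --- EEG events
        events = []
        for spec in config.burst_spec:
            if spec.condition not in ("both", cond):
                continue
            for ch in spec.channels:
                if ch not in ch_index:
                    continue
                for _ in range(rng.poisson(spec.rate)):
                    lo, hi = spec.latency_window
                    t0 = ref + rng.uniform(lo, hi) + rng.normal(0, spec.jitter)
                    t0 = float(np.clip(t0, times[0] + 1, times[-1] - 1))
                    phase = rng.uniform(0, 2 * np.pi)
                    events.append((ch_index[ch], t0, spec.frequency,
                                   spec.amplitude * config.background_sd, phase))
                    eeg_log.append((pid, row["trial"], ch, t0,
                                    spec.frequency,
                                    spec.amplitude * config.background_sd))
        eeg[:, :, i] = generate_eeg_epoch(
            len(channels), times, config.sampling_rate,
            config.background_exponent, config.background_sd, events, rng)

        # --- EMG bursts
        responded = not (row["type"] == "Stop" and row["stop_success"])
        premature_t = None
        if row["type"] == "Go" and rng.random() < es.p_premature:
            premature_t = ref - rng.uniform(*es.premature_lead_range)
        partial_t = None
        if row["type"] == "Stop" and row["stop_success"] and \
                rng.random() < es.p_partial:
            partial_t = row["ssd_ms"] + rng.normal(es.cancel_time_mean,
                                                   es.cancel_time_sd)
        for h, hand in enumerate(HANDS):
            bursts = []
            if responded:
                lift = row[f"lift_{hand}_ms"]
                if t_emg[0] < lift < t_emg[-1]:
                    bursts.append((float(lift), es.main_amplitude,
                                   es.main_width, rng.uniform(0, 2 * np.pi)))
                    emg_log.append((pid, row["trial"], hand, "main",
                                    float(lift), es.main_amplitude,
                                    es.main_width))
            if premature_t is not None and t_emg[0] < premature_t < t_emg[-1]:
                bursts.append((float(premature_t), es.premature_amplitude,
                               es.premature_width, rng.uniform(0, 2 * np.pi)))
                emg_log.append((pid, row["trial"], hand, "premature",
                                float(premature_t), es.premature_amplitude,
                                es.premature_width))
            if partial_t is not None and t_emg[0] < partial_t < t_emg[-1]:
                bursts.append((float(partial_t), es.partial_amplitude,
                               es.partial_width, rng.uniform(0, 2 * np.pi)))
                emg_log.append((pid, row["trial"], hand, "partial",
                                float(partial_t), es.partial_amplitude,
                                es.partial_width))
            emg[i, h] = generate_emg_trace(t_emg, es.noise_sd, bursts, rng,
                                           es.carrier_freq)

    cols_e = ["participant", "trial", "channel", "time_ms", "frequency",
              "amplitude"]
    cols_m = ["participant", "trial", "hand", "cls", "peak_ms", "amplitude",
              "width_ms"]
    gt = GroundTruth(
        eeg_bursts=pd.DataFrame(eeg_log, columns=cols_e),
        emg_bursts=pd.DataFrame(emg_log, columns=cols_m),
        true_ssrt=config.true_ssrt,
        reference_ms=pd.DataFrame(refs, columns=["participant", "trial",
                                                 "reference_ms"]),
    )
    epochs = EpochSet(eeg, channels, positions, config.sampling_rate, times)
    emg_ep = EMGEpochs(emg, config.sampling_rate, t_emg)
    return epochs, emg_ep, trials, gt


def generate_dataset(config: SimulationConfig, seed: int | None = None
                     ) -> SimulatedDataset:
    """All participants. Identical (config, seed) gives identical output."""
    if seed is not None:
        config = dataclass_replace_seed(config, seed)
    config.validate()
    eeg, emg, tables, gts = {}, {}, [], []
    for idx in range(config.n_participants):
        ep, em, tr, gt = generate_participant(config, idx)
        pid = tr["participant"].iloc[0]
        eeg[pid], emg[pid] = ep, em
        tables.append(tr)
        gts.append(gt)
    trials = pd.concat(tables, ignore_index=True)
    gt_all = GroundTruth(
        eeg_bursts=pd.concat([g.eeg_bursts for g in gts], ignore_index=True),
        emg_bursts=pd.concat([g.emg_bursts for g in gts], ignore_index=True),
        true_ssrt=config.true_ssrt,
        reference_ms=pd.concat([g.reference_ms for g in gts],
                               ignore_index=True),
    )
    return SimulatedDataset(eeg=eeg, emg=emg, trials=trials,
                            ground_truth=gt_all)


def dataclass_replace_seed(config: SimulationConfig,
                           seed: int) -> SimulationConfig:
    import dataclasses
    return dataclasses.replace(config, random_seed=int(seed))


def true_rate_effect(config: SimulationConfig, n_bins: int = 10,
                     bin_ms: float = 31.25) -> np.ndarray:
    """Expected Stop-minus-Go injected-burst rate per channel x bin.

    The bins cover [-n_bins*bin_ms, 0) ms relative to the reference time;
    each spec contributes rate x (overlap of its latency window with the
    bin) / (window length), per listed channel, signed by condition.
    """
    channels = list(config.channel_layout)
    out = np.zeros((len(channels), n_bins))
    edges = -n_bins * bin_ms + bin_ms * np.arange(n_bins + 1)
    for spec in config.burst_spec:
        if spec.condition == "both":
            continue
        sign = 1.0 if spec.condition == "Stop" else -1.0
        lo, hi = spec.latency_window
        for b in range(n_bins):
            ov = max(0.0, min(hi, edges[b + 1]) - max(lo, edges[b]))
            frac = ov / (hi - lo)
            for ch in spec.channels:
                if ch in channels:
                    out[channels.index(ch), b] += sign * spec.rate * frac
    return out


# ---------------------------------------------------------------------------
# statistics-level generator (binned burst rates)
# ---------------------------------------------------------------------------

def simulate_binned_rates(n_participants: int, n_trials_per_cond: int,
                          n_channels: int, n_bins: int,
                          rng: np.random.Generator,
                          baseline_rate: float = 0.23,
                          intercept_sd: float = 0.05,
                          effect: float = 0.0,
                          effect_channels: tuple[int, ...] = (),
                          effect_bins: tuple[int, ...] = (),
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial binned burst counts with participant random intercepts.

    Counts are Poisson with mean baseline_rate + intercept_i, plus ``effect``
    added on Stop trials at the (effect_channels x effect_bins) cells. The
    0.23 default matches typical per-bin burst rates in this paradigm.

    Returns (Y, X, groups, true_mask): Y is (points x trials) with points
    ordered channel-major; X is (trials x 2) with an intercept and a
    Go=-1/Stop=+1 effects-coded predictor; groups is the participant index
    per trial; true_mask is the (channels x bins) boolean effect map.
    """
    n_points = n_channels * n_bins
    n_trials = 2 * n_trials_per_cond * n_participants
    Y = np.empty((n_points, n_trials))
    X = np.empty((n_trials, 2))
    groups = np.empty(n_trials, dtype=np.int64)
    true_mask = np.zeros((n_channels, n_bins), bool)
    for c in effect_channels:
        for b in effect_bins:
            true_mask[c, b] = True
    eff_flat = true_mask.reshape(-1).astype(float) * effect
    col = 0
    for p in range(n_participants):
        a_p = rng.normal(0.0, intercept_sd)
        code = np.repeat([-1.0, 1.0], n_trials_per_cond)
        rng.shuffle(code)
        for x in code:
            mu = np.full(n_points, baseline_rate + a_p)
            if x > 0:
                mu += eff_flat
            Y[:, col] = rng.poisson(np.maximum(mu, 0.0))
            X[col] = (1.0, x)
            groups[col] = p
            col += 1
    return Y, X, groups, true_mask
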