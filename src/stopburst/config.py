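"""Configuration objects for the simulation and analysis pipeline.

Defaults follow the study conditions of a bimanual anticipatory response
inhibition task (ARIT): 320 Go / 160 Stop trials per participant (2:1 ratio),
1,024 Hz sampling, an 800 ms rising-indicator target, a staircased stop-signal
delay (SSD), beta-band (15-29 Hz) burst detection at 2x the trial median
power, and the EMG burst rules (15 SD baseline threshold, >=5 ms duration,
<15 ms merge gap, 30 uV baseline-rms trial exclusion).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a configuration is internally inconsistent."""


def default_channel_layout() -> dict[str, tuple[float, float]]:
    """A 16-channel schematic scalp montage (label -> 2D position).

    Positions are on a unit head circle, x to the right, y to the front.
    The montage covers frontal, central, parietal and occipital sites so
    Delaunay adjacency yields a realistic neighbor graph.
    """
    return {
        "F3": (-0.45, 0.55), "Fz": (0.0, 0.60), "F4": (0.45, 0.55),
        "FC3": (-0.50, 0.28), "FCz": (0.0, 0.30), "FC4": (0.50, 0.28),
        "C3": (-0.55, 0.0), "Cz": (0.0, 0.0), "C4": (0.55, 0.0),
        "CP3": (-0.50, -0.28), "CPz": (0.0, -0.30), "CP4": (0.50, -0.28),
        "P3": (-0.45, -0.55), "Pz": (0.0, -0.60), "P4": (0.45, -0.55),
        "Oz": (0.0, -0.85),
    }


@dataclass
class InjectedBurstSpec:
    """One family of transient beta events to inject into synthetic EEG.

    Parameters
    ----------
    channels : channel labels receiving the events.
    condition : "Go", "Stop" or "both" — which trials receive them.
    latency_window : (lo, hi) ms relative to the trial's reference time
        (earliest lift on Go, SSD+SSRT on Stop); event centers are uniform
        in this window.
    rate : expected number of events per trial (Poisson).
    frequency : center frequency in Hz, inside the beta band [15, 29].
    amplitude : peak envelope amplitude in units of the background SD.
    jitter : additional Gaussian jitter (ms SD) on the event center.
    """

    channels: tuple[str, ...]
    condition: str = "both"
    latency_window: tuple[float, float] = (-250.0, -50.0)
    rate: float = 0.3
    frequency: float = 20.0
    amplitude: float = 3.0
    jitter: float = 5.0

    def validate(self) -> None:
        if self.rate < 0:
            raise ConfigError(f"burst rate must be >= 0, got {self.rate}")
        if not 15.0 <= self.frequency <= 29.0:
            raise ConfigError(
                f"burst frequency {self.frequency} outside beta band [15, 29]")
        if self.condition not in ("Go", "Stop", "both"):
            raise ConfigError(f"unknown condition {self.condition!r}")


def default_burst_spec() -> list["InjectedBurstSpec"]:
    """Default injected beta-event structure.

    A condition-independent background of transient events at every channel,
    plus a Stop-specific rate increase over right-central / midline sites in
    the last ~100 ms before the reference time — the kind of contrast the
    mass-univariate analysis is built to detect.
    """
    all_ch = tuple(default_channel_layout())
    return [
        InjectedBurstSpec(channels=all_ch, condition="both",
                          latency_window=(-300.0, -10.0), rate=0.25,
                          frequency=20.0, amplitude=3.0, jitter=5.0),
        InjectedBurstSpec(channels=("FCz", "Cz", "C4", "CP4"),
                          condition="Stop", latency_window=(-100.0, -5.0),
                          rate=0.5, frequency=22.0, amplitude=3.0, jitter=5.0),
    ]


@dataclass
class EMGSpec:
    """Synthetic EMG noise / burst envelope parameters (uV, ms)."""

    noise_sd: float = 2.5              # baseline white-noise SD, uV
    carrier_freq: float = 150.0        # Hz, inside the 50-450 Hz hardware band
    main_amplitude: float = 120.0      # envelope peak of the lift burst, uV
    main_width: float = 25.0           # Gaussian envelope SD, ms
    partial_amplitude: float = 60.0
    partial_width: float = 15.0
    premature_amplitude: float = 50.0
    premature_width: float = 15.0
    p_premature: float = 0.184         # per-Go-trial probability of a premature burst
    p_partial: float = 0.515           # per-successful-Stop probability of a partial burst
    cancel_time_mean: float = 140.0    # partial-burst peak relative to SSD, ms
    cancel_time_sd: float = 10.0
    premature_lead_range: tuple[float, float] = (100.0, 210.0)  # ms before lift


@dataclass
class SimulationConfig:
    """Ground-truth generator settings; defaults mirror the task design."""

    n_participants: int = 20
    n_go_trials: int = 320
    n_stop_trials: int = 160
    sampling_rate: float = 1024.0
    target_time: float = 800.0         # ms, indicator reaches the target line
    epoch_start: float = -500.0        # ms relative to indicator rise
    epoch_end: float = 1000.0
    channel_layout: dict[str, tuple[float, float]] = field(
        default_factory=default_channel_layout)
    background_exponent: float = 1.0   # 1/f^alpha EEG noise slope
    background_sd: float = 1.0         # time-domain SD of the EEG background
    burst_spec: list[InjectedBurstSpec] = field(default_factory=default_burst_spec)
    emg_spec: EMGSpec = field(default_factory=EMGSpec)
    lift_mean_offset: float = 35.0     # ms after the target, anticipatory lag
    lift_sd: float = 25.0              # within-participant lift-time SD, ms
    true_ssrt: float = 200.0           # ms, drives the stop-success race
    staircase_start_ssd: float = 550.0
    staircase_step: float = 25.0
    staircase_bounds: tuple[float, float] = (100.0, 775.0)
    random_seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigError("n_participants must be positive")
        if self.n_go_trials <= 0 or self.n_stop_trials <= 0:
            raise ConfigError("trial counts must be positive")
        if self.sampling_rate <= 2 * 29:
            raise ConfigError("sampling rate must exceed 2x the top beta frequency")
        if self.epoch_end <= self.epoch_start:
            raise ConfigError("epoch_end must exceed epoch_start")
        for d in (self.target_time, self.lift_sd, self.staircase_step):
            if d < 0:
                raise ConfigError("durations must be non-negative")
        for spec in self.burst_spec:
            spec.validate()


@dataclass
class AnalysisConfig:
    """Analysis-stage parameters. Every default that the study states is fixed
    at the stated value: 2x median burst threshold, 10 x 31.25 ms bins, 700 ms
    SSD cap, +/-50 ms on-target window, +/-3 SD lift trimming, 15 SD EMG
    threshold, >=5 ms duration, <15 ms merge, 30 uV baseline exclusion,
    100-400 ms pre-rise dB baseline."""

    threshold_factor: float = 2.0        # x median beta power
    n_bins: int = 10
    bin_ms: float = 31.25
    ssd_cap: float = 700.0               # ms; Stop trials with SSD > cap excluded
    on_target_tol: float = 50.0          # ms
    trim_sd: float = 3.0
    baseline_window: tuple[float, float] = (-400.0, -100.0)  # ms pre-rise
    baseline_per_trial: bool = False
    emg_baseline_window: tuple[float, float] = (0.0, 400.0)
    emg_exclude_window: tuple[float, float] = (300.0, 400.0)
    emg_exclude_rms: float = 30.0        # uV
    emg_threshold_sd: float = 15.0
    emg_min_duration: float = 5.0        # ms
    emg_merge_gap: float = 15.0          # ms
    emg_smooth_ms: float = 10.0
    emg_refine_window: float = 25.0      # ms, single-threshold onset refinement
    emg_refine_sd: float = 3.0
    emg_refine: bool = True
    ssrt_rank: str = "ceil"              # or "nearest"
    staircased_ssd_mode: str = "mean"    # or "last"
    volume_integrand: str = "excess"     # or "raw"
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_dh_frac: float = 0.01           # dh = frac * max|stat|
    n_permutations: int = 1000
    alpha: float = 0.05
    adjacency_method: str = "delaunay"   # or "distance"
    adjacency_distance: float = 0.65


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration: simulation + analysis + outputs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "stopburst_output"
    features: tuple[str, ...] = ("power", "rate", "volume", "amplitude", "duration")
    contrasts: tuple[str, ...] = ("TrialType", "MuscleBurst")

    def validate(self) -> None:
        self.simulation.validate()
        if not 0 < self.analysis.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.analysis.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        ana = dict(d.pop("analysis", {}))
        bursts = [InjectedBurstSpec(**{**b, "channels": tuple(b["channels"])})
                  for b in sim.pop("burst_spec", [])]
        emg = EMGSpec(**_tupled(sim.pop("emg_spec", {}),
                                ("premature_lead_range",)))
        layout = {k: tuple(v) for k, v in sim.pop(
            "channel_layout", default_channel_layout()).items()}
        sim = _tupled(sim, ("staircase_bounds",))
        simulation = SimulationConfig(burst_spec=bursts, emg_spec=emg,
                                      channel_layout=layout, **sim)
        analysis = AnalysisConfig(**_tupled(
            ana, ("baseline_window", "emg_baseline_window", "emg_exclude_window")))
        d = _tupled(d, ("features", "contrasts"))
        return cls(simulation=simulation, analysis=analysis, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable hash identifying a configuration (stamped on outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d
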