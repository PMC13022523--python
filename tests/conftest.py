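import dataclasses

import numpy as np
import pytest

from stopburst.config import (EMGSpec, InjectedBurstSpec, PipelineConfig,
                              SimulationConfig, default_channel_layout)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_layout():
    full = default_channel_layout()
    keep = ["F3", "Fz", "F4", "Cz", "C3", "C4", "Pz", "Oz"]
    return {k: full[k] for k in keep}


@pytest.fixture
def small_sim_config():
    """A scaled-down simulation: 3 participants, 24/12 trials, 8 channels."""
    return SimulationConfig(
        n_participants=3, n_go_trials=24, n_stop_trials=12,
        channel_layout=small_layout(),
        burst_spec=[
            InjectedBurstSpec(channels=("Cz", "C4"), condition="both",
                              latency_window=(-250.0, -50.0), rate=0.4,
                              frequency=20.0, amplitude=3.0, jitter=5.0),
        ],
        emg_spec=EMGSpec(),
        random_seed=7,
    )


@pytest.fixture
def small_pipeline_config(small_sim_config):
    cfg = PipelineConfig(simulation=small_sim_config)
    cfg.analysis.n_permutations = 50
    return cfg


@pytest.fixture
def behavior_config():
    """Behavior-only config: cheap to simulate many trials."""
    return SimulationConfig(n_participants=1, n_go_trials=300,
                            n_stop_trials=150, random_seed=3)
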