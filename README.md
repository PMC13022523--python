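# stopburst

Trial-level β-burst and muscle-burst analysis of anticipatory response
inhibition (ARIT), with a mass-univariate **LMM–TFCE** statistical engine
and a fully synthetic, ground-truthed test bench.

Conventional trial-averaged β-power (15–29 Hz) masks the transient,
burst-like structure of sensorimotor β activity. `stopburst` implements the
burst-level alternative end to end, for researchers analyzing stop-signal /
anticipatory-inhibition EEG+EMG experiments:

* **β-burst features** — complex Morlet decomposition (15 linearly spaced
  frequencies 15–29 Hz, 4–10 log-spaced cycles), per-trial 2 × median power
  thresholding, and per-event rate, volume, amplitude and duration, binned
  into ten 31.25 ms windows ending at the lift-time (Go) or SSD + SSRT
  (successful Stop).
* **Behavior** — on-target classification (±50 ms), ±3 SD lift-time
  trimming, staircased-SSD summary, and SSRT by the integration method:
  SSRT = *n*th trimmed Go lift-time − staircased SSD, *n* = *N* ·
  p(respond | Stop).
* **EMG** — rectified/smoothed traces, 15 SD baseline-threshold burst
  detection (≥5 ms, <15 ms merge), main/premature/partial classification,
  and CancelTime = partial-burst peak − SSD, a single-trial index of
  stopping latency.
* **Statistics** — at every channel × bin point the mixed model
  `y ~ 1 + condition + (1 | participant)` (effects-coded) is fitted by
  REML; estimated random intercepts are removed and mass OLS on the
  marginal data reproduces the fixed-effect t map at permutation-loop
  speed. Threshold-free cluster enhancement (E = 0.5, H = 2) with
  within-participant label permutations controls the family-wise error of
  the whole map.
* **Synthetic data** — 1/f EEG with injected Morlet transients, EMG with
  Gaussian-envelope carrier bursts, and staircased race-model behavior,
  all with a ground-truth log, so every stage is testable without any
  recordings.

## Worked example

```python
import numpy as np
from stopburst import behavior, simulate, tfce
from stopburst.config import SimulationConfig, default_channel_layout

# Behavioral chain: staircased race with a true SSRT of 200 ms
cfg = SimulationConfig(n_participants=1, burst_spec=[], random_seed=3)
trials = simulate.generate_behavior(cfg, np.random.default_rng(3))
s = behavior.summarize_participant(trials)
print(f"stop success {s['stop_success_rate']:.1%}, "
      f"staircased SSD {s['staircased_ssd_ms']:.0f} ms, "
      f"SSRT {s['ssrt_ms']:.1f} ms")
# stop success 50.6%, staircased SSD 635 ms, SSRT 199.9 ms

# Mass LMM-TFCE on binned burst rates with a known Stop-specific effect
layout = default_channel_layout()
chan = tfce.channel_adjacency(np.array(list(layout.values())))
rng = np.random.default_rng(0)
Y, X, groups, truth = simulate.simulate_binned_rates(
    20, 30, 16, 10, rng, effect=0.5,
    effect_channels=(4, 7, 8, 11), effect_bins=(7, 8, 9))
res = tfce.lmm_tfce(Y, X, groups, chan, n_bins=10,
                    n_permutations=500, rng=rng)
print(f"significant points: {res.mask.sum()} "
      f"(true-effect cells hit: {res.mask[truth].sum()}/{truth.sum()})")
# significant points: 12 (true-effect cells hit: 12/12)
```

The first block prints the staircase converging to ~50% stop success and
the integration method recovering the generating SSRT of 200 ms. The
second injects an extra 0.5 bursts/bin on Stop trials at 4 channels ×
3 bins and shows the FWER-corrected map flagging exactly those cells.

The same chain runs from the shell:

```bash
stopburst init my.yaml          # write the full default config block
stopburst run-all --config my.yaml --seed 1 --output-dir out/
```

which writes the simulated dataset, binned features, behavioral and EMG
tables, TFCE maps (TSV + topographic-grid figures) and a run log with
exclusion accounting under `out/`.

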