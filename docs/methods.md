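# Methods

`stopburst` re-implements, as a tested and reusable pipeline, a trial-level
analysis of cortical β-bursting and muscle bursting during a bimanual
anticipatory response inhibition task (ARIT). This note documents the models
and procedures, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Task model

In the ARIT, two indicators rise and the participant releases two switches
so the indicators intercept a target line at 800 ms (Go trials; on-target if
both lifts are within ±50 ms of the target). On Stop trials (one third of
trials; the 2:1 ratio builds a prepotent Go response) the indicators halt at
the stop-signal delay (SSD) and the response must be withheld. The SSD is
staircased — success makes the next Stop trial harder (+step), failure
easier (−step) — so stopping succeeds on roughly half the trials.

Stop-signal reaction time (SSRT) is estimated by the integration method:
trimmed Go lift-times (averaged across hands, ±3 SD single-pass trim) are
rank-ordered, the *n*th value is selected with *n* = *N* ·
p(respond | Stop), and the staircased SSD is subtracted. Non-integer ranks
are realized as the 1-based ceiling (a `nearest` alternative is available).
The staircased SSD is summarized as the mean over Stop trials by default
(`last` available); how the operational study summarized it is not
derivable from the procedure description, so both are exposed.

## β-features

EEG epochs are decomposed with complex Morlet wavelets at 15 linearly
spaced frequencies from 15 to 29 Hz, with 4–10 cycles logarithmically
spaced across frequencies. Power is the squared magnitude of the
convolution. Wavelets are unit-energy; absolute scale is irrelevant because
every downstream threshold is relative (median-based or dB).

*Edge validity.* Wavelets are constructed with Gaussian support ±2.5 σ_t
(σ_t = cycles / 2πf), and samples within half a wavelet length of an epoch
edge are flagged invalid **per frequency**. The margin at 15 Hz/4 cycles is
≈106 ms, so in a −500 ms epoch the −400…−100 ms baseline loses only its
first few milliseconds at the lowest frequencies; baselining uses the valid
subset per frequency. Binning windows that touch invalid samples exclude
the trial with a logged reason.

*dB normalization.* Average β-power is expressed as
10·log₁₀(power / baseline mean), baseline = 100–400 ms before the
indicators rise. The baseline mean is taken per channel × frequency over
baseline samples **and trials** (the conventional choice; a per-trial
variant is available via `baseline_per_trial`).

*Burst detection.* Bursts are detected on raw (non-normalized) power: each
connected suprathreshold region (strictly above 2 × the median of the
trial × channel time–frequency map; 4-connectivity, no diagonals) yields
one event at its power maximum. The median pools all time × frequency
samples of the map — making the threshold scale-free, so the detected
burst set is exactly invariant to multiplying the signal by any constant.
Per event: peak time/frequency, amplitude (peak − threshold), duration
(time extent of the region at the peak frequency), and volume
(Σ (power − threshold) · dt over the region, summed over frequencies).
Volume integrates the *excess over threshold* rather than raw power: the
excess form vanishes continuously as a burst shrinks to threshold and
preserves the invariant rate = 0 ⇒ volume = 0 (a `raw` integrand switch
exists for sensitivity analysis).

*Binning.* Features are collected in 10 left-closed bins of 31.25 ms
(32 samples at 1,024 Hz) ending at the trial's reference time: earliest
lift on on-target Go trials, SSD + participant SSRT on successful Stop
trials (trials with SSD > 700 ms excluded). A burst belongs to the bin
containing its peak (events are counts, not intervals); a peak exactly on
an interior edge belongs to the later bin. Rate is the per-bin count;
volume/amplitude/duration are per-bin sums; β-power is the per-bin mean dB
over frequencies, computed over whole epochs before binning.

## EMG

Traces are full-wave rectified and smoothed with a 10 ms centered moving
average (the smoothing kernel is a stand-in; only "smoothed" is inherent
to the procedure). Trials with baseline rms above 30 µV in 300–400 ms are
excluded. Bursts are runs above baseline mean + 15 × SD (baseline =
rectified-smoothed trace over 0–400 ms; the mean term keeps the threshold
sensible when the baseline mean dwarfs its SD — a pure 15 × SD mode is
available), merged when separated by <15 ms, discarded when shorter than
5 ms. Onsets/offsets are refined by a single-threshold rule: scanning
forward from 100 ms before the coarse onset, the first sample whose 25 ms
forward-window mean exceeds baseline mean + 3 SD (offset symmetric); the
25 ms / 3 SD parameters are explicit stand-ins and configurable, and
refinement can be disabled. Manual review is replaced by the audit trail
(burst tables with flags).

Classification: on Go trials the main burst is the last burst with onset
before the recorded switch release; earlier bursts are premature. On
successful Stop trials, bursts peaking inside the participant's ±3 SD
trimmed Go lift-time window are partial (the peak, not the onset, is
tested — consistent with CancelTime's focus on the peak). CancelTime =
partial-burst peak − SSD; negative values are flagged, not dropped.
Incidence = % of traces with ≥1 burst of a class.

## Mass-univariate statistics (LMM + TFCE)

At every channel × bin point the model is
`y ~ 1 + condition + (1 | participant)` with effects coding (Go = −1,
Stop = +1; no-burst = −1, burst = +1), so a positive t means "greater on
Stop/burst trials" and the slope is half the condition difference. The
point model is estimated by profiled REML specialized to the single
random-intercept case: the covariance V = I + λZZ′ inverts in closed form
per participant block, leaving a 1-D bounded optimization over
λ = σ²_u/σ²_e. Boundary fits (λ → 0) degrade to OLS with zero intercepts
and are flagged. The solver reproduces a general-purpose REML
implementation to ~6 significant digits (tested) at ~100× the speed, which
is what makes the permutation loops below tractable.

Predicted random intercepts are subtracted from the response ("marginal
data"); a single factorized OLS solve shared by all map points then
reproduces the mixed-model fixed-effect t point-wise (within ~1% on
realistic data; exactly when the intercept variance is zero). Permutations
shuffle the condition labels *within* each participant — the
exchangeability structure the random-intercept model implies — with one
shared permutation per map to preserve spatiotemporal correlation.

TFCE integrates cluster extent^E × height^H over thresholds (E = 0.5,
H = 2, dh = 0.01 × max|t|; the threshold ladder is h = k·dh). Map
connectivity links Delaunay-neighbor channels within a bin and adjacent
bins within a channel; no diagonal links. Positive and negative values are
enhanced separately and recombined signed. The production kernel is an
incremental union-find (numba); a naive per-threshold connected-components
implementation is kept as an independent oracle and the two agree to
<1e-9. Family-wise error uses the permutation null of map maxima of
|TFCE| with p = (1 + #{null ≥ obs}) / (1 + n_perm), so p > 0 always;
default 1,000 permutations, seedable.

*Post hoc timing.* For successful Stop trials with exactly one partial
burst not in the first or last bin, the bins (before, during, after) the
burst are extracted and participant-level mean burst rates over a chosen
electrode cluster are compared by a one-way ANOVA across the three
positions. The omnibus treats positions as independent groups
(df = (2, 3n−3), matching the df convention of the reported analyses this
mirrors; a repeated-measures formulation would give (2, 2n−2) error df),
with η² = SS_effect/SS_total and Bonferroni-corrected paired t tests.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **EEG** = 1/f^α background noise (α = 1, SD 1 in arbitrary units; shaped
  in the frequency domain) plus real Morlet transients whose envelope
  matches the analysis wavelet at their frequency. Event rates, channels,
  latency windows (relative to each trial's reference time), frequencies
  and amplitudes come from `InjectedBurstSpec`s; the default set injects a
  condition-independent background (rate 0.25/trial/channel) plus a
  Stop-specific increase at right-central/midline sites in the final
  100 ms.
* **EMG** = white baseline noise (2.5 µV SD) plus Gaussian-envelope bursts
  carrying a 150 Hz sinusoid (inside the 50–450 Hz hardware band), so
  rectification and smoothing are genuinely exercised: a main burst at the
  lift on responded trials (120 µV, 25 ms envelope SD), premature bursts on
  18.4% of Go trials 100–210 ms before the lift (50 µV), and partial
  bursts on 51.5% of successful Stops peaking at SSD + N(140, 10) ms
  (60 µV). Those probabilities and latencies mirror the observed incidence
  and CancelTime ranges in this paradigm.
* **Behavior**: per-hand lift-times = common bimanual component
  N(835, 25) ms plus 4 ms per-hand jitter; Stop outcome from an
  independent race against a true SSRT of 200 ms; SSD staircase ±25 ms
  from 550 ms within [100, 775] ms (step and start are not derivable from
  the task description; these are common ARIT practice).

One global seed spawns stateless per-participant child seeds, so datasets
are bit-reproducible and single participants can be regenerated
independently. A separate statistics-level generator
(`simulate_binned_rates`) draws per-trial binned Poisson burst counts with
participant intercepts and an optional Stop-specific mean shift; it is used
for the error-rate and sensitivity studies where signal-level simulation at
hundreds of replicates would be pointlessly expensive — those studies test
the statistical engine, not the signal chain.

Not emulated: eye blinks and other artifacts (inputs are assumed
preprocessed), channel-specific noise, volume conduction between channels,
spectral nonstationarity, the current-source-density transform, and any
correlation between CancelTime and SSRT across participants. Passing
recovery tests therefore demonstrates correctness of the analysis chain
under its own assumptions, not robustness to artifacts of real recordings.
One known interplay worth naming: partial bursts are generated at
SSD + CancelTime, but classified only when they peak inside the ±3 SD
lift-time window, so during the staircase's approach phase (short SSDs)
some generated bursts are correctly left unclassified and the measured
partial-burst incidence undershoots the generation probability.

## Problem sizes

Defaults follow the study conditions (20 participants, 320/160 trials,
1,024 Hz, 128→16-channel schematic montage, 1,000 permutations). The test
suite and acceptance script run scaled-down replicates chosen to keep the
full run in minutes while leaving each check statistically decisive:
5 participants × 40 trials × 20–80 points for the equivalence and
error-rate studies (200 simulations × 200 permutations for the null FWER),
20-participant cohorts for sensitivity, 60–80 trials for burst and
CancelTime recovery, and a 6-participant × 96-trial end-to-end pipeline
demonstration.

## Known limitations

* The ±15 ms / ±2 Hz burst-recovery matching tolerance reflects the
  time–frequency uncertainty of the wavelets themselves, not detector
  error; two injected events closer than the wavelet's resolution merge
  into one connected region and count once, by design.
* TFCE inevitably bleeds some enhancement into neighbors of a strong
  cluster; localization is assessed statistically (≥90% of flagged points
  at true-effect cells), not point-exactly.
* The profiled-REML solver covers exactly the model family used here
  (single random intercept, single fixed effect); it is not a general
  mixed-model engine.
* `staircased_ssd`, the rank rule, the EMG smoothing window and the
  refinement parameters are documented stand-ins wherever the procedure
  description leaves them open; each is configurable.
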