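"""Beta-burst detection and binned feature extraction.

Bursts are peaks of raw (non-normalized) beta power exceeding two times the
median power of their own trial x channel map — a scale-free threshold that
adapts per channel, per trial and per participant. Each connected
suprathreshold region of the time x frequency map (4-connectivity) yields one
event at its global peak. Four per-event metrics are kept:

* rate       — event count (per bin, downstream)
* volume     — suprathreshold area: sum over region samples of
               (power - threshold) * dt, summed over frequencies
* amplitude  — peak power minus threshold
* duration   — time extent of the region at the peak frequency

Features are binned into 10 left-closed 31.25 ms bins ending at a per-trial
reference time: SSD + SSRT on successful Stop trials (excluded if SSD exceeds
700 ms), the earliest lift-time on Go trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .timefreq import TFPower

#: 4-connectivity in the time x frequency grid (no diagonals).
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)

N_BINS = 10
BIN_MS = 31.25
WINDOW_MS = N_BINS * BIN_MS           # 312.5 ms
SSD_CAP_MS = 700.0


def burst_threshold(power_ft: np.ndarray, valid: np.ndarray,
                    factor: float = 2.0) -> float:
    """Burst threshold for one trial x channel: factor x the median over all
    valid time x frequency samples of the raw power map."""
    vals = power_ft[valid]
    if vals.size == 0:
        raise ValueError("no valid samples to compute the burst threshold")
    return factor * float(np.median(vals))


def detect_bursts(power_ft: np.ndarray, threshold: float,
                  valid: np.ndarray, times_ms: np.ndarray,
                  frequencies: np.ndarray, sfreq: float,
                  volume_integrand: str = "excess") -> pd.DataFrame:
    """Detect bursts on one trial x channel raw-power map.

    Each connected region of samples strictly exceeding ``threshold``
    (4-connectivity, valid samples only) becomes one event located at the
    region's power maximum. Events are sorted by peak time.

    Returns a DataFrame with columns peak_time_ms, peak_freq_hz, peak_power,
    amplitude, volume, duration_ms, n_samples.
    """
    dt_ms = 1000.0 / sfreq
    mask = (power_ft > threshold) & valid
    labels, n = ndimage.label(mask, structure=_STRUCTURE)
    rows = []
    for lab in range(1, n + 1):
        region = labels == lab
        masked = np.where(region, power_ft, -np.inf)
        fi, ti = np.unravel_index(np.argmax(masked), masked.shape)
        peak_power = power_ft[fi, ti]
        if volume_integrand == "excess":
            vol = float((power_ft[region] - threshold).sum() * dt_ms)
        elif volume_integrand == "raw":
            vol = float(power_ft[region].sum() * dt_ms)
        else:
            raise ValueError(f"unknown volume integrand {volume_integrand!r}")
        duration = int(region[fi].sum()) * dt_ms
        rows.append((float(times_ms[ti]), float(frequencies[fi]),
                     float(peak_power), float(peak_power - threshold),
                     vol, duration, int(region.sum())))
    df = pd.DataFrame(rows, columns=["peak_time_ms", "peak_freq_hz",
                                     "peak_power", "amplitude", "volume",
                                     "duration_ms", "n_samples"])
    return df.sort_values("peak_time_ms", ignore_index=True)


def detect_all_bursts(tf: TFPower, participant: str,
                      trial_ids: np.ndarray | None = None,
                      channels: list[str] | None = None,
                      factor: float = 2.0,
                      volume_integrand: str = "excess") -> pd.DataFrame:
    """Run threshold + detection over every trial x channel of a TFPower."""
    if tf.is_db:
        raise ValueError("burst detection requires raw (non-dB) power")
    n_ch, _, _, n_tr = tf.power.shape
    if trial_ids is None:
        trial_ids = np.arange(n_tr)
    if channels is None:
        channels = [f"ch{c}" for c in range(n_ch)]
    out = []
    for c in range(n_ch):
        for j in range(n_tr):
            pmap = tf.power[c, :, :, j]
            thr = burst_threshold(pmap, tf.valid, factor)
            ev = detect_bursts(pmap, thr, tf.valid, tf.times_ms,
                               tf.frequencies, tf.sfreq, volume_integrand)
            if len(ev):
                ev.insert(0, "participant", participant)
                ev.insert(1, "trial", trial_ids[j])
                ev.insert(2, "channel", channels[c])
                ev["threshold"] = thr
                out.append(ev)
    if not out:
        return pd.DataFrame(columns=["participant", "trial", "channel",
                                     "peak_time_ms", "peak_freq_hz",
                                     "peak_power", "amplitude", "volume",
                                     "duration_ms", "n_samples", "threshold"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# reference times and binning
# ---------------------------------------------------------------------------

def reference_time_stop(ssd_ms: float, ssrt_ms: float,
                        cap_ms: float = SSD_CAP_MS) -> tuple[float, bool]:
    """Reference for a successful Stop trial: SSD + participant SSRT.

    Trials whose SSD strictly exceeds the cap are flagged excluded (the
    window would run past the usable epoch for long delays).
    """
    if ssrt_ms is None or np.isnan(ssrt_ms):
        raise ValueError("participant SSRT is required")
    return float(ssd_ms + ssrt_ms), bool(ssd_ms <= cap_ms)


def reference_time_go(lift_left_ms: float, lift_right_ms: float) -> float:
    """Reference for a Go trial: the earliest lift-time."""
    if np.isnan(lift_left_ms) or np.isnan(lift_right_ms):
        raise ValueError("Go trials without both lift-times are excluded upstream")
    return float(min(lift_left_ms, lift_right_ms))


def bin_edges(reference_ms: float, n_bins: int = N_BINS,
              bin_ms: float = BIN_MS) -> np.ndarray:
    """Left-closed, right-open bin edges covering
    [reference - n_bins*bin_ms, reference)."""
    return reference_ms - n_bins * bin_ms + bin_ms * np.arange(n_bins + 1)


def assign_bin(peak_time_ms: float, reference_ms: float,
               n_bins: int = N_BINS, bin_ms: float = BIN_MS) -> int:
    """Bin index (0-based) of a burst peak, or -1 if outside the window.

    Left-closed convention: a peak exactly on an interior edge belongs to
    the later bin; a peak exactly at the reference is outside.
    """
    left = reference_ms - n_bins * bin_ms
    if not (left <= peak_time_ms < reference_ms):
        return -1
    return int((peak_time_ms - left) // bin_ms)


def bin_trial_features(events: pd.DataFrame, db_power_ft: np.ndarray,
                       valid: np.ndarray, times_ms: np.ndarray,
                       reference_ms: float, n_bins: int = N_BINS,
                       bin_ms: float = BIN_MS) -> pd.DataFrame | None:
    """Binned features for one trial x channel.

    Bursts contribute to the bin containing their peak; per-bin rate is the
    count and volume/amplitude/duration are sums over the bin's events.
    Beta power (already dB-normalized over the whole epoch) is averaged over
    frequencies and bin samples. Returns None if the window leaves the
    epoch's valid region (trial excluded upstream with a logged reason).
    """
    edges = bin_edges(reference_ms, n_bins, bin_ms)
    all_valid = valid.all(axis=0)
    covered = (times_ms >= edges[0]) & (times_ms < edges[-1])
    if not covered.any() or not all_valid[covered].all() or \
            edges[0] < times_ms[0] or edges[-1] > times_ms[-1] + 1e-9:
        return None
    rate = np.zeros(n_bins)
    vol = np.zeros(n_bins)
    amp = np.zeros(n_bins)
    dur = np.zeros(n_bins)
    for _, ev in events.iterrows():
        b = assign_bin(ev["peak_time_ms"], reference_ms, n_bins, bin_ms)
        if b >= 0:
            rate[b] += 1
            vol[b] += ev["volume"]
            amp[b] += ev["amplitude"]
            dur[b] += ev["duration_ms"]
    power = np.empty(n_bins)
    for b in range(n_bins):
        sel = (times_ms >= edges[b]) & (times_ms < edges[b + 1])
        power[b] = db_power_ft[:, sel].mean()
    return pd.DataFrame({"bin": np.arange(n_bins), "rate": rate,
                         "volume": vol, "amplitude": amp, "duration": dur,
                         "power": power})


def extract_binned_features(tf_raw: TFPower, tf_db: TFPower,
                            events: pd.DataFrame, trials: pd.DataFrame,
                            references: pd.DataFrame, participant: str,
                            channels: list[str],
                            n_bins: int = N_BINS, bin_ms: float = BIN_MS
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format binned features for one participant.

    ``references`` must carry columns trial, reference_ms, included (bool)
    and reason. Returns (features, exclusions): features has one row per
    trial x channel x bin with the five response columns; exclusions logs
    every dropped trial with its rule.
    """
    out, excluded = [], []
    trial_pos = {t: j for j, t in enumerate(trials["trial"].to_numpy())}
    for _, ref_row in references.iterrows():
        t = ref_row["trial"]
        if not ref_row["included"]:
            excluded.append((participant, t, ref_row["reason"]))
            continue
        j = trial_pos[t]
        for c, ch in enumerate(channels):
            ev = events[(events["trial"] == t) & (events["channel"] == ch)]
            binned = bin_trial_features(
                ev, tf_db.power[c, :, :, j], tf_db.valid, tf_db.times_ms,
                ref_row["reference_ms"], n_bins, bin_ms)
            if binned is None:
                excluded.append((participant, t, "window_outside_valid_epoch"))
                break
            binned.insert(0, "participant", participant)
            binned.insert(1, "trial", t)
            binned.insert(2, "channel", ch)
            out.append(binned)
        else:
            continue
    features = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["participant", "trial", "channel", "bin", "rate", "volume",
                 "amplitude", "duration", "power"])
    exclusions = pd.DataFrame(excluded,
                              columns=["participant", "trial", "reason"])
    # a trial excluded at any channel is excluded everywhere
    if len(exclusions):
        bad = set(exclusions["trial"])
        features = features[~features["trial"].isin(bad)].reset_index(drop=True)
    return features, exclusions


def make_references(trials: pd.DataFrame, ssrt_ms: float,
                    on_target: pd.Series | None = None,
                    cap_ms: float = SSD_CAP_MS) -> pd.DataFrame:
    """Per-trial reference times and inclusion flags for the binned window.

    Included: on-target Go trials (reference = earliest lift) and successful
    Stop trials with SSD <= cap (reference = SSD + SSRT). Everything else is
    excluded with a reason.
    """
    rows = []
    for _, r in trials.iterrows():
        t = r["trial"]
        if r["type"] == "Go":
            if np.isnan(r["lift_left_ms"]) or np.isnan(r["lift_right_ms"]):
                rows.append((t, np.nan, False, "go_no_lift"))
                continue
            if on_target is not None and not bool(on_target.loc[r.name]):
                rows.append((t, np.nan, False, "go_off_target"))
                continue
            rows.append((t, reference_time_go(r["lift_left_ms"],
                                              r["lift_right_ms"]),
                         True, ""))
        else:
            if not bool(r["stop_success"]):
                rows.append((t, np.nan, False, "stop_failed"))
                continue
            ref, ok = reference_time_stop(r["ssd_ms"], ssrt_ms, cap_ms)
            if not ok:
                rows.append((t, np.nan, False, "ssd_above_cap"))
            else:
                rows.append((t, ref, True, ""))
    return pd.DataFrame(rows, columns=["trial", "reference_ms", "included",
                                       "reason"])
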