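"""EMG preprocessing, burst detection and classification, CancelTime.

The trace is full-wave rectified and smoothed (10 ms moving average). A
muscle burst is a run of samples above baseline mean + 15 x baseline SD
(baseline = 0-400 ms after the indicators rise) lasting >= 5 ms after runs
separated by < 15 ms are merged. Trials whose baseline rms between 300 and
400 ms exceeds 30 uV are excluded. Burst onsets/offsets are refined with a
single-threshold sliding-window criterion.

Classification: on Go trials the main (lift-generating) burst is the last
burst whose onset precedes the recorded switch release; every earlier burst
is premature. On successful Stop trials, bursts peaking inside the
participant's +/-3 SD trimmed Go lift-time window are partial bursts, and
CancelTime = partial-burst peak time - SSD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

BURST_COLUMNS = ["onset_ms", "offset_ms", "peak_time_ms", "peak_amplitude"]


def preprocess_emg(raw: np.ndarray, sfreq: float,
                   smooth_ms: float = 10.0) -> np.ndarray:
    """Full-wave rectification followed by a centered moving average."""
    rect = np.abs(np.asarray(raw, float))
    win = max(1, int(round(smooth_ms / 1000.0 * sfreq)))
    return uniform_filter1d(rect, size=win, mode="nearest")


def baseline_stats(trace: np.ndarray, times_ms: np.ndarray,
                   window: tuple[float, float] = (0.0, 400.0)
                   ) -> tuple[float, float, float]:
    """(mean, SD, rms) of a rectified-smoothed trace over the baseline window."""
    sel = (times_ms >= window[0]) & (times_ms <= window[1])
    seg = trace[sel]
    return float(seg.mean()), float(seg.std(ddof=0)), \
        float(np.sqrt(np.mean(seg ** 2)))


def exclude_high_baseline(trace: np.ndarray, times_ms: np.ndarray,
                          window: tuple[float, float] = (300.0, 400.0),
                          limit_uv: float = 30.0) -> bool:
    """True (drop the trial) iff baseline rms strictly exceeds the limit."""
    _, _, rms = baseline_stats(trace, times_ms, window)
    return rms > limit_uv


def detect_emg_bursts(trace: np.ndarray, times_ms: np.ndarray, sfreq: float,
                      n_sd: float = 15.0, min_duration_ms: float = 5.0,
                      merge_gap_ms: float = 15.0,
                      baseline_window: tuple[float, float] = (0.0, 400.0),
                      threshold_mode: str = "mean_plus_sd") -> pd.DataFrame:
    """Detect (unclassified) muscle bursts on a rectified-smoothed trace.

    threshold_mode 'mean_plus_sd' (default) uses baseline mean + n_sd * SD;
    'sd_only' uses n_sd * SD alone.
    """
    mean, sd, _ = baseline_stats(trace, times_ms, baseline_window)
    if sd == 0:
        raise ValueError("degenerate baseline (SD = 0)")
    if threshold_mode == "mean_plus_sd":
        thr = mean + n_sd * sd
    elif threshold_mode == "sd_only":
        thr = n_sd * sd
    else:
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")

    above = trace > thr
    runs = _runs(above)
    merged = _merge_runs(runs, times_ms, merge_gap_ms)
    dt_ms = 1000.0 / sfreq
    rows = []
    for i0, i1 in merged:                       # half-open sample range
        dur = (i1 - i0) * dt_ms
        if dur < min_duration_ms:
            continue
        seg = trace[i0:i1]
        pk = i0 + int(np.argmax(seg))
        rows.append((float(times_ms[i0]), float(times_ms[i1 - 1]),
                     float(times_ms[pk]), float(trace[pk])))
    return pd.DataFrame(rows, columns=BURST_COLUMNS)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) sample indices."""
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _merge_runs(runs: list[tuple[int, int]], times_ms: np.ndarray,
                gap_ms: float) -> list[tuple[int, int]]:
    """Merge runs whose inter-run gap is strictly below gap_ms."""
    if not runs:
        return []
    out = [runs[0]]
    for s, e in runs[1:]:
        prev_s, prev_e = out[-1]
        gap = times_ms[s] - times_ms[prev_e - 1]
        if gap < gap_ms:
            out[-1] = (prev_s, e)
        else:
            out.append((s, e))
    return out


def refine_onset_single_threshold(trace: np.ndarray, times_ms: np.ndarray,
                                  sfreq: float, onset_ms: float,
                                  offset_ms: float,
                                  baseline_mean: float, baseline_sd: float,
                                  window_ms: float = 25.0, n_sd: float = 3.0,
                                  lookback_ms: float = 100.0
                                  ) -> tuple[float, float]:
    """Single-threshold onset/offset refinement.

    Scanning forward from ``lookback_ms`` before the coarse onset, the
    refined onset is the first sample whose forward ``window_ms`` mean
    exceeds baseline mean + n_sd * SD; the offset is found symmetrically
    scanning backward from ``lookback_ms`` after the coarse offset. Falls
    back to the coarse bounds if the criterion is never met.
    """
    thr = baseline_mean + n_sd * baseline_sd
    win = max(1, int(round(window_ms / 1000.0 * sfreq)))
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    n = len(trace)

    def fwd_mean(i):
        j = min(i + win, n)
        return (csum[j] - csum[i]) / (j - i)

    def back_mean(i):
        j = max(i - win + 1, 0)
        return (csum[i + 1] - csum[j]) / (i + 1 - j)

    i_on = int(np.searchsorted(times_ms, onset_ms - lookback_ms))
    i_coarse_on = int(np.searchsorted(times_ms, onset_ms))
    refined_on = onset_ms
    for i in range(i_on, i_coarse_on + 1):
        if fwd_mean(i) > thr:
            refined_on = float(times_ms[i])
            break

    i_off = min(int(np.searchsorted(times_ms, offset_ms + lookback_ms)), n - 1)
    i_coarse_off = int(np.searchsorted(times_ms, offset_ms))
    refined_off = offset_ms
    for i in range(i_off, i_coarse_off - 1, -1):
        if back_mean(i) > thr:
            refined_off = float(times_ms[i])
            break
    return min(refined_on, onset_ms), max(refined_off, offset_ms)


def classify_bursts(bursts: pd.DataFrame, trial_type: str,
                    release_ms: float | None, stop_success: bool,
                    go_lift_mean: float, go_lift_sd: float,
                    n_sd: float = 3.0) -> pd.DataFrame:
    """Assign main / premature / partial / unclassified labels.

    Go trials: main = last burst with onset before the switch release;
    all earlier bursts are premature; bursts after the release are
    unclassified. Successful Stop trials: bursts peaking within
    go_lift_mean +/- n_sd * go_lift_sd are partial; others unclassified.
    """
    out = bursts.copy()
    out["cls"] = "unclassified"
    out["flag"] = ""
    if out.empty:
        return out
    if trial_type == "Go" or (trial_type == "Stop" and not stop_success):
        if release_ms is None or np.isnan(release_ms):
            return out
        before = out.index[out["onset_ms"] < release_ms]
        if len(before) == 0:
            out["flag"] = "lift_without_emg"
            return out
        main_idx = out.loc[before, "onset_ms"].idxmax()
        out.loc[main_idx, "cls"] = "main"
        out.loc[[i for i in before if i != main_idx], "cls"] = "premature"
    else:
        lo = go_lift_mean - n_sd * go_lift_sd
        hi = go_lift_mean + n_sd * go_lift_sd
        inside = (out["peak_time_ms"] >= lo) & (out["peak_time_ms"] <= hi)
        out.loc[inside, "cls"] = "partial"
    return out


def cancel_time(peak_time_ms: float, ssd_ms: float) -> tuple[float, bool]:
    """CancelTime = partial-burst peak time - SSD; flagged if negative
    (muscle activity peaking before the stop signal)."""
    ct = float(peak_time_ms - ssd_ms)
    return ct, ct < 0


def burst_incidence(burst_table: pd.DataFrame, trials: pd.DataFrame,
                    cls: str, trial_type: str,
                    stop_success: bool | None = None) -> float:
    """Percentage of included trials of a type with >= 1 burst of a class."""
    sel = trials["type"] == trial_type
    if stop_success is not None:
        sel &= trials["stop_success"].astype("boolean").fillna(False) == stop_success
    pool = trials.loc[sel, "trial"]
    if len(pool) == 0:
        raise ValueError("no included trials of the requested type")
    with_burst = burst_table[(burst_table["cls"] == cls)
                             & burst_table["trial"].isin(set(pool))]
    return 100.0 * with_burst["trial"].nunique() / len(pool)


def process_participant(emg_data: np.ndarray, times_ms: np.ndarray,
                        sfreq: float, trials: pd.DataFrame,
                        go_lift_mean: float, go_lift_sd: float,
                        hands: tuple[str, ...] = ("left", "right"),
                        smooth_ms: float = 10.0, n_sd: float = 15.0,
                        min_duration_ms: float = 5.0,
                        merge_gap_ms: float = 15.0,
                        exclude_rms_uv: float = 30.0,
                        refine: bool = True,
                        refine_window_ms: float = 25.0,
                        refine_sd: float = 3.0,
                        trim_n_sd: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full EMG chain for one participant.

    ``emg_data`` is (trials x hands x samples) raw EMG aligned with the rows
    of ``trials``. Returns (burst table, exclusion log). The burst table has
    one row per detected burst with class, refined bounds and cancel_time
    (partial bursts only).
    """
    rows, excluded = [], []
    pid = trials["participant"].iloc[0]
    for j, (_, tr) in enumerate(trials.iterrows()):
        for h, hand in enumerate(hands):
            trace = preprocess_emg(emg_data[j, h], sfreq, smooth_ms)
            if exclude_high_baseline(trace, times_ms, limit_uv=exclude_rms_uv):
                excluded.append((pid, tr["trial"], hand, "baseline_rms"))
                continue
            mean, sd, _ = baseline_stats(trace, times_ms)
            try:
                bursts = detect_emg_bursts(trace, times_ms, sfreq, n_sd,
                                           min_duration_ms, merge_gap_ms)
            except ValueError:
                excluded.append((pid, tr["trial"], hand, "degenerate_baseline"))
                continue
            if refine and len(bursts):
                refined = [refine_onset_single_threshold(
                    trace, times_ms, sfreq, b["onset_ms"], b["offset_ms"],
                    mean, sd, refine_window_ms, refine_sd)
                    for _, b in bursts.iterrows()]
                bursts["onset_ms"] = [r[0] for r in refined]
                bursts["offset_ms"] = [r[1] for r in refined]
            release = tr[f"lift_{hand}_ms"]
            success = bool(tr["stop_success"]) if tr["type"] == "Stop" else False
            labeled = classify_bursts(bursts, tr["type"], release, success,
                                      go_lift_mean, go_lift_sd, trim_n_sd)
            for _, b in labeled.iterrows():
                ct, neg = (np.nan, False)
                if b["cls"] == "partial":
                    ct, neg = cancel_time(b["peak_time_ms"], tr["ssd_ms"])
                rows.append((pid, tr["trial"], hand, b["cls"], b["onset_ms"],
                             b["offset_ms"], b["peak_time_ms"],
                             b["peak_amplitude"], ct,
                             "negative_cancel_time" if neg else b["flag"]))
    table = pd.DataFrame(rows, columns=["participant", "trial", "hand", "cls",
                                        "onset_ms", "offset_ms",
                                        "peak_time_ms", "peak_amplitude",
                                        "cancel_time_ms", "flag"])
    log = pd.DataFrame(excluded, columns=["participant", "trial", "hand",
                                          "reason"])
    return table, log
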