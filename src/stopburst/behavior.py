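"""Behavioral performance: trial classification, lift-time trimming,
staircased SSD summary, and SSRT by the integration method."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def classify_go_trial(lift_left_ms: float, lift_right_ms: float,
                      target_ms: float = 800.0, tol_ms: float = 50.0) -> bool:
    """A Go trial is on-target iff both lifts are within +/-tol of the target."""
    if np.isnan(lift_left_ms) or np.isnan(lift_right_ms):
        raise ValueError("Go trials without both lifts are excluded, not classified")
    return abs(lift_left_ms - target_ms) <= tol_ms and \
        abs(lift_right_ms - target_ms) <= tol_ms


def trim_lift_times(values, n_sd: float = 3.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass +/- n_sd outlier trim.

    Mean and sample SD (ddof=1) are computed once on the full list; values
    outside mean +/- n_sd * SD are excluded. SD = 0 keeps everything.
    Returns (survivors, excluded indices).
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("need at least 3 values to trim")
    m, s = v.mean(), v.std(ddof=1)
    keep = np.abs(v - m) <= n_sd * s
    return v[keep], np.nonzero(~keep)[0]


def staircased_ssd(ssd_sequence, mode: str = "mean") -> float:
    """Summary SSD of the staircase: the delay at which it held ~50% success.

    ``mean`` (default) averages across Stop trials; ``last`` takes the final
    delay of the run.
    """
    s = np.asarray(ssd_sequence, float)
    s = s[~np.isnan(s)]
    if s.size == 0:
        raise ValueError("no Stop trials with an SSD")
    if mode == "mean":
        return float(s.mean())
    if mode == "last":
        return float(s[-1])
    raise ValueError(f"unknown staircased SSD mode {mode!r}")


def ssrt_integration(go_lift_times, p_respond_stop: float,
                     staircased_ssd_ms: float, rank: str = "ceil") -> float:
    """SSRT by the integration method.

    Trimmed Go lift-times (already averaged across hands) are rank-ordered
    and the nth value selected, n = p(respond | Stop) x N; the staircased
    SSD is subtracted. Non-integer n is realized as the ceiling rank
    (1-based) by default; ``rank='nearest'`` rounds instead.
    """
    if not 0.0 < p_respond_stop < 1.0:
        raise ValueError("p(respond | Stop) must be in (0, 1)")
    v = np.sort(np.asarray(go_lift_times, float))
    if v.size == 0:
        raise ValueError("empty lift-time list")
    n = p_respond_stop * v.size
    if rank == "ceil":
        k = math.ceil(n)
    elif rank == "nearest":
        k = int(round(n))
    else:
        raise ValueError(f"unknown rank rule {rank!r}")
    k = min(max(k, 1), v.size)
    return float(v[k - 1] - staircased_ssd_ms)


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-tailed p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def summarize_participant(trials: pd.DataFrame, target_ms: float = 800.0,
                          tol_ms: float = 50.0, trim_sd: float = 3.0,
                          ssd_mode: str = "mean", rank: str = "ceil") -> dict:
    """Behavioral summary for one participant's trial table.

    Returns mean lift-times per hand (trimmed), on-target rate, stop-success
    rate, p(respond | Stop), staircased SSD and the integration SSRT.
    """
    go = trials[trials["type"] == "Go"].copy()
    go = go.dropna(subset=["lift_left_ms", "lift_right_ms"])
    stop = trials[trials["type"] == "Stop"]
    if len(go) < 3 or len(stop) == 0:
        raise ValueError("insufficient trials for a behavioral summary")
    on_target = go.apply(lambda r: classify_go_trial(
        r["lift_left_ms"], r["lift_right_ms"], target_ms, tol_ms), axis=1)

    trimmed = {}
    for hand in ("left", "right"):
        kept, _ = trim_lift_times(go[f"lift_{hand}_ms"].to_numpy(), trim_sd)
        trimmed[hand] = kept
    # across-hand average per trial, then the same +/-3 SD trim before ranking
    both = go[["lift_left_ms", "lift_right_ms"]].mean(axis=1).to_numpy()
    both_trimmed, _ = trim_lift_times(both, trim_sd)

    p_respond = float((~stop["stop_success"].astype(bool)).mean())
    ssd = staircased_ssd(stop["ssd_ms"].to_numpy(), ssd_mode)
    if 0.0 < p_respond < 1.0:
        ssrt = ssrt_integration(both_trimmed, p_respond, ssd, rank)
    else:
        ssrt = float("nan")
    return {
        "n_go": int(len(go)),
        "n_stop": int(len(stop)),
        "mean_lift_left_ms": float(trimmed["left"].mean()),
        "mean_lift_right_ms": float(trimmed["right"].mean()),
        "lift_sd_ms": float(both_trimmed.std(ddof=1)),
        "mean_lift_ms": float(both_trimmed.mean()),
        "on_target_rate": float(on_target.mean()),
        "stop_success_rate": float(stop["stop_success"].astype(bool).mean()),
        "p_respond_stop": p_respond,
        "staircased_ssd_ms": float(ssd),
        "ssrt_ms": float(ssrt),
    }


def summarize_all(trials: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-participant behavioral summaries as a DataFrame."""
    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        s = summarize_participant(sub, **kwargs)
        s["participant"] = pid
        rows.append(s)
    return pd.DataFrame(rows).set_index("participant")
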