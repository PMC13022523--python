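"""Post hoc temporal analysis around partial muscle bursts.

For every retained successful Stop trial the time bin containing the partial
muscle burst is extracted together with its two directly adjacent bins.
Trials with multiple partial bursts, with the burst in the final bin (no
following bin) or in the first bin (no preceding bin) are excluded. A
one-way ANOVA over the three positions (before / during / after the muscle
burst) is run on participant-level mean burst rates, with eta-squared and
Bonferroni-corrected pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

POSITIONS = ("before", "during", "after")


def posthoc_bin_extraction(partial_bins: pd.DataFrame, n_bins: int = 10
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial (bin-1, bin, bin+1) triplets around partial-burst bins.

    ``partial_bins`` needs columns participant, trial, bin (0-based).
    Returns (triplets, exclusions); exclusion reasons are multiple_bursts,
    final_bin and first_bin.
    """
    trips, excl = [], []
    for (pid, trial), grp in partial_bins.groupby(["participant", "trial"]):
        if len(grp) > 1:
            excl.append((pid, trial, "multiple_bursts"))
            continue
        b = int(grp["bin"].iloc[0])
        if b == n_bins - 1:
            excl.append((pid, trial, "final_bin"))
        elif b == 0:
            excl.append((pid, trial, "first_bin"))
        else:
            trips.append((pid, trial, b - 1, b, b + 1))
    triplets = pd.DataFrame(trips, columns=["participant", "trial",
                                            "bin_before", "bin_during",
                                            "bin_after"])
    exclusions = pd.DataFrame(excl, columns=["participant", "trial",
                                             "reason"])
    return triplets, exclusions


@dataclass
class AnovaResult:
    F: float
    p: float
    df: tuple[int, int]
    eta_squared: float
    means: dict
    pairwise: pd.DataFrame        # position pair, t, p (Bonferroni)


def anova_time(values: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA over the three bin positions.

    ``values`` is participants x 3 (columns before/during/after) of
    participant-level mean burst rates; incomplete rows are dropped
    listwise. The omnibus test treats the three positions as groups
    (df = (2, 3n-3)); pairwise comparisons are paired t tests with
    Bonferroni correction.
    """
    v = values[list(POSITIONS)].dropna()
    n = len(v)
    if n < 2:
        raise ValueError("need >= 2 participants with complete triplets")
    cols = [v[c].to_numpy() for c in POSITIONS]
    F, p = stats.f_oneway(*cols)
    grand = np.concatenate(cols).mean()
    ss_total = float(((np.concatenate(cols) - grand) ** 2).sum())
    ss_effect = float(sum(len(c) * (c.mean() - grand) ** 2 for c in cols))
    eta2 = ss_effect / ss_total if ss_total > 0 else 0.0
    pairs = []
    for i in range(3):
        for j in range(i + 1, 3):
            if np.allclose(cols[i], cols[j]):
                t, pp = 0.0, 1.0
            else:
                t, pp = stats.ttest_rel(cols[i], cols[j])
            pairs.append((POSITIONS[i], POSITIONS[j], float(t),
                          float(min(pp * 3, 1.0))))
    pairwise = pd.DataFrame(pairs, columns=["a", "b", "t", "p_bonf"])
    return AnovaResult(F=float(F), p=float(p), df=(2, 3 * n - 3),
                       eta_squared=float(eta2),
                       means={c: float(v[c].mean()) for c in POSITIONS},
                       pairwise=pairwise)


def triplet_rates(features: pd.DataFrame, triplets: pd.DataFrame,
                  channels: list[str]) -> pd.DataFrame:
    """Participant-level mean burst rate at the three positions, averaged
    over ``channels`` (e.g., the significant cluster's electrodes)."""
    sub = features[features["channel"].isin(channels)]
    rows = []
    for _, tr in triplets.iterrows():
        sel = sub[(sub["participant"] == tr["participant"])
                  & (sub["trial"] == tr["trial"])]
        vals = {}
        for pos, col in zip(POSITIONS, ("bin_before", "bin_during",
                                        "bin_after")):
            vals[pos] = sel.loc[sel["bin"] == tr[col], "rate"].mean()
        rows.append({"participant": tr["participant"],
                     "trial": tr["trial"], **vals})
    per_trial = pd.DataFrame(rows)
    if per_trial.empty:
        return pd.DataFrame(columns=["participant", *POSITIONS])
    return per_trial.groupby("participant", as_index=False)[
        list(POSITIONS)].mean()
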