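"""End-to-end orchestration: simulate -> time-frequency -> bursts ->
behavior -> EMG -> mass LMM-TFCE statistics -> post hoc timing.

Each stage reads the previous stage's files from the output directory, so
stages can be re-run independently. Every output carries the configuration
hash; the run log accounts for every excluded trial by rule.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, bursts, emg, io, posthoc, simulate, tfce, timefreq
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "behavior", "emg", "stats", "posthoc",
          "report")


class PipelineError(RuntimeError):
    """A stage failed, typically because an upstream output is missing."""


def _out(config: PipelineConfig, output_dir=None) -> Path:
    p = Path(output_dir or config.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' requires missing input {path}; run the "
            "upstream stage first")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path,
                   seed: int | None = None) -> None:
    sim = config.simulation
    if seed is not None:
        sim = simulate.dataclass_replace_seed(sim, seed)
    sim.validate()
    pdir = out / "participants"
    pdir.mkdir(exist_ok=True)
    tables, gts = [], []
    for idx in range(sim.n_participants):
        ep, em, tr, gt = simulate.generate_participant(sim, idx)
        pid = tr["participant"].iloc[0]
        io.write_epochs(pdir / f"{pid}_eeg.h5", ep)
        io.write_emg(pdir / f"{pid}_emg.h5", em)
        tables.append(tr)
        gts.append(gt)
    trials = pd.concat(tables, ignore_index=True)
    io.write_trial_table(out / "trials.tsv", trials)
    gt_all = simulate.GroundTruth(
        eeg_bursts=pd.concat([g.eeg_bursts for g in gts], ignore_index=True),
        emg_bursts=pd.concat([g.emg_bursts for g in gts], ignore_index=True),
        true_ssrt=sim.true_ssrt,
        reference_ms=pd.concat([g.reference_ms for g in gts],
                               ignore_index=True))
    io.write_ground_truth(out / "ground_truth.json", gt_all)


def stage_behavior(config: PipelineConfig, out: Path) -> pd.DataFrame:
    trials = io.read_trial_table(_require(out / "trials.tsv", "behavior"))
    ana = config.analysis
    summary = behavior.summarize_all(
        trials, target_ms=config.simulation.target_time,
        tol_ms=ana.on_target_tol, trim_sd=ana.trim_sd,
        ssd_mode=ana.staircased_ssd_mode, rank=ana.ssrt_rank)
    summary.reset_index().to_json(out / "behavior_summary.json",
                                  orient="records", indent=1)
    return summary


def stage_features(config: PipelineConfig, out: Path,
                   summary: pd.DataFrame) -> None:
    """Time-frequency decomposition, burst detection and binning."""
    trials = io.read_trial_table(_require(out / "trials.tsv", "features"))
    ana = config.analysis
    feats, excls, events_all = [], [], []
    for pid, sub in trials.groupby("participant", sort=True):
        ep = io.read_epochs(_require(out / "participants" / f"{pid}_eeg.h5",
                                     "features"))
        tf_raw = timefreq.tf_power(ep.data, ep.sfreq, ep.times_ms)
        tf_db = timefreq.db_normalize(tf_raw, ana.baseline_window,
                                      ana.baseline_per_trial)
        events = bursts.detect_all_bursts(
            tf_raw, pid, sub["trial"].to_numpy(), ep.channels,
            ana.threshold_factor, ana.volume_integrand)
        events_all.append(events)
        go = sub[sub["type"] == "Go"]
        on_target = go.apply(lambda r: behavior.classify_go_trial(
            r["lift_left_ms"], r["lift_right_ms"],
            config.simulation.target_time, ana.on_target_tol), axis=1)
        on_target = on_target.reindex(sub.index)
        refs = bursts.make_references(sub, summary.loc[pid, "ssrt_ms"],
                                      on_target, ana.ssd_cap)
        f, e = bursts.extract_binned_features(
            tf_raw, tf_db, events, sub, refs, pid, ep.channels,
            ana.n_bins, ana.bin_ms)
        feats.append(f)
        excls.append(e)
    pd.concat(feats, ignore_index=True).to_csv(out / "features.tsv",
                                               sep="\t", index=False)
    pd.concat(events_all, ignore_index=True).to_csv(
        out / "burst_events.tsv", sep="\t", index=False)
    pd.concat(excls, ignore_index=True).to_csv(
        out / "feature_exclusions.tsv", sep="\t", index=False)


def stage_emg(config: PipelineConfig, out: Path,
              summary: pd.DataFrame) -> None:
    trials = io.read_trial_table(_require(out / "trials.tsv", "emg"))
    ana = config.analysis
    tables, logs = [], []
    for pid, sub in trials.groupby("participant", sort=True):
        em = io.read_emg(_require(out / "participants" / f"{pid}_emg.h5",
                                  "emg"))
        tab, log = emg.process_participant(
            em.data, em.times_ms, em.sfreq, sub.reset_index(drop=True),
            summary.loc[pid, "mean_lift_ms"], summary.loc[pid, "lift_sd_ms"],
            hands=em.hands, smooth_ms=ana.emg_smooth_ms,
            n_sd=ana.emg_threshold_sd, min_duration_ms=ana.emg_min_duration,
            merge_gap_ms=ana.emg_merge_gap, exclude_rms_uv=ana.emg_exclude_rms,
            refine=ana.emg_refine, refine_window_ms=ana.emg_refine_window,
            refine_sd=ana.emg_refine_sd, trim_n_sd=ana.trim_sd)
        tables.append(tab)
        logs.append(log)
    pd.concat(tables, ignore_index=True).to_csv(out / "emg_bursts.tsv",
                                                sep="\t", index=False)
    pd.concat(logs, ignore_index=True).to_csv(out / "emg_exclusions.tsv",
                                              sep="\t", index=False)


def assemble_mass_data(features: pd.DataFrame, feature: str,
                       channels: list[str], n_bins: int
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Pivot long features into a (channels x bins) x trials matrix.

    Returns (Y, trial_info) with trial_info rows aligned to Y columns.
    """
    wide = features.pivot_table(index=["participant", "trial"],
                                columns=["channel", "bin"], values=feature)
    cols = pd.MultiIndex.from_product([channels, range(n_bins)])
    wide = wide.reindex(columns=cols).dropna(axis=0)
    info = wide.index.to_frame(index=False)
    return wide.to_numpy().T, info


def stage_stats(config: PipelineConfig, out: Path, seed: int | None = None,
                n_permutations: int | None = None) -> dict:
    trials = io.read_trial_table(_require(out / "trials.tsv", "stats"))
    features = pd.read_csv(_require(out / "features.tsv", "stats"), sep="\t")
    ana = config.analysis
    n_perm = n_permutations or ana.n_permutations
    rng = np.random.default_rng(seed)
    channels = list(config.simulation.channel_layout)
    positions = np.array([config.simulation.channel_layout[c]
                          for c in channels])
    chan_adj = tfce.channel_adjacency(positions, ana.adjacency_method,
                                      ana.adjacency_distance)
    sdir = out / "stats"
    sdir.mkdir(exist_ok=True)
    trials_key = trials.set_index(["participant", "trial"])

    partial_trials = set()
    emg_path = out / "emg_bursts.tsv"
    if emg_path.exists():
        eb = pd.read_csv(emg_path, sep="\t")
        partial = eb[eb["cls"] == "partial"]
        partial_trials = set(zip(partial["participant"], partial["trial"]))

    summary = {}
    for feature in config.features:
        for contrast in config.contrasts:
            Y, info = assemble_mass_data(features, feature, channels,
                                         ana.n_bins)
            key = list(zip(info["participant"], info["trial"]))
            ttype = trials_key.loc[key, "type"].to_numpy()
            if contrast == "TrialType":
                x = np.where(ttype == "Stop", 1.0, -1.0)
                keep = np.ones(len(info), bool)
            elif contrast == "MuscleBurst":
                keep = ttype == "Stop"
                if not emg_path.exists():
                    raise PipelineError("MuscleBurst contrast requires the "
                                        "emg stage output")
                x = np.array([1.0 if k in partial_trials else -1.0
                              for k in key])
            else:
                raise PipelineError(f"unknown contrast {contrast!r}")
            groups = info["participant"].to_numpy()[keep]
            if len(np.unique(x[keep])) < 2 or len(np.unique(groups)) < 2:
                logger.warning("skipping %s/%s: a predictor level or "
                               "participant is missing", feature, contrast)
                continue
            X = np.column_stack([np.ones(keep.sum()), x[keep]])
            result = tfce.lmm_tfce(Y[:, keep], X, groups, chan_adj,
                                   ana.n_bins, n_perm, rng, ana.tfce_e,
                                   ana.tfce_h, ana.tfce_dh_frac, ana.alpha)
            name = f"{feature}_{contrast}"
            io.write_tfce_result(sdir / f"{name}.tsv", result, channels)
            summary[name] = {
                "n_trials": int(keep.sum()),
                "n_significant": int(result.mask.sum()),
                "max_abs_t": float(np.abs(result.t_map).max()),
                "significant_channels": sorted(
                    {channels[c] for c, b in zip(*np.nonzero(result.mask))}),
            }
    with open(sdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def stage_posthoc(config: PipelineConfig, out: Path) -> dict | None:
    """Burst-rate timing around partial muscle bursts."""
    features = pd.read_csv(_require(out / "features.tsv", "posthoc"),
                           sep="\t")
    eb = pd.read_csv(_require(out / "emg_bursts.tsv", "posthoc"), sep="\t")
    trials = io.read_trial_table(_require(out / "trials.tsv", "posthoc"))
    ana = config.analysis
    summary = behavior.summarize_all(trials)
    partial = eb[eb["cls"] == "partial"].copy()
    if partial.empty:
        return None
    rows = []
    for _, b in partial.iterrows():
        ssrt = summary.loc[b["participant"], "ssrt_ms"]
        tr = trials[(trials["participant"] == b["participant"])
                    & (trials["trial"] == b["trial"])].iloc[0]
        ref = tr["ssd_ms"] + ssrt
        bin_idx = bursts.assign_bin(b["peak_time_ms"], ref, ana.n_bins,
                                    ana.bin_ms)
        if bin_idx >= 0:
            rows.append((b["participant"], b["trial"], bin_idx))
    if not rows:
        return None
    pbins = pd.DataFrame(rows, columns=["participant", "trial", "bin"])
    pbins = pbins.drop_duplicates()       # both hands carry the same burst
    triplets, excl = posthoc.posthoc_bin_extraction(pbins, ana.n_bins)
    stats_summary_path = out / "stats" / "summary.json"
    cluster = list(config.simulation.channel_layout)
    if stats_summary_path.exists():
        with open(stats_summary_path) as fh:
            ss = json.load(fh)
        sig = ss.get("rate_MuscleBurst", {}).get("significant_channels", [])
        if sig:
            cluster = sig
    table = posthoc.triplet_rates(features, triplets, cluster)
    if len(table) < 2:
        return None
    res = posthoc.anova_time(table)
    payload = {"F": res.F, "p": res.p, "df": list(res.df),
               "eta_squared": res.eta_squared, "means": res.means,
               "cluster_channels": cluster,
               "n_excluded": int(len(excl)),
               "pairwise": res.pairwise.to_dict(orient="records")}
    with open(out / "posthoc.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload


def export_maps(config: PipelineConfig, out: Path) -> list[Path]:
    """Topographic-grid figures: one per feature x contrast, 10 panels of
    channel-position scatter maps colored by t, significant channels marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sdir = _require(out / "stats", "report")
    fdir = out / "figures"
    fdir.mkdir(exist_ok=True)
    layout = config.simulation.channel_layout
    paths = []
    for tsv in sorted(sdir.glob("*_*.tsv")):
        df = pd.read_csv(tsv, sep="\t")
        n_bins = df["bin"].nunique()
        vmax = max(np.abs(df["t"]).max(), 1e-9)
        fig, axes = plt.subplots(1, n_bins, figsize=(2 * n_bins, 2.4))
        for b, ax in zip(range(n_bins), np.atleast_1d(axes)):
            sub = df[df["bin"] == b]
            xs = [layout[c][0] for c in sub["channel"]]
            ys = [layout[c][1] for c in sub["channel"]]
            sc = ax.scatter(xs, ys, c=sub["t"], cmap="RdBu_r",
                            vmin=-vmax, vmax=vmax, s=60)
            sig = sub[sub["significant"]]
            if len(sig):
                ax.scatter([layout[c][0] for c in sig["channel"]],
                           [layout[c][1] for c in sig["channel"]],
                           facecolors="none", edgecolors="k", s=120)
            ax.set_title(f"bin {b + 1}", fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
            ax.set_aspect("equal")
        fig.colorbar(sc, ax=np.atleast_1d(axes).tolist(), shrink=0.7,
                     label="t")
        path = fdir / f"{tsv.stem}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, seed: int | None = None,
                 output_dir=None, stages=STAGES,
                 n_permutations: int | None = None) -> dict:
    """Run the requested stages in dependency order; returns the run log."""
    config.validate()
    out = _out(config, output_dir)
    log = {"config_hash": config.hash(), "stages": list(stages)}
    if "simulate" in stages:
        stage_simulate(config, out, seed)
    summary = None
    if {"behavior", "features", "emg"} & set(stages):
        summary = stage_behavior(config, out)
        log["behavior"] = {
            "mean_ssrt_ms": float(summary["ssrt_ms"].mean()),
            "mean_stop_success": float(summary["stop_success_rate"].mean()),
        }
    if "features" in stages:
        stage_features(config, out, summary)
    if "emg" in stages:
        stage_emg(config, out, summary)
    if "stats" in stages:
        log["stats"] = stage_stats(config, out, seed, n_permutations)
    if "posthoc" in stages:
        log["posthoc"] = stage_posthoc(config, out)
    if "report" in stages:
        log["figures"] = [str(p) for p in export_maps(config, out)]
    # exclusion accounting
    counts = {}
    for name in ("feature_exclusions.tsv", "emg_exclusions.tsv"):
        p = out / name
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            counts[name] = df["reason"].value_counts().to_dict() \
                if len(df) else {}
    log["exclusions"] = counts
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return log
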