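"""File formats: HDF5 epochs, TSV tables, JSON summaries."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .simulate import EMGEpochs, EpochSet
from .tfce import TFCEResult

TRIAL_COLUMNS = ["participant", "trial", "type", "lift_left_ms",
                 "lift_right_ms", "ssd_ms", "stop_success"]


def write_epochs(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("channels",
                         data=np.array(epochs.channels, dtype="S"))
        f.create_dataset("positions", data=epochs.positions)
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.attrs["sfreq"] = epochs.sfreq


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            channels=[c.decode() for c in f["channels"][()]],
            positions=f["positions"][()],
            sfreq=float(f.attrs["sfreq"]),
            times_ms=f["times_ms"][()],
        )


def write_emg(path, emg: EMGEpochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=emg.data, compression="gzip")
        f.create_dataset("times_ms", data=emg.times_ms)
        f.create_dataset("hands", data=np.array(emg.hands, dtype="S"))
        f.attrs["sfreq"] = emg.sfreq


def read_emg(path) -> EMGEpochs:
    with h5py.File(path, "r") as f:
        return EMGEpochs(data=f["data"][()], sfreq=float(f.attrs["sfreq"]),
                         times_ms=f["times_ms"][()],
                         hands=tuple(h.decode() for h in f["hands"][()]))


def write_trial_table(path, trials: pd.DataFrame) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["stop_success"] = df["stop_success"].astype("boolean")
    return df


def write_ground_truth(path, gt) -> None:
    payload = {
        "true_ssrt": gt.true_ssrt,
        "eeg_bursts": gt.eeg_bursts.to_dict(orient="list"),
        "emg_bursts": gt.emg_bursts.to_dict(orient="list"),
        "reference_ms": gt.reference_ms.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_ground_truth(path):
    from .simulate import GroundTruth
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(eeg_bursts=pd.DataFrame(d["eeg_bursts"]),
                       emg_bursts=pd.DataFrame(d["emg_bursts"]),
                       true_ssrt=d["true_ssrt"],
                       reference_ms=pd.DataFrame(d["reference_ms"]))


def write_tfce_result(path, result: TFCEResult, channels: list[str]) -> None:
    """TFCE maps as long-format TSV (channel, bin, t, tfce, p, significant)."""
    n_ch, n_bins = result.t_map.shape
    rows = []
    for c in range(n_ch):
        for b in range(n_bins):
            rows.append((channels[c], b, result.t_map[c, b],
                         result.tfce_map[c, b], result.p_map[c, b],
                         bool(result.mask[c, b])))
    pd.DataFrame(rows, columns=["channel", "bin", "t", "tfce", "p",
                                "significant"]).to_csv(path, sep="\t",
                                                       index=False)


def read_epochs_fif(path) -> EpochSet:
    """Load real preprocessed epochs from an MNE FIF file (optional)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading FIF files requires mne "
                          "(pip install stopburst[eeg-io])") from err
    ep = mne.read_epochs(path, preload=True, verbose="error")
    data = ep.get_data().transpose(1, 2, 0) * 1e6        # to uV
    montage_pos = []
    for ch in ep.ch_names:
        loc = ep.info["chs"][ep.ch_names.index(ch)]["loc"][:2]
        montage_pos.append(loc)
    return EpochSet(data=data, channels=list(ep.ch_names),
                    positions=np.array(montage_pos), sfreq=ep.info["sfreq"],
                    times_ms=ep.times * 1000.0)
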