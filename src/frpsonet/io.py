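"""Containers on disk.

Epoched trial sets, feature maps, SPD matrices and model checkpoints
live in HDF5 files with a fixed dataset layout; continuous recordings
pair an HDF5 EEG container with plain-CSV gaze and event tables.  EDF
continuous EEG can be read when the optional ``mne`` dependency is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import ChannelLayout, EEGTrialSet, RawRecording, make_channel_layout

__all__ = [
    "save_trialset",
    "load_trialset",
    "save_recording",
    "load_recording",
    "save_feature_maps",
    "load_feature_maps",
    "save_spd",
    "load_spd",
    "read_raw_edf",
]


def save_trialset(path: str | Path, ts: EEGTrialSet) -> None:
    """Write an epoched trial set: /data, /labels, /fs, /channels, /order."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("labels", data=ts.labels)
        f.create_dataset("fs", data=float(ts.fs))
        f.create_dataset("channels", data=np.array(ts.layout.names, dtype="S"))
        f.create_dataset("spatial_weight", data=ts.layout.spatial_weight)
        f.create_dataset("order", data=ts.order)


def load_trialset(path: str | Path) -> EEGTrialSet:
    with h5py.File(path, "r") as f:
        names = tuple(n.decode() for n in f["channels"][()])
        layout = ChannelLayout(names=names, spatial_weight=f["spatial_weight"][()])
        return EEGTrialSet(data=f["data"][()], labels=f["labels"][()],
                           fs=float(f["fs"][()]), layout=layout, order=f["order"][()])


def save_recording(prefix: str | Path, rec: RawRecording) -> dict[str, Path]:
    """Write a continuous session: <prefix>.h5 (EEG), _gaze.csv, _events.csv.

    Gaze columns: time_ms, x_deg, y_deg.  Event columns: sample, x_deg,
    y_deg, is_target.
    """
    prefix = Path(prefix)
    eeg_path = prefix.with_suffix(".h5")
    gaze_path = prefix.parent / (prefix.name + "_gaze.csv")
    events_path = prefix.parent / (prefix.name + "_events.csv")
    with h5py.File(eeg_path, "w") as f:
        f.create_dataset("eeg", data=rec.eeg)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("channels", data=np.array(rec.layout.names, dtype="S"))
        f.create_dataset("spatial_weight", data=rec.layout.spatial_weight)
    t_ms = np.arange(rec.gaze.shape[0]) / rec.fs * 1000.0
    pd.DataFrame({"time_ms": t_ms, "x_deg": rec.gaze[:, 0],
                  "y_deg": rec.gaze[:, 1]}).to_csv(gaze_path, index=False)
    pd.DataFrame([{"sample": s, "x_deg": c[0], "y_deg": c[1], "is_target": int(t)}
                  for (s, c, t) in rec.events]).to_csv(events_path, index=False)
    return {"eeg": eeg_path, "gaze": gaze_path, "events": events_path}


def load_recording(eeg_path: str | Path, gaze_path: str | Path,
                   events_path: str | Path) -> RawRecording:
    eeg_path = Path(eeg_path)
    if eeg_path.suffix.lower() == ".edf":
        eeg, fs, layout = read_raw_edf(eeg_path)
    else:
        with h5py.File(eeg_path, "r") as f:
            eeg = f["eeg"][()]
            fs = float(f["fs"][()])
            names = tuple(n.decode() for n in f["channels"][()])
            layout = ChannelLayout(names=names, spatial_weight=f["spatial_weight"][()])
    gaze = pd.read_csv(gaze_path)[["x_deg", "y_deg"]].to_numpy()
    ev = pd.read_csv(events_path)
    events = [(int(r.sample), (float(r.x_deg), float(r.y_deg)), bool(r.is_target))
              for r in ev.itertuples()]
    return RawRecording(eeg=eeg, gaze=gaze, events=events, fs=fs, layout=layout)


def read_raw_edf(path: str | Path):
    """Read continuous EEG from EDF via mne (optional dependency); returns uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    eeg = raw.get_data() * 1e6  # volts -> microvolts
    names = tuple(raw.ch_names)
    if len(names) == 19:
        layout = ChannelLayout(names=names,
                               spatial_weight=make_channel_layout().spatial_weight)
    else:  # pragma: no cover - montage mismatch path
        raise ValueError(f"expected 19 channels, EDF has {len(names)}")
    return eeg, float(raw.info["sfreq"]), layout


def save_feature_maps(path: str | Path, maps: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=np.asarray(maps))


def load_feature_maps(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["maps"][()]


def save_spd(path: str | Path, spd: np.ndarray, template: np.ndarray | None,
             lam: float) -> None:
    """SPD container: /spd (n, 2D, 2D), /template (D, N), /lambda."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spd", data=np.asarray(spd))
        if template is not None:
            f.create_dataset("template", data=np.asarray(template))
        f.create_dataset("lambda", data=float(lam))


def load_spd(path: str | Path):
    with h5py.File(path, "r") as f:
        template = f["template"][()] if "template" in f else None
        return f["spd"][()], template, float(f["lambda"][()])


def save_checkpoint(path: str | Path, arrays: dict, config: dict) -> None:
    """Single-file model checkpoint: arrays plus a JSON-encoded config attr."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(config)
        for key, value in arrays.items():
            f.create_dataset(key, data=np.asarray(value))


def load_checkpoint(path: str | Path):
    with h5py.File(path, "r") as f:
        config = json.loads(f.attrs["config"])
        arrays = {key: f[key][()] for key in f.keys()}
    return arrays, config
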