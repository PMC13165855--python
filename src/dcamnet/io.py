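"""Readers and writers for continuous EEG, epoch stores, and label streams.

Continuous EEG comes in as EDF (via :mod:`mne`, optional dependency), HDF5,
or CSV array dumps (channels x time with a JSON sidecar carrying the
sampling rate, channel names, and subject id).  Epoch collections round-trip
through a single HDF5 file holding samples, labels, subjects, and optionally
the cached band tensors.  Behavioral streams use plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .labeling import DeviationEvent, EyeEpochDurations, SessionEvents

__all__ = [
    "read_edf",
    "read_continuous",
    "write_epochs_hdf5",
    "load_epochs_hdf5",
    "read_deviation_events_csv",
    "read_eye_epochs_csv",
    "write_labels_csv",
]


def read_edf(path):
    """Continuous EEG from EDF: returns (data uV (C, T), fs, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def read_continuous(path):
    """Dispatch on suffix: .edf, .h5/.hdf5, or .csv (with `<stem>.json` sidecar).

    Returns ``(data (C, T), fs, channel_names, subject_id)``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        data, fs, names = read_edf(path)
        return data, fs, names, path.stem
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = np.asarray(f["data"])
            fs = float(f.attrs["fs"])
            names = [str(n) for n in f.attrs.get("channel_names", [])]
            subject = str(f.attrs.get("subject_id", path.stem))
        return data, fs, names or [f"CH{i+1}" for i in range(data.shape[0])], subject
    if suffix == ".csv":
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        data = pd.read_csv(path, header=None).to_numpy(dtype=float)
        names = meta.get("channel_names") or [f"CH{i+1}" for i in range(data.shape[0])]
        return data, float(meta["fs"]), names, str(meta.get("subject_id", path.stem))
    raise ValueError(f"unsupported recording format: {path.suffix!r}")


def write_epochs_hdf5(path, X, y, subjects, fs, channel_names=None, band_tensor=None):
    """Store an epoch collection (and optionally its band-tensor cache)."""
    X = np.asarray(X)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=X)
        f.create_dataset("labels", data=np.asarray(y, dtype=np.int64))
        f.create_dataset(
            "subjects", data=np.asarray([str(s) for s in subjects], dtype="S32")
        )
        f.attrs["fs"] = float(fs)
        if channel_names is not None:
            f.attrs["channel_names"] = [str(n) for n in channel_names]
        if band_tensor is not None:
            f.create_dataset("band_tensor", data=np.asarray(band_tensor))


def load_epochs_hdf5(path):
    """Inverse of :func:`write_epochs_hdf5`; returns a plain dict."""
    with h5py.File(path, "r") as f:
        out = {
            "X": np.asarray(f["epochs"]),
            "y": np.asarray(f["labels"]),
            "subjects": np.array([s.decode() for s in f["subjects"]]),
            "fs": float(f.attrs["fs"]),
            "channel_names": [str(n) for n in f.attrs.get("channel_names", [])],
        }
        if "band_tensor" in f:
            out["band_tensor"] = np.asarray(f["band_tensor"])
    return out


def read_deviation_events_csv(path) -> dict[str, SessionEvents]:
    """CSV with columns subject_id, dep_s, act_s -> one session per subject."""
    df = pd.read_csv(path)
    sessions = {}
    for subject, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("dep_s")
        events = [
            DeviationEvent(dep=float(r.dep_s), act=float(r.act_s))
            for r in grp.itertuples()
        ]
        sessions[str(subject)] = SessionEvents(events, subject_id=str(subject))
    return sessions


def read_eye_epochs_csv(path) -> dict[str, list[EyeEpochDurations]]:
    """CSV with subject_id, epoch_index, t_blink, t_fixation, t_saccade, t_closure."""
    df = pd.read_csv(path)
    out: dict[str, list[EyeEpochDurations]] = {}
    for subject, grp in df.groupby("subject_id", sort=False):
        out[str(subject)] = [
            EyeEpochDurations(
                t_blink=float(r.t_blink),
                t_fixation=float(r.t_fixation),
                t_saccade=float(r.t_saccade),
                t_closure=float(r.t_closure),
                epoch_index=int(r.epoch_index),
            )
            for r in grp.sort_values("epoch_index").itertuples()
        ]
    return out


def write_labels_csv(path, rows):
    """Rows of (subject_id, epoch_index, label) -> CSV."""
    pd.DataFrame(rows, columns=["subject_id", "epoch_index", "label"]).to_csv(
        path, index=False
    )
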