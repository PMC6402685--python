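"""Container I/O: HDF5 recordings/epochs, EDF import, VAS CSV tables.

The internal container is plain HDF5 with a documented layout:

recordings (``save_recording``)::

    /data               channels x samples, float64
    /trigger_samples    int64 trial onsets
    attrs: fs_hz, channel_labels, annotations

epoch sets (``save_epochs``)::

    /<target label>/data   epochs(/trials) x channels x samples
    attrs on each group: fs_hz, target_label

User-supplied EDF recordings are read through MNE; trigger onsets are
taken from the EDF annotations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preproc import EpochArray
from .synthdata import EEGRecording, VASTable

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "read_edf",
    "save_vas_csv",
    "load_vas_csv",
]


def save_recording(path, rec: EEGRecording) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("trigger_samples", data=rec.trigger_samples)
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["channel_labels"] = list(rec.channel_labels)
        f.attrs["annotations"] = list(rec.annotations)


def load_recording(path) -> EEGRecording:
    import h5py

    with h5py.File(path, "r") as f:
        return EEGRecording(
            data=f["data"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            trigger_samples=f["trigger_samples"][()],
            channel_labels=tuple(str(c) for c in f.attrs["channel_labels"]),
            annotations=tuple(str(a) for a in f.attrs["annotations"]),
        )


def save_epochs(path, epochs: dict[str, EpochArray | list[EpochArray]]) -> None:
    """Write per-target epochs; lists of trial EpochArrays are stacked
    into a trials x epochs x channels x samples dataset."""
    import h5py

    with h5py.File(path, "w") as f:
        for label, ep in epochs.items():
            grp = f.create_group(label)
            if isinstance(ep, list):
                grp.create_dataset("data", data=np.stack([t.data for t in ep]))
                grp.attrs["fs_hz"] = ep[0].fs_hz
                grp.attrs["per_trial"] = True
            else:
                grp.create_dataset("data", data=ep.data)
                grp.attrs["fs_hz"] = ep.fs_hz
                grp.attrs["per_trial"] = False


def load_epochs(path) -> dict[str, EpochArray | list[EpochArray]]:
    import h5py

    out: dict[str, EpochArray | list[EpochArray]] = {}
    with h5py.File(path, "r") as f:
        for label in f:
            grp = f[label]
            data = grp["data"][()]
            fs = float(grp.attrs["fs_hz"])
            if bool(grp.attrs.get("per_trial", False)):
                out[label] = [
                    EpochArray(trial, fs_hz=fs, target_label=label) for trial in data
                ]
            else:
                out[label] = EpochArray(data, fs_hz=fs, target_label=label)
    return out


def read_edf(path, trigger_annotation: str | None = None) -> EEGRecording:
    """Import an EDF recording via MNE; annotations become trial triggers.

    ``trigger_annotation`` restricts which annotation descriptions count
    as trial onsets (default: all).
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    onsets, labels = [], []
    for ann in raw.annotations:
        if trigger_annotation is None or ann["description"] == trigger_annotation:
            onsets.append(int(round(ann["onset"] * raw.info["sfreq"])))
            labels.append(str(ann["description"]))
    return EEGRecording(
        data=raw.get_data(),
        fs_hz=float(raw.info["sfreq"]),
        trigger_samples=np.asarray(onsets, dtype=np.int64),
        channel_labels=tuple(raw.ch_names),
        annotations=tuple(labels),
    )


def save_vas_csv(path, table: VASTable) -> None:
    table.scores.to_csv(path, index_label="subject")


def load_vas_csv(path) -> VASTable:
    df = pd.read_csv(path, index_col="subject")
    return VASTable(scores=df)
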