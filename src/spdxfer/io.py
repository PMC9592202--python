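"""Reading and writing epoch containers.

The native container is HDF5 with one group per subject::

    /fs                      scalar sampling rate (attr)
    /channels                channel-name list (attr)
    /subjects/<id>/X         (n_trials, n_channels, n_samples) float array
    /subjects/<id>/y         (n_trials,) int labels, 0 = unlabelled

A CSV label manifest (subject, trial, label) can be written alongside.  A
reader for the BCI-competition MAT layout (continuous ``cnt`` recording with
``mrk`` cue positions) is provided for users with the public motor-imagery
archives; no such data ships with the package.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .riemann import TrialEpoch

__all__ = ["save_dataset", "load_dataset", "write_label_manifest", "load_bci_mat"]


def save_dataset(
    path: str | Path,
    dataset: dict[str, list[TrialEpoch]],
    fs: float = 100.0,
    channels: list[str] | None = None,
) -> None:
    """Write per-subject epoch lists to the HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = float(fs)
        if channels is not None:
            f.attrs["channels"] = [str(c) for c in channels]
        grp = f.create_group("subjects")
        for sid, epochs in dataset.items():
            X = np.stack([e.samples for e in epochs])
            y = np.array([0 if e.label is None else e.label for e in epochs])
            g = grp.create_group(sid)
            g.create_dataset("X", data=X)
            g.create_dataset("y", data=y)


def load_dataset(path: str | Path) -> tuple[dict[str, list[TrialEpoch]], float]:
    """Read an HDF5 epoch container back into per-subject epoch lists."""
    dataset: dict[str, list[TrialEpoch]] = {}
    with h5py.File(path, "r") as f:
        fs = float(f.attrs.get("fs", 100.0))
        for sid, g in f["subjects"].items():
            X = np.asarray(g["X"])
            y = np.asarray(g["y"])
            dataset[sid] = [
                TrialEpoch(
                    samples=X[i],
                    subject_id=sid,
                    label=None if y[i] == 0 else int(y[i]),
                )
                for i in range(X.shape[0])
            ]
    return dataset, fs


def write_label_manifest(path: str | Path, dataset: dict[str, list[TrialEpoch]]) -> None:
    """Write a (subject, trial, label) CSV manifest; 0 marks unlabelled."""
    rows = [
        {"subject": sid, "trial": i, "label": 0 if e.label is None else e.label}
        for sid, epochs in dataset.items()
        for i, e in enumerate(epochs)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_bci_mat(path: str | Path) -> dict:
    """Load a BCI-competition-style MAT file (continuous layout).

    Expects variables ``cnt`` (samples x channels, 0.1 microvolt integers),
    ``mrk`` (fields ``pos`` and ``y``) and ``nfo`` (fields ``fs`` and
    ``clab``).  Returns a dict with the continuous signal in microvolts
    (channels x samples), cue sample positions, cue labels and metadata.
    Trials are cut from the continuous signal with
    :func:`spdxfer.pipeline.epoch_window` relative to each cue.
    """
    from scipy.io import loadmat

    m = loadmat(path, squeeze_me=True, struct_as_record=False)
    if "cnt" not in m or "mrk" not in m or "nfo" not in m:
        raise ValueError("MAT file lacks the expected cnt/mrk/nfo variables")
    cnt = 0.1 * np.asarray(m["cnt"], dtype=float).T  # to microvolts, ch x t
    mrk, nfo = m["mrk"], m["nfo"]
    labels = np.asarray(mrk.y, dtype=float).ravel()
    return {
        "signal": cnt,
        "cue_positions": np.asarray(mrk.pos, dtype=int).ravel(),
        "cue_labels": labels,
        "fs": float(np.asarray(nfo.fs).ravel()[0]),
        "channels": [str(c) for c in np.asarray(nfo.clab).ravel()],
    }
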