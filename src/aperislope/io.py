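"""Packaged-epochs HDF5 container, TSV trial tables, and stat-table export.

Container layout: ``/data`` (trials x channels x samples, uV), ``/times``
(ms), ``/channels`` (labels), ``/trial_link`` (trial-table row index), and
an ``fs`` attribute.  Real epoched recordings (BDF/EDF/BrainVision) can be
loaded through mne when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import Epochs


def write_epochs_h5(path, epochs: Epochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", shuffle=True)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset(
            "channels",
            data=np.array(epochs.channel_labels, dtype=h5py.string_dtype()),
        )
        f.create_dataset("trial_link", data=np.asarray(epochs.trial_link))
        f.attrs["fs"] = epochs.fs


def read_epochs_h5(path) -> Epochs:
    with h5py.File(path, "r") as f:
        return Epochs(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            times=f["times"][()],
            channel_labels=[s.decode() if isinstance(s, bytes) else str(s)
                            for s in f["channels"][()]],
            trial_link=f["trial_link"][()],
        )


def write_trial_table(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=True, index_label="row")


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="row")


def write_stat_table(path, table: pd.DataFrame) -> None:
    path = Path(path)
    table.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    with open(path.with_suffix(".json"), "w") as f:
        json.dump(table.to_dict(orient="records"), f, indent=1, default=str)


def write_slope_series(path, slopes) -> None:
    """Slope tensors to HDF5: /slope, /intercept, /valid_mask (+ times, fs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("slope", data=slopes.slope, compression="gzip")
        f.create_dataset("intercept", data=slopes.intercept, compression="gzip")
        f.create_dataset("valid_mask", data=np.asarray(slopes.valid_mask))
        if slopes.times is not None:
            f.create_dataset("times", data=slopes.times)
        if slopes.trial_link is not None:
            f.create_dataset("trial_link", data=np.asarray(slopes.trial_link))
        if slopes.fs:
            f.attrs["fs"] = slopes.fs


def read_slope_series(path):
    from .slope import SlopeSeries

    with h5py.File(path, "r") as f:
        return SlopeSeries(
            slope=f["slope"][()],
            intercept=f["intercept"][()],
            valid_mask=f["valid_mask"][()].astype(bool),
            times=f["times"][()] if "times" in f else None,
            fs=float(f.attrs["fs"]) if "fs" in f.attrs else None,
            trial_link=f["trial_link"][()] if "trial_link" in f else None,
        )


def write_component_model(path, model) -> None:
    """ComponentModel to HDF5 plus a TSV of rotated loadings per variable."""
    path = Path(path)
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        f.create_dataset(
            "variables",
            data=np.array([str(v) for v in model.variables],
                          dtype=h5py.string_dtype()),
        )
        for name in (
            "mean", "covariance", "eigenvalues", "eigenvalues_corr",
            "loadings_unrotated", "loadings_rotated", "loadings_rotated_std",
            "rotation", "explained_variance", "explained_of_solution",
        ):
            f.create_dataset(name, data=getattr(model, name))
        f.create_dataset("retained", data=model.retained)
        f.attrs["n_cases"] = model.n_cases
        f.attrs["n_ekc"] = model.n_ekc
        if model.names:
            f.create_dataset(
                "names", data=np.array(model.names, dtype=h5py.string_dtype())
            )
    cols = {"variable": [str(v) for v in model.variables]}
    k = model.loadings_rotated.shape[1]
    names = model.names or [f"comp{j + 1}" for j in range(k)]
    for j in range(k):
        cols[f"{names[j]}_loading"] = model.loadings_rotated[:, j]
        cols[f"{names[j]}_loading_std"] = model.loadings_rotated_std[:, j]
    pd.DataFrame(cols).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


def read_raw_epochs(path, tmin_s: float = -0.5, tmax_s: float = 1.5,
                    event_id=None) -> Epochs:
    """Load real epoched EEG from BDF/EDF/BrainVision via mne (optional).

    Stimulus events are taken from the recording's annotations; the caller
    is responsible for aligning the resulting ``trial_link`` with a trial
    table.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "reading raw EEG requires the optional 'mne' dependency"
        ) from exc
    path = Path(path)
    readers = {
        ".bdf": mne.io.read_raw_bdf,
        ".edf": mne.io.read_raw_edf,
        ".vhdr": mne.io.read_raw_brainvision,
    }
    reader = readers.get(path.suffix.lower())
    if reader is None:
        raise ValueError(f"unsupported raw EEG format: {path.suffix}")
    raw = reader(path, preload=True, verbose="error")
    events, _ = mne.events_from_annotations(raw, event_id=event_id, verbose="error")
    ep = mne.Epochs(
        raw, events, tmin=tmin_s, tmax=tmax_s - 1.0 / raw.info["sfreq"],
        baseline=None, preload=True, verbose="error",
    )
    data = ep.get_data(copy=True) * 1e6  # volts -> microvolts
    return Epochs(
        data=data,
        fs=float(ep.info["sfreq"]),
        times=ep.times * 1000.0,
        channel_labels=list(ep.ch_names),
        trial_link=np.arange(data.shape[0]),
    )
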