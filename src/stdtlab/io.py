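"""File interfaces: TSV tables, HDF5 epoch/volume containers, YAML configs.

Epoched data and scalp volumes are stored as HDF5 datasets with a JSON
sidecar carrying the channel names, sampling rate, window and any ground
truth parameters; behavioral tables are plain TSV. Continuous real-data
recordings are read from EDF through :func:`read_raw_edf`.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .calibration import ISIDesign, PsychometricFit
from .eegsim import EpochSet
from .layout import ChannelLayout, biosemi64_layout

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_volumes",
    "load_volumes",
    "fits_to_tsv",
    "design_to_tsv",
    "load_config",
    "read_raw_edf",
]


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an epoch container (HDF5) plus a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["tmin"] = epochs.tmin
        f.attrs["tmax"] = epochs.tmax
        f.create_dataset(
            "meta_json", data=np.bytes_(epochs.meta.to_json(orient="table"))
        )
    sidecar = {
        "channel_names": list(epochs.layout.names),
        "sfreq": epochs.sfreq,
        "window_s": [epochs.tmin, epochs.tmax],
        "n_trials": epochs.n_trials,
        "ground_truth": {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in epochs.ground_truth.items()
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path: str | Path, layout: ChannelLayout | None = None) -> EpochSet:
    path = Path(path)
    if layout is None:
        layout = biosemi64_layout()
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        meta = pd.read_json(f["meta_json"][()].decode(), orient="table")
        return EpochSet(
            data=data,
            sfreq=float(f.attrs["sfreq"]),
            tmin=float(f.attrs["tmin"]),
            tmax=float(f.attrs["tmax"]),
            layout=layout,
            meta=meta,
        )


def save_volumes(volumes: np.ndarray, mask: np.ndarray, times_ms: np.ndarray, path: str | Path) -> None:
    """Store contrast/trial volumes (any leading shape x n x n x samples)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("volumes", data=volumes, compression="gzip")
        f.create_dataset("mask", data=mask)
        f.create_dataset("times_ms", data=times_ms)


def load_volumes(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["volumes"][()], f["mask"][()].astype(bool), f["times_ms"][()]


def fits_to_tsv(fits: dict[str, PsychometricFit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "observer_id": oid,
                "t50": fit.t50,
                "scale": fit.scale,
                "t01": fit.t01,
                "t99": fit.t99,
                "mse": fit.mse,
            }
            for oid, fit in fits.items()
        ]
    ).to_csv(path, sep="\t", index=False)


def design_to_tsv(design: ISIDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "level": np.arange(1, 11),
            "isi_ms": design.levels,
            "trials_per_run": design.counts_per_run,
        }
    ).to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Read a YAML pipeline/config file into a plain dict."""
    with open(path) as f:
        return yaml.safe_load(f) or {}


def read_raw_edf(path: str | Path, events_tsv: str | Path | None = None):
    """Real-data entry point: continuous EDF plus an optional events TSV.

    Returns ``(data_uV, sfreq, ch_names, events_df)``; data are scaled to uV.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6
    events = pd.read_csv(events_tsv, sep="\t") if events_tsv is not None else None
    return data, float(raw.info["sfreq"]), list(raw.ch_names), events
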