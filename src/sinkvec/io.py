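"""Reading and writing the pipeline's on-disk formats.

Snapshots come in as EDF (via mne, optional dependency), as an HDF5
container (dataset ``samples`` channels x time, attrs ``fs`` and
``labels``), or as a CSV array with a JSON sidecar ``{"fs": ..,
"labels": [..]}``. Annotations are CSV or JSON with columns/keys
``label``, ``is_ez``, ``excluded``. Windowed data and fitted model
sequences are stored in HDF5; feature tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dnm import DNMSequence, StateTransition
from .preprocess import ChannelAnnotation, Snapshot, WindowedData

__all__ = [
    "read_snapshot",
    "write_snapshot_h5",
    "read_annotations",
    "write_windows_h5",
    "read_windows_h5",
    "write_dnm_h5",
    "read_dnm_h5",
]


def read_snapshot(path: str | Path) -> Snapshot:
    """Load a snapshot from .edf, .h5/.hdf5, or .csv (+ .json sidecar)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return _read_edf(path)
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            samples = f["samples"][()]
            fs = float(f["samples"].attrs["fs"])
            labels = tuple(
                lab.decode() if isinstance(lab, bytes) else str(lab)
                for lab in f["samples"].attrs["labels"]
            )
        return Snapshot(samples=samples, fs=fs, channel_labels=labels)
    if suffix == ".csv":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"CSV snapshot needs a JSON sidecar with fs and labels: {sidecar}"
            )
        meta = json.loads(sidecar.read_text())
        samples = np.loadtxt(path, delimiter=",", ndmin=2)
        return Snapshot(
            samples=samples, fs=float(meta["fs"]), channel_labels=tuple(meta["labels"])
        )
    raise ValueError(f"unsupported snapshot format: {path.name}")


def _read_edf(path: Path) -> Snapshot:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne; install the 'edf' extra"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Snapshot(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def write_snapshot_h5(snapshot: Snapshot, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=snapshot.samples)
        ds.attrs["fs"] = snapshot.fs
        ds.attrs["labels"] = list(snapshot.channel_labels)


def read_annotations(path: str | Path) -> list[ChannelAnnotation]:
    """Load channel annotations from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [
        ChannelAnnotation(
            label=str(r["label"]),
            is_ez=bool(r.get("is_ez", False)),
            excluded=bool(r.get("excluded", False)),
            notes=str(r.get("notes", "")),
        )
        for r in rows
    ]


def write_windows_h5(windowed: WindowedData, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("windows", data=np.stack(windowed.windows))
        ds.attrs["fs"] = windowed.fs
        ds.attrs["window_ms"] = windowed.window_ms
        ds.attrs["labels"] = list(windowed.channel_labels)


def read_windows_h5(path: str | Path) -> WindowedData:
    with h5py.File(path, "r") as f:
        ds = f["windows"]
        stack = ds[()]
        return WindowedData(
            windows=tuple(stack),
            fs=float(ds.attrs["fs"]),
            window_ms=int(ds.attrs["window_ms"]),
            channel_labels=tuple(
                lab.decode() if isinstance(lab, bytes) else str(lab)
                for lab in ds.attrs["labels"]
            ),
        )


def write_dnm_h5(seq: DNMSequence, path: str | Path) -> None:
    """Serialize a model sequence: dataset "A" (windows x N x N) + labels."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("A", data=seq.stack())
        ds.attrs["labels"] = list(seq.channel_labels)
        ds.attrs["n_samples_fit"] = [t.n_samples_fit for t in seq.transitions]


def read_dnm_h5(path: str | Path) -> DNMSequence:
    with h5py.File(path, "r") as f:
        ds = f["A"]
        stack = ds[()]
        labels = tuple(
            lab.decode() if isinstance(lab, bytes) else str(lab)
            for lab in ds.attrs["labels"]
        )
        n_fit = list(ds.attrs.get("n_samples_fit", [0] * len(stack)))
    transitions = tuple(
        StateTransition(A=a, window_index=i, n_samples_fit=int(n))
        for i, (a, n) in enumerate(zip(stack, n_fit))
    )
    return DNMSequence(transitions=transitions, channel_labels=labels)
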