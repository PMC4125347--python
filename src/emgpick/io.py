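"""Recording and configuration I/O.

Three containers are supported, dispatched on file extension:

``.h5`` / ``.hdf5``
    Datasets ``signal`` (samples x channels), ``labels``, ``trial_ids``
    and a root attribute ``fs``.
``.npz``
    NumPy archive with arrays ``signal``, ``labels``, ``trial_ids`` and
    scalar ``fs``.
``.csv``
    A leading metadata line ``# fs=<Hz>``, then a header of channel
    names plus ``label`` and ``trial`` columns, one sample per row.

Round-tripping any recording through any container reproduces signal
(to float64 precision), sampling rate and annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .recording import EmgRecording


class FormatError(ValueError):
    """A container is missing a required field or is malformed."""


def write_recording(recording: EmgRecording, path: str | Path) -> None:
    """Write a recording to ``path``; format chosen by extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=recording.signal)
            f.create_dataset("labels", data=recording.labels)
            f.create_dataset("trial_ids", data=recording.trial_ids)
            f.attrs["fs"] = float(recording.fs)
    elif ext == ".npz":
        np.savez(
            path,
            signal=recording.signal,
            labels=recording.labels,
            trial_ids=recording.trial_ids,
            fs=np.float64(recording.fs),
        )
    elif ext == ".csv":
        df = pd.DataFrame(
            recording.signal,
            columns=[f"ch{j}" for j in range(recording.n_channels)],
        )
        df["label"] = recording.labels
        df["trial"] = recording.trial_ids
        with open(path, "w") as fh:
            fh.write(f"# fs={recording.fs}\n")
            df.to_csv(fh, index=False)
    else:
        raise FormatError(f"unsupported recording container: {ext or path.name}")


def read_recording(path: str | Path) -> EmgRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for name in ("signal", "labels", "trial_ids"):
                if name not in f:
                    raise FormatError(f"HDF5 container missing dataset '{name}'")
            if "fs" not in f.attrs:
                raise FormatError("HDF5 container missing attribute 'fs'")
            return EmgRecording(
                signal=f["signal"][()],
                fs=float(f.attrs["fs"]),
                labels=f["labels"][()],
                trial_ids=f["trial_ids"][()],
            )
    if ext == ".npz":
        with np.load(path) as z:
            for name in ("signal", "labels", "trial_ids", "fs"):
                if name not in z:
                    raise FormatError(f"npz container missing array '{name}'")
            return EmgRecording(
                signal=z["signal"],
                fs=float(z["fs"]),
                labels=z["labels"],
                trial_ids=z["trial_ids"],
            )
    if ext == ".csv":
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("# fs="):
                raise FormatError("CSV container missing '# fs=' metadata line")
            try:
                fs = float(first.split("=", 1)[1])
            except ValueError as exc:
                raise FormatError(f"unparseable fs metadata: {first!r}") from exc
            df = pd.read_csv(fh)
        for col in ("label", "trial"):
            if col not in df.columns:
                raise FormatError(f"CSV container missing column '{col}'")
        chan_cols = [c for c in df.columns if c not in ("label", "trial")]
        if not chan_cols:
            raise FormatError("CSV container has no channel columns")
        return EmgRecording(
            signal=df[chan_cols].to_numpy(dtype=np.float64),
            fs=fs,
            labels=df["label"].to_numpy(),
            trial_ids=df["trial"].to_numpy(),
        )
    raise FormatError(f"unsupported recording container: {ext or path.name}")


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must contain a mapping")
    return cfg
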