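"""File formats: HDF5 recordings and banks, CSV spike trains, YAML configs."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import EmgRecording, GridGeometry, MuapTemplate, SpikeTrain
from .offline import SeparationBank, SeparationVector
from .preprocess import WhiteningModel


def write_recording(path: str | Path, recording: EmgRecording) -> None:
    """Datasets /emg (n x ch, float32 µV) and /force; attrs fs, grid shape."""
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=recording.samples.astype(np.float32))
        if recording.force is not None:
            f.create_dataset("force", data=recording.force.astype(np.float32))
        f.attrs["fs"] = recording.fs
        f.attrs["grid_rows"] = recording.grid.rows
        f.attrs["grid_cols"] = recording.grid.cols


def read_recording(path: str | Path) -> EmgRecording:
    with h5py.File(path, "r") as f:
        grid = GridGeometry(rows=int(f.attrs["grid_rows"]),
                            cols=int(f.attrs["grid_cols"]))
        force = f["force"][:].astype(np.float64) if "force" in f else None
        return EmgRecording(samples=f["emg"][:].astype(np.float64),
                            fs=float(f.attrs["fs"]), grid=grid, force=force)


def write_spike_trains(path: str | Path, trains: list[SpikeTrain]) -> None:
    """CSV with columns (mu_id, sample_index), 0-based."""
    rows = [(t.mu_id, int(s)) for t in trains for s in t.spikes]
    pd.DataFrame(rows, columns=["mu_id", "sample_index"]).to_csv(path,
                                                                 index=False)


def read_spike_trains(path: str | Path, fs: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(mu_id=int(mu), spikes=np.sort(g["sample_index"].to_numpy()),
                   fs=fs)
        for mu, g in df.groupby("mu_id")
    ]


def write_bank(path: str | Path, bank: SeparationBank) -> None:
    with h5py.File(path, "w") as f:
        w = f.create_group("whitening")
        w.create_dataset("channel_means", data=bank.whitening.channel_means)
        w.create_dataset("matrix", data=bank.whitening.matrix)
        w.create_dataset("eigenvalues", data=bank.whitening.eigenvalues)
        w.attrs["eig_floor"] = bank.whitening.eig_floor
        f.create_dataset("vectors",
                         data=np.stack([v.weights for v in bank.vectors]))
        f.create_dataset("qualities",
                         data=np.array([v.quality for v in bank.vectors]))
        f.create_dataset("templates",
                         data=np.stack([t.waveforms for t in bank.templates]))
        f.create_dataset("mu_ids", data=np.array(bank.mu_ids))
        f.attrs["version"] = bank.version
        f.attrs["R"] = bank.whitening.extension_factor
        f.attrs["fs"] = bank.fs
        f.attrs["created_at"] = bank.created_at


def read_bank(path: str | Path) -> SeparationBank:
    with h5py.File(path, "r") as f:
        whitening = WhiteningModel(
            extension_factor=int(f.attrs["R"]),
            channel_means=f["whitening/channel_means"][:],
            matrix=f["whitening/matrix"][:],
            eigenvalues=f["whitening/eigenvalues"][:],
            eig_floor=float(f["whitening"].attrs["eig_floor"]),
        )
        mu_ids = f["mu_ids"][:]
        vectors = [SeparationVector(weights=wv, mu_id=int(mu), quality=float(q))
                   for wv, mu, q in zip(f["vectors"][:], mu_ids,
                                        f["qualities"][:])]
        templates = [MuapTemplate(mu_id=int(mu), waveforms=wf)
                     for mu, wf in zip(mu_ids, f["templates"][:])]
        return SeparationBank(whitening=whitening, vectors=vectors,
                              templates=templates, fs=float(f.attrs["fs"]),
                              created_at=int(f.attrs["created_at"]),
                              version=int(f.attrs["version"]))


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}
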