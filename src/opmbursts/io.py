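"""On-disk layout for synthetic datasets and derivatives.

A dataset directory holds ``data.h5`` (/data channels x samples in tesla,
/truth/sources, /truth/bursts/<region>), ``channels.tsv`` (name, position,
axis) and ``events.tsv`` (BIDS events dialect).  Derivatives (virtual
electrodes, HMM outputs, burst events) append to ``derivatives.h5`` and TSV
side-cars in the same directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .beamformer import VirtualElectrodeSet
from .containers import RawRecording
from .paradigm import events_from_tsv, events_to_tsv
from .synth import SyntheticDataset


def save_dataset(out_dir: str | Path, dataset: SyntheticDataset) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = dataset.recording
    with h5py.File(out / "data.h5", "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["fs"] = rec.fs
        d.attrs["units"] = "T"
        f.create_dataset("truth/sources", data=dataset.truth_sources)
        f.create_dataset("truth/orientations", data=dataset.truth_orientations)
        for label, iv in dataset.truth_bursts.items():
            f.create_dataset(f"truth/bursts/{label}", data=iv)
        f.create_dataset("source_model/centroids", data=dataset.source_model.centroids)
        f["source_model"].attrs["labels"] = list(dataset.source_model.labels)
        f["source_model"].attrs["conductor_radius"] = dataset.source_model.conductor_radius

    chans = pd.DataFrame(dict(
        name=rec.channel_names,
        x=rec.positions[:, 0], y=rec.positions[:, 1], z=rec.positions[:, 2],
        ax=rec.axes[:, 0], ay=rec.axes[:, 1], az=rec.axes[:, 2],
        bad=rec.bad,
    ))
    chans.to_csv(out / "channels.tsv", sep="\t", index=False)
    events_to_tsv(rec.events, out / "events.tsv")
    return out


def load_recording(in_dir: str | Path, name: str = "data.h5") -> RawRecording:
    in_dir = Path(in_dir)
    with h5py.File(in_dir / name, "r") as f:
        data = f["data"][()]
        fs = float(f["data"].attrs["fs"])
    chans = pd.read_csv(in_dir / "channels.tsv", sep="\t")
    events_path = in_dir / "events.tsv"
    events = events_from_tsv(events_path) if events_path.exists() else None
    return RawRecording(
        data=data, fs=fs, channel_names=list(chans.name),
        positions=chans[["x", "y", "z"]].to_numpy(),
        axes=chans[["ax", "ay", "az"]].to_numpy(),
        bad=chans.bad.to_numpy(dtype=bool), events=events,
    )


def save_preprocessed(out_dir: str | Path, recording: RawRecording,
                      qc: dict) -> None:
    out = Path(out_dir)
    with h5py.File(out / "preproc.h5", "w") as f:
        d = f.create_dataset("data", data=recording.data)
        d.attrs["fs"] = recording.fs
        f.create_dataset("bad", data=recording.bad)
    with open(out / "preproc_log.jsonl", "a") as fh:
        fh.write(json.dumps(qc) + "\n")


def save_virtual_electrodes(out_dir: str | Path, ve: VirtualElectrodeSet) -> None:
    out = Path(out_dir)
    key = f"ve/{ve.band[0]:g}-{ve.band[1]:g}"
    with h5py.File(out / "derivatives.h5", "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("data", data=ve.data)
        g.create_dataset("orientations", data=ve.orientations)
        g.create_dataset("weights", data=ve.weights)
        g.attrs["labels"] = list(ve.labels)
        g.attrs["fs"] = ve.fs


def save_burst_events(out_dir: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=["region", "onset", "offset", "duration",
                                "peak_amplitude"]).to_csv(
        Path(out_dir) / "burst_events.tsv", sep="\t", index=False)
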