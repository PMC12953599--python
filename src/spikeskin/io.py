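"""Dataset, spike-event and result serialization (text-first formats).

Records go to one delimited table per trial plus a JSON sidecar with the
ground truth; spike events to two-column CSV or an HDF5 container for
large runs; network specs to JSON; decode results to delimited tables.
Every artifact can embed the config hash and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .neurons import SpikeEvents
from .skin import Contact, IndentationRecord

__all__ = [
    "save_record",
    "load_record",
    "save_manifest",
    "load_manifest",
    "save_spikes_csv",
    "load_spikes_csv",
    "save_spikes_h5",
    "load_spikes_h5",
    "save_decode_result",
]


def save_record(record: IndentationRecord, directory, metadata: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"trial_{record.trial_id:05d}"
    cols = {"t_ms": record.t_ms}
    for i in range(record.n_channels):
        cols[f"ch{i + 1:02d}"] = record.delta_lambda[:, i]
    pd.DataFrame(cols).to_csv(directory / f"{stem}.csv", index=False)
    side = {
        "trial_id": record.trial_id,
        "seed": record.seed,
        "contacts": [
            {"theta": c.theta, "z": c.z, "force": np.asarray(c.force).tolist()}
            for c in record.contacts
        ],
        **(metadata or {}),
    }
    (directory / f"{stem}.json").write_text(json.dumps(side))
    return directory / f"{stem}.csv"


def load_record(csv_path) -> IndentationRecord:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    chans = [c for c in frame.columns if c.startswith("ch")]
    contacts = [
        Contact(c["theta"], c["z"], np.asarray(c["force"], dtype=float))
        for c in side["contacts"]
    ]
    return IndentationRecord(
        frame["t_ms"].to_numpy(dtype=float),
        frame[chans].to_numpy(dtype=float),
        contacts,
        trial_id=side["trial_id"],
        seed=side.get("seed", 0),
    )


def save_manifest(directory, records: list[IndentationRecord], metadata: dict | None = None) -> Path:
    directory = Path(directory)
    manifest = {
        "trials": [f"trial_{r.trial_id:05d}.csv" for r in records],
        **(metadata or {}),
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest))
    return path


def load_manifest(directory) -> list[IndentationRecord]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [load_record(directory / t) for t in manifest["trials"]]


def save_spikes_csv(spikes: SpikeEvents, path) -> None:
    pd.DataFrame({"time_ms": spikes.times, "neuron_id": spikes.ids}).to_csv(path, index=False)


def load_spikes_csv(path, n_neurons: int, duration: float) -> SpikeEvents:
    frame = pd.read_csv(path)
    return SpikeEvents(
        frame["time_ms"].to_numpy(dtype=float),
        frame["neuron_id"].to_numpy(dtype=np.int64),
        n_neurons,
        duration,
    )


def save_spikes_h5(spikes: SpikeEvents, path, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=spikes.times)
        f.create_dataset("neuron_id", data=spikes.ids)
        f.attrs["n_neurons"] = spikes.n_neurons
        f.attrs["duration"] = spikes.duration
        for k, v in (metadata or {}).items():
            f.attrs[k] = v


def load_spikes_h5(path) -> SpikeEvents:
    with h5py.File(path, "r") as f:
        return SpikeEvents(
            f["time_ms"][:], f["neuron_id"][:],
            int(f.attrs["n_neurons"]), float(f.attrs["duration"]),
        )


def save_decode_result(result, path, metadata: dict | None = None) -> None:
    """Decoded trajectory as (t_ms, theta, z, detected) with a JSON header."""
    header = json.dumps(metadata or {})
    frame = pd.DataFrame(
        {"t_ms": result.t_ms, "theta": result.theta, "z": result.z,
         "detected": result.detected.astype(int)}
    )
    with open(path, "w") as f:
        f.write(f"# {header}\n")
        frame.to_csv(f, index=False)
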