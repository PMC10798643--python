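"""Readers and writers: HDF5 epoch containers, CSV/TSV results, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochedDataset, TripletSet


def save_epochs(dataset: EpochedDataset, path) -> None:
    """Persist an EpochedDataset to an HDF5 container.

    Layout: /data (events x channels x times), /times, /channels/positions
    and one integer dataset per event-metadata column under /events.
    Written with fixed-order metadata and no timestamps, so identical
    datasets produce byte-identical files.
    """
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["subject_id"] = dataset.subject_id
        f.create_dataset("data", data=dataset.data)
        f.create_dataset("times", data=dataset.times)
        f.create_dataset("channels/positions", data=dataset.channel_positions)
        grp = f.create_group("events")
        grp.attrs["columns"] = json.dumps(list(dataset.events.columns))
        for col in dataset.events.columns:
            grp.create_dataset(col, data=dataset.events[col].to_numpy())


def load_epochs(path) -> EpochedDataset:
    with h5py.File(path, "r") as f:
        cols = json.loads(f["events"].attrs["columns"])
        events = pd.DataFrame({c: f["events"][c][()] for c in cols})
        return EpochedDataset(
            subject_id=str(f.attrs["subject_id"]),
            data=f["data"][()],
            times=f["times"][()],
            events=events,
            channel_positions=f["channels/positions"][()],
        )


def load_triplets(path) -> TripletSet:
    return TripletSet(trials=pd.read_csv(path))


def timecourse_frame(timecourses, analysis: str) -> pd.DataFrame:
    """Tidy long-format table: subject, analysis, label, time_ms, accuracy."""
    rows = []
    for tc in timecourses:
        rows.append(
            pd.DataFrame(
                {
                    "subject": tc.subject_id,
                    "analysis": analysis,
                    "label": tc.label,
                    "time_ms": tc.times,
                    "accuracy": tc.accuracy,
                    "chance": tc.chance,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_rdm_stack(path, rdms: np.ndarray, stimulus_ids, times, subject_id: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = subject_id
        f.create_dataset("rdms", data=rdms)
        f.create_dataset("stimulus_ids", data=np.asarray(stimulus_ids))
        f.create_dataset("times", data=np.asarray(times))


def load_rdm_stack(path):
    with h5py.File(path, "r") as f:
        return (
            f["rdms"][()],
            f["stimulus_ids"][()],
            f["times"][()],
            str(f.attrs["subject_id"]),
        )


def write_manifest(out_dir, stage: str, seed: int, config: dict) -> Path:
    """JSON run manifest: stage, seed, config and a config hash."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
    }
    path = out_dir / f"manifest-{stage}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
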