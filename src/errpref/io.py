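"""Readers/writers for the pipeline's on-disk interchange formats.

Trial metadata travels as TSV, subject profiles as JSON, epochs and
trajectory state dumps as HDF5.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocessing import EpochSet
from .synthetic import SubjectProfile
from .trajectory import Trajectory

__all__ = [
    "save_trials_tsv",
    "load_trials_tsv",
    "save_profile_json",
    "load_profile_json",
    "save_epochs_h5",
    "load_epochs_h5",
    "save_trajectory_h5",
    "load_trajectory_h5",
]


def save_trials_tsv(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False)


def load_trials_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_profile_json(path, profile: SubjectProfile) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(profile), indent=2))


def load_profile_json(path) -> SubjectProfile:
    return SubjectProfile(**json.loads(Path(path).read_text()))


def save_epochs_h5(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=epochs.labels.astype(bool))
        f.create_dataset("rejected", data=epochs.rejected.astype(bool))
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["ch_names"] = list(epochs.ch_names)


def load_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            labels=f["labels"][()].astype(bool),
            rejected=f["rejected"][()].astype(bool),
            sfreq=float(f.attrs["sfreq"]),
            ch_names=[str(c) for c in f.attrs["ch_names"]],
        )


def save_trajectory_h5(path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("states", data=traj.states)
        f.create_dataset("times", data=traj.times)
        f.attrs["completed"] = bool(traj.completed)


def load_trajectory_h5(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(states=f["states"][()], times=f["times"][()],
                          completed=bool(f.attrs["completed"]))
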