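"""Readers/writers for DEAP-style containers and rating -> label rules.

Supported on-disk formats:

* ``deap-mat`` — per-subject MATLAB container with ``data``
  (trials x 40 x samples; EEG on channels 0-31, peripheral channels
  dropped) and ``labels`` (trials x 4: valence, arousal, dominance,
  liking).
* ``hdf5`` — datasets ``/data`` (trials x 32 x samples), ``/labels``
  (trials x 2), ``/channel_names``; attrs ``fs``, ``baseline_sec``,
  ``subject_id``.
* ``npz`` — the same arrays as NumPy archives.

Ratings on the 1-9 self-assessment scale binarise at 5 (``>= 5`` is high,
``< 5`` is low), and the two binarisations combine into the four
valence-arousal quadrants HVHA/HVLA/LVHA/LVLA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.io import loadmat, savemat

from .layout import DEAP_CHANNELS
from .recording import EEGRecording

__all__ = [
    "LabelSpec", "QUADRANT_ORDER", "FormatError", "binarize_label",
    "quadrant_label", "labels_for_task", "read_recording", "write_recording",
]

#: Class-id order used for quadrant classification.
QUADRANT_ORDER: tuple[str, ...] = ("HVHA", "HVLA", "LVHA", "LVLA")

N_EEG_CHANNELS = 32
DEAP_MAT_CHANNELS = 40  # 32 EEG + 8 peripheral


class FormatError(ValueError):
    """A container does not match its declared format."""


@dataclass(frozen=True)
class LabelSpec:
    """Which rating dimension to classify and where to cut it."""

    dimension: str = "quadrant"  # valence | arousal | quadrant
    threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.dimension not in ("valence", "arousal", "quadrant"):
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if not (1.0 < self.threshold < 9.0):
            raise ValueError("threshold must lie strictly inside (1, 9)")


def binarize_label(rating: float, threshold: float = 5.0) -> str:
    """``high`` iff ``rating >= threshold`` (DEAP convention), else ``low``."""
    if not (1.0 <= rating <= 9.0):
        raise ValueError(f"rating {rating} outside [1, 9]")
    return "high" if rating >= threshold else "low"


def quadrant_label(valence: float, arousal: float,
                   threshold: float = 5.0) -> str:
    """Combine the two binarisations into HVHA/HVLA/LVHA/LVLA."""
    v = "H" if binarize_label(valence, threshold) == "high" else "L"
    a = "H" if binarize_label(arousal, threshold) == "high" else "L"
    return f"{v}V{a}A"


def labels_for_task(ratings, task: str = "quadrant",
                    threshold: float = 5.0) -> np.ndarray:
    """Integer class ids per trial for a classification task.

    Binary tasks use 0 = low, 1 = high; the quadrant task indexes into
    :data:`QUADRANT_ORDER`.
    """
    ratings = np.asarray(ratings, dtype=float)
    if task == "valence":
        return np.array([0 if binarize_label(v, threshold) == "low" else 1
                         for v in ratings[:, 0]])
    if task == "arousal":
        return np.array([0 if binarize_label(a, threshold) == "low" else 1
                         for a in ratings[:, 1]])
    if task == "quadrant":
        return np.array([
            QUADRANT_ORDER.index(quadrant_label(v, a, threshold))
            for v, a in ratings
        ])
    raise ValueError(f"unknown task {task!r}")


def _normalize_channel_order(data, names):
    """Reorder channels to the canonical DEAP order if needed."""
    names = tuple(str(n) for n in names)
    if names == DEAP_CHANNELS:
        return data, DEAP_CHANNELS
    if sorted(names) != sorted(DEAP_CHANNELS):
        raise FormatError(
            "channel names do not form the 32-electrode DEAP set"
        )
    order = [names.index(ch) for ch in DEAP_CHANNELS]
    return data[:, order, :], DEAP_CHANNELS


def read_recording(path, format: str, fs: float = 128.0,
                   baseline_sec: float = 3.0) -> EEGRecording:
    """Load one subject's trials from ``path`` in the declared ``format``."""
    path = Path(path)
    if format == "deap-mat":
        return _read_deap_mat(path, fs, baseline_sec)
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "npz":
        return _read_npz(path)
    raise ValueError(f"unknown format {format!r}")


def _read_deap_mat(path, fs, baseline_sec) -> EEGRecording:
    mat = loadmat(path)
    if "data" not in mat:
        raise FormatError(f"{path}: no 'data' variable")
    data = np.asarray(mat["data"], dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: 'data' must be trials x channels x samples")
    if data.shape[1] == DEAP_MAT_CHANNELS:
        data = data[:, :N_EEG_CHANNELS, :]  # drop peripheral channels
    elif data.shape[1] != N_EEG_CHANNELS:
        raise FormatError(
            f"{path}: {data.shape[1]} channels; expected "
            f"{DEAP_MAT_CHANNELS} (DEAP) or {N_EEG_CHANNELS} (EEG only)"
        )
    if "labels" not in mat:
        raise FormatError(f"{path}: no 'labels' variable (ratings missing)")
    labels = np.asarray(mat["labels"], dtype=float)
    if labels.shape[0] != data.shape[0] or labels.shape[1] < 2:
        raise FormatError(f"{path}: labels shape {labels.shape} unusable")
    return EEGRecording(subject_id=path.stem, data=data, fs=fs,
                        ratings=labels[:, :2], channel_names=DEAP_CHANNELS,
                        baseline_sec=baseline_sec)


def _read_hdf5(path) -> EEGRecording:
    with h5py.File(path, "r") as fh:
        for key in ("data", "labels", "channel_names"):
            if key not in fh:
                raise FormatError(f"{path}: missing dataset /{key}")
        data = fh["data"][()]
        labels = fh["labels"][()]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in fh["channel_names"][()]]
        fs = float(fh.attrs.get("fs", 128.0))
        baseline_sec = float(fh.attrs.get("baseline_sec", 3.0))
        subject_id = str(fh.attrs.get("subject_id", path.stem))
    if data.shape[1] != len(names):
        raise FormatError(f"{path}: channel count/name mismatch")
    if data.shape[1] != N_EEG_CHANNELS:
        raise FormatError(
            f"{path}: {data.shape[1]} channels; expected {N_EEG_CHANNELS}"
        )
    data, names = _normalize_channel_order(data, names)
    return EEGRecording(subject_id=subject_id, data=data, fs=fs,
                        ratings=labels, channel_names=names,
                        baseline_sec=baseline_sec)


def _read_npz(path) -> EEGRecording:
    with np.load(path, allow_pickle=False) as npz:
        for key in ("data", "labels", "channel_names"):
            if key not in npz:
                raise FormatError(f"{path}: missing array '{key}'")
        data = npz["data"]
        labels = npz["labels"]
        names = [str(n) for n in npz["channel_names"]]
        fs = float(npz["fs"]) if "fs" in npz else 128.0
        baseline_sec = (float(npz["baseline_sec"])
                        if "baseline_sec" in npz else 3.0)
    if data.shape[1] != N_EEG_CHANNELS:
        raise FormatError(
            f"{path}: {data.shape[1]} channels; expected {N_EEG_CHANNELS}"
        )
    data, names = _normalize_channel_order(data, names)
    return EEGRecording(subject_id=path.stem, data=data, fs=fs,
                        ratings=labels, channel_names=names,
                        baseline_sec=baseline_sec)


def write_recording(recording: EEGRecording, path, format: str) -> None:
    """Persist a recording as ``hdf5``, ``npz`` or ``deap-mat``."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=recording.data)
            fh.create_dataset("labels", data=recording.ratings)
            fh.create_dataset(
                "channel_names",
                data=np.array([n.encode() for n in recording.channel_names]))
            fh.attrs["fs"] = recording.fs
            fh.attrs["baseline_sec"] = recording.baseline_sec
            fh.attrs["subject_id"] = recording.subject_id
    elif format == "npz":
        np.savez(
            path, data=recording.data, labels=recording.ratings,
            channel_names=np.array(recording.channel_names),
            fs=recording.fs, baseline_sec=recording.baseline_sec)
    elif format == "deap-mat":
        # DEAP container layout: pad ratings to the 4 rating dimensions and
        # append 8 zero peripheral channels.
        n_trials, _, n_samples = recording.data.shape
        data40 = np.zeros((n_trials, DEAP_MAT_CHANNELS, n_samples))
        data40[:, :N_EEG_CHANNELS, :] = recording.data
        labels4 = np.zeros((n_trials, 4))
        labels4[:, :2] = recording.ratings
        savemat(path, {"data": data40, "labels": labels4})
    else:
        raise ValueError(f"unknown format {format!r}")
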