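"""From per-slice feature matrices to fused band-space tensors and sequences.

Per 0.5 s slice, each band's 32 channel features are scattered onto the 8x9
electrode grid (unoccupied cells are exact zeros), the four band grids are
stacked, and the DE and band-power stacks are concatenated DE-first along
the leading axis into an 8 x 8 x 9 fused tensor.  Eight consecutive fused
tensors (a 4 s window) form one model input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .features import featurize_recording
from .io import labels_for_task
from .layout import ElectrodeLayout, default_layout

__all__ = [
    "SequenceSample", "SEQUENCE_LEN", "map_to_grid", "grid_to_vector",
    "stack_bands", "fuse", "split_fused", "build_sequences",
    "recording_to_sequences",
]

SEQUENCE_LEN = 8  # 8 x 0.5 s slices = one 4 s window


@dataclass
class SequenceSample:
    """One model input: 8 consecutive fused tensors plus its label."""

    tensors: np.ndarray  # (8, 8, 8, 9) time step x channel x row x col
    label: int
    subject_id: str = ""
    trial_index: int = 0
    start_slice: int = 0


def map_to_grid(vector, layout: ElectrodeLayout | None = None) -> np.ndarray:
    """Scatter 32 channel values onto the spatial grid; rest stays zero."""
    layout = layout or default_layout()
    vector = np.asarray(vector, dtype=float)
    if vector.shape[-1] != layout.n_channels:
        raise ValueError(
            f"vector has {vector.shape[-1]} entries; layout expects "
            f"{layout.n_channels}"
        )
    rows, cols = layout.rows_cols(layout.channel_order)
    grid = np.zeros(vector.shape[:-1] + (layout.grid_rows, layout.grid_cols))
    grid[..., rows, cols] = vector
    return grid


def grid_to_vector(grid, layout: ElectrodeLayout | None = None) -> np.ndarray:
    """Read the occupied cells back out in canonical channel order."""
    layout = layout or default_layout()
    grid = np.asarray(grid, dtype=float)
    rows, cols = layout.rows_cols(layout.channel_order)
    return grid[..., rows, cols]


def stack_bands(grids) -> np.ndarray:
    """Stack the four band grids (theta, alpha, beta, gamma) along axis 0."""
    grids = [np.asarray(g, dtype=float) for g in grids]
    if len(grids) != 4:
        raise ValueError(f"expected 4 band grids, got {len(grids)}")
    return np.stack(grids, axis=0)


def fuse(t_de, t_psd) -> np.ndarray:
    """Concatenate the DE and PSD band stacks DE-first along the channel axis."""
    t_de = np.asarray(t_de, dtype=float)
    t_psd = np.asarray(t_psd, dtype=float)
    if t_de.shape != t_psd.shape:
        raise ValueError(f"shape mismatch {t_de.shape} vs {t_psd.shape}")
    return np.concatenate([t_de, t_psd], axis=-3)


def split_fused(fused) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`fuse`: return ``(t_de, t_psd)``."""
    fused = np.asarray(fused)
    half = fused.shape[-3] // 2
    return fused[..., :half, :, :], fused[..., half:, :, :]


def build_sequences(slices, label: int, length: int = SEQUENCE_LEN,
                    subject_id: str = "", trial_index: int = 0
                    ) -> list[SequenceSample]:
    """Group consecutive fused tensors of one trial into model inputs.

    Sequences are non-overlapping and preserve temporal order; a trailing
    remainder shorter than ``length`` is discarded.
    """
    slices = np.asarray(slices)
    n = slices.shape[0] // length
    if n == 0:
        warnings.warn(
            f"trial has {slices.shape[0]} slices < sequence length {length}; "
            "no sequences produced", stacklevel=2)
        return []
    return [
        SequenceSample(
            tensors=slices[i * length:(i + 1) * length],
            label=label, subject_id=subject_id, trial_index=trial_index,
            start_slice=i * length)
        for i in range(n)
    ]


def fused_tensors_for_recording(recording, layout=None, **feature_kwargs):
    """Fused tensors of every stimulus slice: ``(trials, slices, 8, 8, 9)``."""
    layout = layout or default_layout()
    de, bp = featurize_recording(recording, **feature_kwargs)
    de_grids = map_to_grid(de, layout)  # (trials, slices, bands, 8, 9)
    bp_grids = map_to_grid(bp, layout)
    return fuse(de_grids, bp_grids)


def recording_to_sequences(recording, task: str = "quadrant",
                           layout: ElectrodeLayout | None = None,
                           threshold: float = 5.0,
                           length: int = SEQUENCE_LEN,
                           **feature_kwargs) -> list[SequenceSample]:
    """Full front end: recording -> labelled 8-step fused-tensor sequences."""
    fused = fused_tensors_for_recording(recording, layout=layout,
                                        **feature_kwargs)
    labels = labels_for_task(recording.ratings, task=task,
                             threshold=threshold)
    samples: list[SequenceSample] = []
    for t in range(fused.shape[0]):
        samples.extend(
            build_sequences(fused[t], int(labels[t]), length=length,
                            subject_id=recording.subject_id, trial_index=t))
    return samples
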