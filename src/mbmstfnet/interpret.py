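"""Topographic maps, Inception branch activations and GRU temporal structure.

Three lenses on what the pipeline learns:

* group-mean DE / band-power values per electrode rendered on the 8x9 grid
  (cells without an electrode are NaN, not zero, so renderers can mask them);
* per-branch mean absolute activation of the Inception block over the grid;
* T x T Pearson correlation between GRU hidden-state vectors at pairs of
  time steps (correlated across hidden units within a sample, averaged over
  samples), compared between low- and high-arousal groups with a
  Mann-Whitney U test on the pooled off-diagonal entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .features import SliceFeatures
from .layout import ElectrodeLayout, default_layout
from .nn.model import MBMSTFNet

__all__ = [
    "TemporalCorrelationMatrix", "band_topomap", "branch_activation_maps",
    "gru_hidden_states", "temporal_correlation",
    "compare_arousal_correlations", "save_heatmap", "save_grid_csv",
]

BAND_INDEX = {"theta": 0, "alpha": 1, "beta": 2, "gamma": 3}


@dataclass
class TemporalCorrelationMatrix:
    """Symmetric T x T correlation structure of one GRU direction."""

    values: np.ndarray
    direction: str = "forward"     # forward | backward
    arousal_group: str = ""        # low | high | ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.values = v

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(self.values.shape[0], dtype=bool)
        return self.values[mask]


def band_topomap(features, band, feature_kind: str = "de",
                 layout: ElectrodeLayout | None = None) -> np.ndarray:
    """Group-mean feature per electrode on the grid; empty cells are NaN."""
    layout = layout or default_layout()
    if feature_kind not in ("de", "bp"):
        raise ValueError("feature_kind must be 'de' or 'bp'")
    if isinstance(band, str):
        band = BAND_INDEX[band]
    if isinstance(features, np.ndarray):
        mats = features  # (..., bands, channels)
        mats = mats.reshape(-1, mats.shape[-2], mats.shape[-1])
    else:
        feats = list(features)
        if not feats:
            raise ValueError("empty feature set")
        mats = np.stack([getattr(f, feature_kind) for f in feats
                         if isinstance(f, SliceFeatures)])
    if mats.size == 0:
        raise ValueError("empty feature set")
    mean_per_channel = mats[:, band, :].mean(axis=0)
    grid = np.full((layout.grid_rows, layout.grid_cols), np.nan)
    rows, cols = layout.rows_cols(layout.channel_order)
    grid[rows, cols] = mean_per_channel
    return grid


def branch_activation_maps(model: MBMSTFNet, inputs) -> dict[str, np.ndarray]:
    """Mean |activation| of each Inception branch over the 8x9 grid.

    ``inputs`` are model sequences ``(B, T, C, 8, 9)``; batch, time and
    feature channels are averaged out.
    """
    if model.inception is None:
        raise ValueError("model has no Inception block")
    x = np.asarray(inputs, dtype=model.config.np_dtype)
    B, T = x.shape[:2]
    folded = x.reshape(B * T, *x.shape[2:])
    conv_out = model.conv_stack_forward(folded)
    branches = model.inception.branch_outputs(conv_out)
    return {name: np.abs(act).mean(axis=(0, 1))
            for name, act in branches.items()}


def gru_hidden_states(model: MBMSTFNet, inputs, layer: int = -1
                      ) -> dict[str, np.ndarray]:
    """Per-direction hidden states ``(B, T, hidden)`` of one GRU layer.

    ``layer`` indexes the stacked recurrent layers (default: last).
    """
    if not model.grus:
        raise ValueError("model has no recurrent stage")
    x = np.asarray(inputs, dtype=model.config.np_dtype)
    B, T = x.shape[:2]
    folded = x.reshape(B * T, *x.shape[2:])
    h = model.conv_stack_forward(folded)
    if model.inception is not None:
        h = model.inception.forward(h)
    seq = model.pool.forward(h).reshape(B, T, -1)
    outputs = []
    for gru in model.grus:
        states = {}
        if hasattr(gru, "fwd"):  # bidirectional
            states["forward"] = gru.fwd.forward(seq)
            states["backward"] = gru.bwd.forward(seq)
            seq = np.concatenate([states["forward"], states["backward"]],
                                 axis=-1)
        else:
            states["forward"] = gru.forward(seq)
            seq = states["forward"]
        outputs.append(states)
    return outputs[layer]


def temporal_correlation(hidden_states, direction: str = "forward",
                         arousal_group: str = "") -> TemporalCorrelationMatrix:
    """Mean Pearson correlation between hidden vectors at step pairs.

    For each sample the hidden vectors at steps ``s`` and ``t`` are
    correlated across hidden units; the T x T matrices are then averaged
    over samples.
    """
    h = np.asarray(hidden_states, dtype=float)
    if h.ndim != 3:
        raise ValueError("hidden_states must be (samples, T, hidden)")
    n, T, H = h.shape
    if T < 2:
        raise ValueError("need at least 2 time steps")
    centered = h - h.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)
    if np.any(norms == 0):
        raise ValueError(
            "zero-variance hidden vector: correlation undefined")
    unit = centered / norms[:, :, np.newaxis]
    corr = np.einsum("nsh,nth->st", unit, unit) / n
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return TemporalCorrelationMatrix(values=corr, direction=direction,
                                     arousal_group=arousal_group)


def compare_arousal_correlations(low_matrices, high_matrices
                                 ) -> tuple[float, float, tuple[float, float]]:
    """Mann-Whitney U on pooled off-diagonal correlations, high vs low.

    Returns ``(U, p, (median_low, median_high))``; U is the statistic of
    the high-arousal sample, so complete dominance of high over low gives
    ``U = n_high * n_low``.
    """
    low = np.concatenate([m.off_diagonal() for m in _as_list(low_matrices)])
    high = np.concatenate([m.off_diagonal() for m in _as_list(high_matrices)])
    if low.size == 0 or high.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(low == low[0]) and np.all(high == high[0]) and low[0] == high[0]:
        warnings.warn("all correlations tied; U test degenerate", stacklevel=2)
        return float(len(high) * len(low) / 2.0), 1.0, \
            (float(np.median(low)), float(np.median(high)))
    res = sstats.mannwhitneyu(high, low, alternative="two-sided")
    return (float(res.statistic), float(res.pvalue),
            (float(np.median(low)), float(np.median(high))))


def _as_list(mats):
    if isinstance(mats, TemporalCorrelationMatrix):
        return [mats]
    return list(mats)


def save_heatmap(grid, path, title: str = "", vmin=None, vmax=None) -> None:
    """Render a grid as a red-high / blue-low heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.2))
    masked = np.ma.masked_invalid(np.asarray(grid, dtype=float))
    im = ax.imshow(masked, cmap="RdBu_r", vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.85)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_grid_csv(grid, path) -> None:
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",", fmt="%.6g")
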