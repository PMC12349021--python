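"""The full classifier: conv stack, Inception, BiGRU, attention, FC head.

The network consumes ``(batch, 8, C, 8, 9)`` sequences of fused band-space
tensors (``C`` = 8 for DE+PSD fusion, 4 for a single modality).  The batch
and time axes are folded together for the convolutional stage — a batch of
100 sequences becomes 800 independent 8x9 frames — and unfolded again into
``(batch, 8, 4096)`` before the recurrent stage:

* three 3x3 same-padded convolutions (8 -> 64 -> 128 -> 256), ReLU after each;
* a four-branch Inception block (1x1; 1x1 -> 3x3; 1x1 -> 5x5;
  3x3 max-pool -> 1x1), 64 channels per branch, concatenated to 256;
* 2x2/stride-2 max pooling to 256 x 4 x 4 and flattening to 4096;
* a two-layer bidirectional GRU with hidden size 128 (per-step output 256);
* 4-head self-attention (head width 64, bias-free projections);
* mean over the 8 attended steps, then 256 -> 1296 -> 512 -> n_classes
  with a softmax read-out.

Ablation variants (single modality, uni/no GRU, no Inception, no attention)
are expressed through :class:`ModelConfig`; widths downstream of a removed
or narrowed stage adapt automatically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from .attention import MultiHeadAttention
from .gru import BiGRU, GRU
from .layers import Conv2d, Linear, MaxPool2d, Module, ReLU, softmax

__all__ = ["ModelConfig", "InceptionBlock", "MBMSTFNet"]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 8
    conv_widths: tuple[int, int, int] = (64, 128, 256)
    inception: bool = True
    inception_out: int = 256
    gru: str = "bi"              # "bi" | "uni" | "none"
    gru_hidden: int = 128
    gru_layers: int = 2
    mha: bool = True
    n_heads: int = 4
    fc_dims: tuple[int, int] = (1296, 512)
    n_classes: int = 4
    temporal_steps: int = 8
    aggregate: str = "mean"      # "mean" | "last"
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gru not in ("bi", "uni", "none"):
            raise ValueError(f"unknown gru mode {self.gru!r}")
        if self.aggregate not in ("mean", "last"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type

    def variant(self, name: str) -> "ModelConfig":
        """Derive an ablation variant's architecture from this config."""
        if name == "full":
            return self
        if name in ("de_only", "psd_only"):
            return replace(self, in_channels=self.in_channels // 2)
        if name == "no_gru":
            return replace(self, gru="none")
        if name == "uni_gru":
            return replace(self, gru="uni")
        if name == "no_inception":
            return replace(self, inception=False)
        if name == "no_mha":
            return replace(self, mha=False)
        raise KeyError(f"unknown variant {name!r}")


class InceptionBlock(Module):
    """Four parallel branches concatenated along the channel axis."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype):
        if out_ch % 4:
            raise ValueError("inception output width must be divisible by 4")
        w = out_ch // 4
        self.b1 = [Conv2d(in_ch, w, 1, rng=rng, dtype=dtype), ReLU()]
        self.b2 = [Conv2d(in_ch, max(out_ch // 8, 1), 1, rng=rng, dtype=dtype),
                   ReLU(),
                   Conv2d(max(out_ch // 8, 1), w, 3, rng=rng, dtype=dtype),
                   ReLU()]
        self.b3 = [Conv2d(in_ch, max(out_ch // 16, 1), 1, rng=rng, dtype=dtype),
                   ReLU(),
                   Conv2d(max(out_ch // 16, 1), w, 5, rng=rng, dtype=dtype),
                   ReLU()]
        self.b4 = [MaxPool2d(3, stride=1, pad=1),
                   Conv2d(in_ch, w, 1, rng=rng, dtype=dtype), ReLU()]
        self.width = w

    def _run(self, branch, x):
        for layer in branch:
            x = layer.forward(x)
        return x

    def _run_back(self, branch, d):
        for layer in reversed(branch):
            d = layer.backward(d)
        return d

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = [self._run(b, x) for b in (self.b1, self.b2, self.b3, self.b4)]
        return np.concatenate(outs, axis=1)

    def branch_outputs(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Per-branch activations, keyed by branch kind."""
        return {
            "1x1": self._run(self.b1, x),
            "3x3": self._run(self.b2, x),
            "5x5": self._run(self.b3, x),
            "pool": self._run(self.b4, x),
        }

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.width
        parts = [dout[:, i * w:(i + 1) * w] for i in range(4)]
        dx = self._run_back(self.b1, parts[0])
        dx = dx + self._run_back(self.b2, parts[1])
        dx = dx + self._run_back(self.b3, parts[2])
        dx = dx + self._run_back(self.b4, parts[3])
        return dx


class MBMSTFNet(Module):
    """Multi-band spatio-temporal fusion network (NumPy implementation)."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        dtype = config.np_dtype
        rng = np.random.default_rng(config.seed)
        c1, c2, c3 = config.conv_widths
        self.conv1 = Conv2d(config.in_channels, c1, 3, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c1, c2, 3, rng=rng, dtype=dtype)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(c2, c3, 3, rng=rng, dtype=dtype)
        self.relu3 = ReLU()
        self.inception = (InceptionBlock(c3, config.inception_out, rng, dtype)
                          if config.inception else None)
        self.pool = MaxPool2d(2, stride=2)
        spatial_ch = config.inception_out if config.inception else c3
        self.flat_dim = spatial_ch * 4 * 4

        self.grus: list[Module] = []
        if config.gru == "bi":
            in_dim = self.flat_dim
            for _ in range(config.gru_layers):
                self.grus.append(BiGRU(in_dim, config.gru_hidden,
                                       rng=rng, dtype=dtype))
                in_dim = 2 * config.gru_hidden
            self.d_model = 2 * config.gru_hidden
        elif config.gru == "uni":
            in_dim = self.flat_dim
            for _ in range(config.gru_layers):
                self.grus.append(GRU(in_dim, config.gru_hidden,
                                     rng=rng, dtype=dtype))
                in_dim = config.gru_hidden
            self.d_model = config.gru_hidden
        else:
            self.d_model = self.flat_dim

        self.attention = (MultiHeadAttention(self.d_model, config.n_heads,
                                             rng=rng, dtype=dtype)
                          if config.mha else None)
        f1, f2 = config.fc_dims
        self.fc1 = Linear(self.d_model, f1, rng=rng, dtype=dtype)
        self.relu_fc1 = ReLU()
        self.fc2 = Linear(f1, f2, rng=rng, dtype=dtype)
        self.relu_fc2 = ReLU()
        self.out_layer = Linear(f2, config.n_classes, rng=rng, dtype=dtype)
        self._cache = None

    # ---------------------------------------------------------------- forward
    def conv_stack_forward(self, x: np.ndarray) -> np.ndarray:
        """(B, C, 8, 9) -> (B, conv_widths[-1], 8, 9)."""
        x = self.relu1.forward(self.conv1.forward(x))
        x = self.relu2.forward(self.conv2.forward(x))
        return self.relu3.forward(self.conv3.forward(x))

    def pool_flatten(self, x: np.ndarray) -> np.ndarray:
        pooled = self.pool.forward(x)
        self._pool_shape = pooled.shape
        return pooled.reshape(pooled.shape[0], -1)

    def head_forward(self, feats: np.ndarray) -> np.ndarray:
        """(B, d_model) aggregated features -> logits."""
        h = self.relu_fc1.forward(self.fc1.forward(feats))
        h = self.relu_fc2.forward(self.fc2.forward(h))
        return self.out_layer.forward(h)

    def forward(self, x: np.ndarray, stages: dict | None = None) -> np.ndarray:
        """Sequences ``(B, T, C, 8, 9)`` -> logits ``(B, n_classes)``.

        If ``stages`` is a dict it is filled with per-stage input/output
        shapes (the layer-table contract).
        """
        cfg = self.config
        B, T = x.shape[:2]
        if T != cfg.temporal_steps:
            raise ValueError(f"expected {cfg.temporal_steps} time steps, got {T}")
        x = np.ascontiguousarray(x, dtype=cfg.np_dtype)

        def log(name, xin, xout):
            if stages is not None:
                stages[name] = (tuple(xin.shape), tuple(xout.shape))

        folded = x.reshape(B * T, *x.shape[2:])
        log("input", x, x)
        h = self.relu1.forward(self.conv1.forward(folded))
        log("conv1", folded, h)
        h2 = self.relu2.forward(self.conv2.forward(h))
        log("conv2", h, h2)
        h3 = self.relu3.forward(self.conv3.forward(h2))
        log("conv3", h2, h3)
        if self.inception is not None:
            h4 = self.inception.forward(h3)
            log("inception", h3, h4)
        else:
            h4 = h3
        pooled = self.pool.forward(h4)
        log("maxpool", h4, pooled)
        self._pool_shape = pooled.shape
        flat = pooled.reshape(B, T, -1)
        log("flatten", pooled, flat.reshape(B * T, -1))

        seq = flat
        for i, gru in enumerate(self.grus):
            new = gru.forward(seq)
            log(f"gru{i + 1}", seq, new)
            seq = new
        if self.attention is not None:
            att = self.attention.forward(seq)
            log("attention", seq, att)
        else:
            att = seq
        if cfg.aggregate == "mean":
            feats = att.mean(axis=1)
        else:
            feats = att[:, -1]
        self._agg_T = T
        f1 = self.relu_fc1.forward(self.fc1.forward(feats))
        log("fc1", feats, f1)
        f2 = self.relu_fc2.forward(self.fc2.forward(f1))
        log("fc2", f1, f2)
        logits = self.out_layer.forward(f2)
        log("out", f2, logits)
        self._batch_time = (B, T)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config
        B, T = self._batch_time
        d = self.out_layer.backward(dlogits)
        d = self.fc2.backward(self.relu_fc2.backward(d))
        d = self.fc1.backward(self.relu_fc1.backward(d))
        if cfg.aggregate == "mean":
            datt = np.repeat(d[:, np.newaxis, :], T, axis=1) / T
        else:
            datt = np.zeros((B, T, d.shape[-1]), dtype=d.dtype)
            datt[:, -1] = d
        if self.attention is not None:
            dseq = self.attention.backward(datt)
        else:
            dseq = datt
        for gru in reversed(self.grus):
            dseq = gru.backward(dseq)
        dpooled = np.ascontiguousarray(dseq).reshape(self._pool_shape)
        dh4 = self.pool.backward(dpooled)
        if self.inception is not None:
            dh3 = self.inception.backward(dh4)
        else:
            dh3 = dh4
        dh2 = self.conv3.backward(self.relu3.backward(dh3))
        dh1 = self.conv2.backward(self.relu2.backward(dh2))
        self.conv1.backward(self.relu1.backward(dh1), need_input_grad=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x), axis=-1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=-1)

    # ------------------------------------------------------------ bookkeeping
    def components(self) -> dict[str, Module | None]:
        comp: dict[str, Module | list] = {
            "conv1": self.conv1, "conv2": self.conv2, "conv3": self.conv3,
            "fc1": self.fc1, "fc2": self.fc2, "out": self.out_layer,
        }
        if self.inception is not None:
            comp["inception"] = self.inception
        if self.grus:
            comp["bigru" if self.config.gru == "bi" else "gru"] = self.grus
        if self.attention is not None:
            comp["attention"] = self.attention
        return comp

    def count_parameters(self, component: str = "total") -> int:
        """Trainable-scalar count of a named component (or ``total``)."""
        if component == "total":
            return self.n_parameters()
        comp = self.components()
        aliases = {"out_layer": "out", "outlayer": "out", "mha": "attention",
                   "gru": "bigru" if self.config.gru == "bi" else "gru"}
        key = aliases.get(component.lower(), component.lower())
        if key not in comp:
            raise KeyError(
                f"unknown component {component!r}; have {sorted(comp)}")
        item = comp[key]
        if isinstance(item, list):
            return sum(m.n_parameters() for m in item)
        return item.n_parameters()

    def summary_rows(self, batch: int = 100) -> list[tuple[str, tuple, tuple, int]]:
        """Layer-table rows: (name, input shape, output shape, n params)."""
        cfg = self.config
        x = np.zeros((batch, cfg.temporal_steps, cfg.in_channels, 8, 9),
                     dtype=cfg.np_dtype)
        stages: dict = {}
        self.forward(x, stages=stages)
        counts = {
            "conv1": self.conv1.n_parameters(),
            "conv2": self.conv2.n_parameters(),
            "conv3": self.conv3.n_parameters(),
            "inception": (self.inception.n_parameters()
                          if self.inception else 0),
            "fc1": self.fc1.n_parameters(),
            "fc2": self.fc2.n_parameters(),
            "out": self.out_layer.n_parameters(),
            "attention": (self.attention.n_parameters()
                          if self.attention else 0),
        }
        for i, gru in enumerate(self.grus):
            counts[f"gru{i + 1}"] = gru.n_parameters()
        rows = []
        for name, (sin, sout) in stages.items():
            rows.append((name, sin, sout, counts.get(name, 0)))
        return rows

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "MBMSTFNet":
        with np.load(path, allow_pickle=False) as npz:
            cfg_dict = json.loads(str(npz["__config__"]))
            for key in ("conv_widths", "fc_dims"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict))
            for i, p in enumerate(model.parameters()):
                p.value[...] = npz[f"p{i}"]
        return model
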