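"""Within-subject cross-validation, ablation variants and fold-paired tests.

Protocol: for each subject, the labelled 4 s sequences are randomly
partitioned into five folds; each fold serves once as the test set while
the other four train a freshly initialised network (Adam, cross-entropy).
Fold accuracies are pooled across subjects into a report with mean and SD.

Folds partition *sequences*, not raw 0.5 s slices, so the eight slices of
one model input never straddle the train/test boundary.  Features are
standardised per tensor channel with statistics computed on the training
folds only (structurally zero grid cells are left untouched).

Ablation variants: ``de_only`` / ``psd_only`` (first/last four tensor
channels), ``no_gru`` (conv features straight into attention), ``uni_gru``
(forward-only recurrence), ``no_inception`` and ``no_mha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .nn import Adam, MBMSTFNet, ModelConfig, softmax_cross_entropy
from .tensorize import recording_to_sequences

__all__ = [
    "TrainConfig", "CVReport", "VARIANTS", "make_folds", "standardize",
    "train_fold", "cross_validate", "run_ablation", "paired_t_test",
    "samples_to_arrays",
]

VARIANTS: tuple[str, ...] = ("full", "de_only", "psd_only", "no_gru",
                             "uni_gru", "no_inception", "no_mha")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 100
    epochs: int = 100
    folds: int = 5
    grad_clip: float | None = None  # global gradient-norm ceiling
    seed: int = 0
    task: str = "quadrant"        # valence | arousal | quadrant
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")


@dataclass
class CVReport:
    """Pooled fold accuracies for one model variant and task."""

    per_fold_acc: list[float]
    per_subject_acc: dict[str, float]
    variant: str
    task: str
    loss_logs: list[list[float]] = field(default_factory=list)

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.per_fold_acc))

    @property
    def sd_acc(self) -> float:
        return float(np.std(self.per_fold_acc, ddof=1)) \
            if len(self.per_fold_acc) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant, "task": self.task,
            "mean_acc": self.mean_acc, "sd_acc": self.sd_acc,
            "per_fold_acc": list(map(float, self.per_fold_acc)),
            "per_subject_acc": {k: float(v)
                                for k, v in self.per_subject_acc.items()},
        }


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def make_folds(n_samples: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Random partition of ``range(n_samples)`` into ``k`` near-equal folds."""
    if n_samples < k:
        raise ValueError(f"{n_samples} samples cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    return [np.sort(part) for part in np.array_split(perm, k)]


def standardize(X_train: np.ndarray, X_test: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per tensor-channel z-scoring with train-fold statistics.

    Statistics pool every sample, time step and occupied grid cell of a
    channel; cells that are structurally zero throughout training (no
    electrode) are left at zero.
    """
    axes = (0, 1, 3, 4)
    mean = X_train.mean(axis=axes, keepdims=True)
    sd = X_train.std(axis=axes, keepdims=True)
    occupied = np.any(X_train != 0.0, axis=(0, 1), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)

    def z(X):
        out = (X - mean) / sd
        return np.where(occupied, out, 0.0).astype(np.float32)

    return z(X_train), z(X_test)


def _slice_variant(X: np.ndarray, variant: str) -> np.ndarray:
    half = X.shape[2] // 2
    if variant == "de_only":
        return X[:, :, :half]
    if variant == "psd_only":
        return X[:, :, half:]
    return X


def _iter_minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_fold(X_train, y_train, X_test, y_test,
               model_config: ModelConfig, train_config: TrainConfig,
               seed: int | None = None) -> tuple[float, list[float]]:
    """Train a fresh model on one fold split; return test accuracy + loss log."""
    seed = train_config.seed if seed is None else seed
    X_train, X_test = standardize(np.asarray(X_train, dtype=np.float32),
                                  np.asarray(X_test, dtype=np.float32))
    model = MBMSTFNet(
        ModelConfig(**{**model_config.__dict__, "seed": seed}))
    opt = Adam(model.parameters(), lr=train_config.lr)
    rng = np.random.default_rng(seed + 1)
    loss_log: list[float] = []
    for epoch in range(train_config.epochs):
        losses = []
        for idx in _iter_minibatches(len(y_train), train_config.batch_size, rng):
            logits = model.forward(X_train[idx])
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            model.backward(dlogits)
            if train_config.grad_clip is not None:
                _clip_grad_norm(model.parameters(), train_config.grad_clip)
            opt.step()
            losses.append(loss)
        loss_log.append(float(np.mean(losses)))
    preds = _predict_batched(model, X_test, train_config.batch_size)
    return float(np.mean(preds == y_test)), loss_log


def _clip_grad_norm(parameters, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                        for p in parameters))
    if total > max_norm:
        scale = max_norm / total
        for p in parameters:
            p.grad *= scale


def _predict_batched(model, X, batch_size):
    preds = []
    for start in range(0, len(X), batch_size):
        preds.append(model.predict(X[start:start + batch_size]))
    return np.concatenate(preds)


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    """Stack ``SequenceSample`` lists into ``(X, y)`` arrays."""
    X = np.stack([s.tensors for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples])
    return X, y


def cross_validate(recordings=None, model_config: ModelConfig | None = None,
                   train_config: TrainConfig = TrainConfig(),
                   subject_samples: dict | None = None,
                   shuffle_labels: bool = False) -> CVReport:
    """Per-subject k-fold CV; pools fold accuracies across subjects.

    ``subject_samples`` (``{subject_id: (X, y)}``) bypasses the feature
    front end when the fused sequences are precomputed; otherwise they are
    derived from ``recordings``.  ``shuffle_labels`` randomly permutes each
    subject's labels (leakage control: accuracy must fall to chance).
    """
    tc = train_config
    mc = (model_config or ModelConfig()).variant(tc.variant)
    if subject_samples is None:
        if recordings is None:
            raise ValueError("need recordings or subject_samples")
        subject_samples = {}
        for rec in recordings:
            X, y = samples_to_arrays(
                recording_to_sequences(rec, task=tc.task))
            subject_samples[rec.subject_id] = (X, y)

    per_fold: list[float] = []
    per_subject: dict[str, float] = {}
    loss_logs: list[list[float]] = []
    for s_idx, (subject, (X, y)) in enumerate(sorted(subject_samples.items())):
        X = _slice_variant(np.asarray(X, dtype=np.float32), tc.variant)
        y = np.asarray(y)
        rng = np.random.default_rng(tc.seed + 1000 * s_idx)
        if shuffle_labels:
            y = rng.permutation(y)
        folds = make_folds(len(y), tc.folds, seed=tc.seed + s_idx)
        subject_accs = []
        all_idx = np.arange(len(y))
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            assert np.intersect1d(train_idx, test_idx).size == 0
            acc, losses = train_fold(
                X[train_idx], y[train_idx], X[test_idx], y[test_idx],
                mc, tc, seed=tc.seed + 100 * s_idx + f)
            per_fold.append(acc)
            subject_accs.append(acc)
            loss_logs.append(losses)
        per_subject[subject] = float(np.mean(subject_accs))
    return CVReport(per_fold_acc=per_fold, per_subject_acc=per_subject,
                    variant=tc.variant, task=tc.task, loss_logs=loss_logs)


def run_ablation(variant: str, recordings=None,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig = TrainConfig(),
                 subject_samples: dict | None = None) -> CVReport:
    """Cross-validate one ablation variant (``full`` = the reference model)."""
    if variant not in VARIANTS:
        raise KeyError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    tc = TrainConfig(**{**train_config.__dict__, "variant": variant})
    return cross_validate(recordings=recordings, model_config=model_config,
                          train_config=tc, subject_samples=subject_samples)


def paired_t_test(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on fold-wise accuracy differences."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length lists of >= 2 fold accuracies")
    d = a - b
    if np.allclose(d.var(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError(
            "zero-variance fold differences: paired t-test degenerate")
    res = sstats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
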