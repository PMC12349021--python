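"""Named run profiles bundling generator, model and training settings.

``desk-demo`` is the self-contained profile the test suite exercises: two
synthetic subjects with strong class-conditional band gains, short (16 s)
stimulus periods and ten training epochs — small enough for a single CPU
while exercising every stage of the full architecture.

``paper-scale`` documents the full protocol (32 subjects x 40 one-minute
trials, 100 epochs, batch 100, five folds within subject).  It requires
the externally licensed DEAP download supplied by the user; nothing is
fetched automatically, and its accuracy figures are not reproducible from
synthetic desk-scale runs.

``smoke`` is a seconds-scale profile (reduced model widths) for CLI and
integration checks only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn.model import ModelConfig
from .synthetic import SynthConfig, default_gain_map
from .training import TrainConfig

__all__ = ["Preset", "get_preset", "PRESETS"]


@dataclass(frozen=True)
class Preset:
    name: str
    synth: SynthConfig
    model: ModelConfig
    train: TrainConfig
    requires_deap: bool = False


def get_preset(name: str, seed: int = 0) -> Preset:
    """Instantiate a named preset with every stage seeded from ``seed``."""
    if name in ("desk-demo", "desk_demo"):
        return Preset(
            name="desk-demo",
            synth=SynthConfig(
                n_subjects=2, n_trials=8, stimulus_sec=16.0,
                band_gain_map=default_gain_map(3.0), noise_sd=1.0, seed=seed),
            model=ModelConfig(seed=seed),
            train=TrainConfig(epochs=10, batch_size=4, lr=2e-4,
                              grad_clip=5.0, seed=seed),
        )
    if name in ("paper-scale", "paper_scale"):
        return Preset(
            name="paper-scale",
            synth=SynthConfig(n_subjects=32, n_trials=40, stimulus_sec=60.0,
                              seed=seed),
            model=ModelConfig(seed=seed),
            train=TrainConfig(epochs=100, batch_size=100, seed=seed),
            requires_deap=True,
        )
    if name == "smoke":
        return Preset(
            name="smoke",
            synth=SynthConfig(
                n_subjects=1, n_trials=8, stimulus_sec=8.0,
                band_gain_map=default_gain_map(3.0), noise_sd=0.5, seed=seed),
            model=ModelConfig(conv_widths=(8, 16, 32), inception_out=32,
                              gru_hidden=16, fc_dims=(64, 32), seed=seed),
            train=TrainConfig(epochs=2, batch_size=8, seed=seed),
        )
    raise KeyError(f"unknown preset {name!r}")


PRESETS: tuple[str, ...] = ("desk-demo", "paper-scale", "smoke")
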