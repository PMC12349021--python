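"""DEAP-shaped synthetic EEG with class-conditional band-power structure.

Each trial is a sum of one fixed mid-band carrier per oscillation band per
channel (theta 6 Hz, alpha 10 Hz, beta 20 Hz, gamma 38 Hz; random phase per
trial/channel/band) plus white Gaussian noise.  Carrier amplitudes during
the stimulus period are scaled by a per-quadrant, per-band, per-region gain
map; the rest baseline carries neutral (unit) gains.  The trial's emotion
quadrant is drawn first and the valence/arousal ratings are then sampled
uniformly from that class's half of the 1-9 scale, so labels and band-power
structure are consistent by construction.

Two optional components create *modality-specific* class signals, exploiting
that the PSD path is average-referenced while the DE path is not:

* a spatially common-mode carrier (identical waveform on every channel)
  whose amplitude depends on the class — visible to DE, removed exactly by
  average referencing, hence invisible to band power;
* a fixed-amplitude carrier whose across-channel sign pattern depends on
  the class (coherent = all channels in phase vs. alternating = half the
  channels sign-flipped) — per-channel variance, and therefore DE, is
  class-invariant, while the average-referenced power vanishes in the
  coherent pattern and survives intact in the alternating one.

This is deliberately not biophysical EEG: no 1/f background, volume
conduction or artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layout import DEAP_CHANNELS, REGIONS, region_of
from .recording import EEGRecording

__all__ = [
    "QUADRANTS", "BAND_CARRIERS", "SynthConfig", "default_gain_map",
    "complementary_config", "generate_recording", "generate_dataset",
]

QUADRANTS: tuple[str, ...] = ("HVHA", "HVLA", "LVHA", "LVLA")
BAND_NAMES: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
#: Fixed mid-band carrier frequency per band (Hz).
BAND_CARRIERS: dict[str, float] = {
    "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 38.0,
}


def default_gain_map(strength: float = 2.0) -> dict:
    """Quadrant -> band -> region gain map with the canonical structure.

    High arousal elevates frontal beta and gamma; high valence elevates
    posterior (parietal + occipital) alpha.  All other gains are 1.
    """
    gains: dict[str, dict[str, dict[str, float]]] = {}
    for cls in QUADRANTS:
        per_band = {b: {} for b in BAND_NAMES}
        if cls[2] == "H":  # high arousal
            per_band["beta"]["frontal"] = strength
            per_band["gamma"]["frontal"] = strength
        if cls[0] == "H":  # high valence
            per_band["alpha"]["parietal"] = strength
            per_band["alpha"]["occipital"] = strength
        gains[cls] = per_band
    return gains


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; identical config + seed gives identical output."""

    n_subjects: int = 2
    n_trials: int = 40
    fs: float = 128.0
    baseline_sec: float = 3.0
    stimulus_sec: float = 60.0
    n_channels: int = 32
    band_gain_map: dict = field(default_factory=default_gain_map)
    carrier_amp: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    # modality-specific components (see module docstring)
    common_mode_amp: dict | None = None      # class -> amplitude
    common_mode_freq: float = 10.0
    coherence_pattern: dict | None = None    # class -> "coherent"|"alternating"
    coherence_amp: float = 0.0
    coherence_freq: float = 20.0
    #: draw carrier phases once per recording instead of per trial, so that
    #: trials differ only through class structure and noise (no per-trial
    #: phase fingerprint a classifier could memorise across CV folds)
    shared_trial_phases: bool = False

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.baseline_sec <= 0 or self.stimulus_sec <= 0:
            raise ValueError("fs and durations must be positive")
        if self.n_channels != len(DEAP_CHANNELS):
            raise ValueError(
                f"n_channels={self.n_channels} does not match the "
                f"{len(DEAP_CHANNELS)}-electrode layout"
            )
        _validate_gain_map(self.band_gain_map)
        for mapping, what in ((self.common_mode_amp, "common_mode_amp"),
                              (self.coherence_pattern, "coherence_pattern")):
            if mapping is not None:
                missing = set(QUADRANTS) - set(mapping)
                if missing:
                    raise ValueError(f"{what} missing classes {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        total = self.fs * (self.baseline_sec + self.stimulus_sec)
        if abs(total - round(total)) > 1e-9:
            raise ValueError("fs * duration must be an integer sample count")
        return int(round(total))

    @property
    def n_baseline_samples(self) -> int:
        return int(round(self.fs * self.baseline_sec))


def _validate_gain_map(gain_map: dict) -> None:
    missing_cls = set(QUADRANTS) - set(gain_map)
    if missing_cls:
        raise ValueError(f"band_gain_map missing classes {sorted(missing_cls)}")
    for cls in QUADRANTS:
        per_band = gain_map[cls]
        missing_band = set(BAND_NAMES) - set(per_band)
        if missing_band:
            raise ValueError(
                f"band_gain_map[{cls}] missing bands {sorted(missing_band)}"
            )
        for band, regions in per_band.items():
            unknown = set(regions) - set(REGIONS)
            if unknown:
                raise ValueError(
                    f"band_gain_map[{cls}][{band}] has unknown regions "
                    f"{sorted(unknown)}"
                )


def complementary_config(n_subjects: int = 1, n_trials: int = 8,
                         stimulus_sec: float = 16.0, noise_sd: float = 1.0,
                         seed: int = 0) -> SynthConfig:
    """Config in which DE and PSD carry complementary class information.

    Valence is encoded only in the common-mode alpha amplitude (DE-visible,
    erased by average referencing); arousal only in the beta coherence
    pattern (band-power-visible, invisible to per-channel variance).  All
    region gains are neutral, so neither modality alone can separate all
    four quadrants but their fusion can.
    """
    neutral = {cls: {b: {} for b in BAND_NAMES} for cls in QUADRANTS}
    # the class carriers sit inside their bands but away from the band
    # carriers (10/20 Hz), so no cross-term between them survives a slice
    return SynthConfig(
        n_subjects=n_subjects, n_trials=n_trials, stimulus_sec=stimulus_sec,
        band_gain_map=neutral, noise_sd=noise_sd, seed=seed,
        common_mode_amp={"HVHA": 4.0, "HVLA": 4.0, "LVHA": 0.5, "LVLA": 0.5},
        common_mode_freq=11.0,
        coherence_pattern={"HVHA": "alternating", "LVHA": "alternating",
                           "HVLA": "coherent", "LVLA": "coherent"},
        coherence_amp=2.0, coherence_freq=26.0,
        shared_trial_phases=True,
    )


def _channel_gains(config: SynthConfig, cls: str) -> np.ndarray:
    """(bands, channels) stimulus amplitude gains for a class."""
    gains = np.ones((len(BAND_NAMES), config.n_channels))
    per_band = config.band_gain_map[cls]
    for b, band in enumerate(BAND_NAMES):
        for c, name in enumerate(DEAP_CHANNELS):
            gains[b, c] = per_band[band].get(region_of(name), 1.0)
    return gains


def _rating_for(cls: str, rng: np.random.Generator) -> tuple[float, float]:
    v = rng.uniform(5.0, 9.0) if cls[0] == "H" else rng.uniform(1.0, 5.0)
    a = rng.uniform(5.0, 9.0) if cls[2] == "H" else rng.uniform(1.0, 5.0)
    return v, a


def generate_recording(config: SynthConfig, subject_id: str = "s01",
                       seed: int | None = None) -> EEGRecording:
    """Synthesise one subject's trials under ``config``.

    Quadrant classes are assigned in a balanced, shuffled order (every class
    appears ``n_trials // 4`` or one more time), then ratings are drawn from
    the matching halves of the scale.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, nb = config.n_samples, config.n_baseline_samples
    t = np.arange(n) / config.fs
    n_ch = config.n_channels

    reps = -(-config.n_trials // len(QUADRANTS))
    classes = np.tile(np.array(QUADRANTS), reps)[: config.n_trials]
    rng.shuffle(classes)

    data = np.empty((config.n_trials, n_ch, n), dtype=np.float64)
    ratings = np.empty((config.n_trials, 2))

    shared = None
    if config.shared_trial_phases:
        shared = {
            "band": rng.uniform(0.0, 2.0 * np.pi, size=(len(BAND_NAMES), n_ch)),
            "cm": rng.uniform(0.0, 2.0 * np.pi),
            "coh": rng.uniform(0.0, 2.0 * np.pi),
        }

    for trial, cls in enumerate(classes):
        gains = _channel_gains(config, cls)
        x = rng.normal(0.0, config.noise_sd, size=(n_ch, n))
        for b, band in enumerate(BAND_NAMES):
            freq = BAND_CARRIERS[band]
            phase = (shared["band"][b] if shared is not None
                     else rng.uniform(0.0, 2.0 * np.pi, size=n_ch))
            carrier = np.sin(2.0 * np.pi * freq * t[np.newaxis, :]
                             + phase[:, np.newaxis])
            amp = np.full((n_ch, n), config.carrier_amp)
            amp[:, nb:] *= gains[b][:, np.newaxis]
            x += amp * carrier
        if config.common_mode_amp is not None:
            phase = (shared["cm"] if shared is not None
                     else rng.uniform(0.0, 2.0 * np.pi))
            wave = np.sin(2.0 * np.pi * config.common_mode_freq * t + phase)
            amp = np.full(n, 1.0)
            amp[nb:] = config.common_mode_amp[cls]
            x += (amp * wave)[np.newaxis, :]
        if config.coherence_pattern is not None:
            phase = (shared["coh"] if shared is not None
                     else rng.uniform(0.0, 2.0 * np.pi))
            wave = config.coherence_amp * np.sin(
                2.0 * np.pi * config.coherence_freq * t + phase)
            signs = np.ones(n_ch)
            if config.coherence_pattern[cls] == "alternating":
                signs[1::2] = -1.0
            # baseline stays coherent for every class (class-neutral)
            x[:, nb:] += np.outer(signs, wave[nb:])
            x[:, :nb] += wave[np.newaxis, :nb]
        data[trial] = x
        ratings[trial] = _rating_for(cls, rng)

    return EEGRecording(subject_id=subject_id, data=data, fs=config.fs,
                        ratings=ratings, channel_names=DEAP_CHANNELS,
                        baseline_sec=config.baseline_sec)


def generate_dataset(config: SynthConfig) -> list[EEGRecording]:
    """One recording per subject, each with a distinct derived sub-seed."""
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_subjects)
    return [
        generate_recording(config, subject_id=f"s{i + 1:02d}",
                           seed=int(seeds[i] % (2**31 - 1)))
        for i in range(config.n_subjects)
    ]


def scaled_config(config: SynthConfig, **overrides) -> SynthConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
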