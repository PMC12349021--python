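"""The in-memory container for one subject's trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import DEAP_CHANNELS


@dataclass
class EEGRecording:
    """One subject: ``trials x channels x samples`` plus ratings.

    ``data`` covers the full trial (rest baseline followed by the stimulus
    period); ``ratings`` holds one ``(valence, arousal)`` pair per trial on
    the 1-9 self-assessment scale.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    ratings: np.ndarray
    channel_names: tuple[str, ...] = field(default=DEAP_CHANNELS)
    baseline_sec: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.ratings.shape != (self.data.shape[0], 2):
            raise ValueError("ratings must be (n_trials, 2) valence/arousal")
        if np.any((self.ratings < 1.0) | (self.ratings > 9.0)):
            raise ValueError("ratings must lie in [1, 9]")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]
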