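import numpy as np
import pytest

from mbmstfnet.synthetic import (SynthConfig, default_gain_map,
                                 generate_recording)


@pytest.fixture(scope="session")
def tiny_recording():
    """One subject, four short trials, strong gains: cheap but structured."""
    config = SynthConfig(n_subjects=1, n_trials=4, stimulus_sec=8.0,
                         band_gain_map=default_gain_map(3.0), noise_sd=0.5,
                         seed=7)
    return generate_recording(config, subject_id="tiny")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
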