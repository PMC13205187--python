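import dataclasses

import numpy as np
import pytest

from pearspec import synthetic


@pytest.fixture(scope="session")
def noiseless_config():
    return synthetic.SpectrumSimConfig(noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def class_spectra(noiseless_config):
    """One noiseless spectrum per class, shared seed."""
    return {
        label: synthetic.generate_spectrum(
            dataclasses.replace(noiseless_config, class_label=label)
        )
        for label in synthetic.CLASS_LABELS
    }


@pytest.fixture(scope="session")
def small_dataset():
    """Low-noise labeled dataset: 20 per class, 1044 wavelengths."""
    template = synthetic.SpectrumSimConfig(noise_sd=0.01)
    return synthetic.generate_dataset((20, 20, 20), template, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
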