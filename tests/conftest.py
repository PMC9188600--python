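import numpy as np
import pytest

from phonemark import preprocess
from phonemark.synth import SynthSpec, synthesize_vowel


@pytest.fixture(scope="session")
def clean_vowel():
    """A clean (negligible-noise, unperturbed) 100 Hz vowel with truth."""
    spec = SynthSpec(duration=1.0, f0=100.0, noise_db=-60.0,
                     tract_length_cm=16.75, seed=1)
    return synthesize_vowel(spec)


@pytest.fixture(scope="session")
def perturbed_vowel():
    """A moderately perturbed vowel resembling a disordered voice."""
    spec = SynthSpec(duration=1.0, f0=110.0, jitter_rel_target=0.01,
                     shimmer_rel_target=0.04, noise_db=-25.0,
                     tract_length_cm=16.75, intensity_drift_db=2.0, seed=7)
    return synthesize_vowel(spec)


def frontend(seg, duration=0.5):
    """The standard extraction front-end: center trim + band-pass."""
    return preprocess.bandpass(preprocess.trim_uniform(seg, duration))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
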