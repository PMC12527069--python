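import numpy as np
import pytest

from ecgkit import BeatDataset, SyntheticSpec, generate_beat_dataset

UNIFORM = (0.2, 0.2, 0.2, 0.2, 0.2)


@pytest.fixture(scope="session")
def balanced_dataset() -> BeatDataset:
    """600 low-noise beats, all five classes equally represented."""
    spec = SyntheticSpec(n_beats=600, class_proportions=UNIFORM,
                         noise_sd=0.05, seed=11)
    return generate_beat_dataset(spec)


@pytest.fixture(scope="session")
def imbalanced_dataset() -> BeatDataset:
    """2,000 beats with the default majority-N class mixture."""
    spec = SyntheticSpec(n_beats=2000, noise_sd=0.05, seed=12)
    return generate_beat_dataset(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
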