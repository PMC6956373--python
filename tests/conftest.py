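import numpy as np
import pytest

from eegstress.deap_io import assemble_datasets
from eegstress.synthetic_data import SyntheticSpec, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_spec(**overrides) -> SyntheticSpec:
    """A small, fast surrogate study (short trials, few channels)."""
    params = dict(
        n_participants=1,
        n_trials_per_participant=6,
        n_channels=4,
        duration_s=8.0,
        baseline_s=1.0,
        seed=7,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture
def tiny_dataset():
    """One participant's labelled dataset from the tiny surrogate study."""
    trials, ratings = generate_study(tiny_spec())
    (ds,) = assemble_datasets(trials, ratings)
    return ds
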