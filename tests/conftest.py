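import numpy as np
import pytest

from emgtrace.evaluation import prepare_trial
from emgtrace.synth import DatasetConfig, iter_trials


@pytest.fixture(scope="session")
def small_dataset():
    """4 shapes x 6 repetitions with full EMG, deterministic."""
    cfg = DatasetConfig(
        shapes=("horizontal_line", "vertical_line", "circle", "arch"),
        repetitions=6,
        seed=42,
    )
    return list(iter_trials(cfg))


@pytest.fixture(scope="session")
def small_trials(small_dataset):
    return [prepare_trial(r) for r in small_dataset]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
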