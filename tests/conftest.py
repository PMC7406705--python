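import numpy as np
import pytest

from dsiscreen import default_config, default_hierarchy, generate_cohort


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (28 negative / 20 positive), fixed seed."""
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def null_config():
    """Default config with positive-class laws set equal to the negative ones."""
    config = default_config(seed=0)
    for f in config.features:
        f.pos_params = dict(f.neg_params)
        f.missing_rate_pos = f.missing_rate_neg
        f.direction_truth = "none"
    return config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
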