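import numpy as np
import pytest

from admarkov import TransitionParamTable


@pytest.fixture(scope="session")
def default_table() -> TransitionParamTable:
    return TransitionParamTable.default()


@pytest.fixture(scope="session")
def zero_sd_table(default_table) -> TransitionParamTable:
    """Default means with all SDs zero: shared, deterministic probabilities."""
    return default_table.with_zero_sds()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180129)
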