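import numpy as np
import pytest

from megconn.geometry import default_head_model, default_source_model


@pytest.fixture(scope="session")
def head_model():
    return default_head_model()


@pytest.fixture(scope="session")
def source_model_20(head_model):
    return default_source_model(20, head_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210317)
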