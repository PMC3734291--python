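import warnings

import numpy as np
import pytest

from tumorperf.params import Parameters

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture()
def params() -> Parameters:
    return Parameters().validate()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
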