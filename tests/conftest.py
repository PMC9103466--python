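import warnings

import numpy as np
import pytest

from cdfcd import gen_sleep_epochs


@pytest.fixture(autouse=True)
def _quiet_convergence():
    """Model-fitting warnings (early stops, pruning) are expected in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_epochs():
    """300 labelled 5-class synthetic epochs shared by the slower tests."""
    return gen_sleep_epochs([60] * 5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
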