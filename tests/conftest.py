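import warnings

import numpy as np
import pytest

import gammatongue as gt

# RF-coverage warnings from edge oscillators are expected on the model patch
warnings.filterwarnings("ignore", message="some receptive fields extend")


@pytest.fixture(scope="session")
def small_sheet():
    """10 x 10 oscillator sheet over the model region (fast tests)."""
    return gt.build_sheet(n=10)


@pytest.fixture(scope="session")
def full_sheet():
    """The study-scale 20 x 20 sheet."""
    return gt.build_sheet(n=20)


@pytest.fixture(scope="session")
def small_simulator(small_sheet):
    return gt.SessionSimulator(sheet=small_sheet, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
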