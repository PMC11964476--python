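import numpy as np
import pytest

from hemafluor import ExcitationSource, default_blood_library


@pytest.fixture
def library():
    return default_blood_library()


@pytest.fixture
def broadband():
    return ExcitationSource(kind="deuterium+halogen")


@pytest.fixture
def ex_grid():
    return np.arange(250.0, 500.0 + 1e-9, 2.0)


@pytest.fixture
def em_grid():
    return np.arange(300.0, 600.0 + 1e-9, 2.0)


@pytest.fixture
def full_grid():
    """200-900 nm at 0.5 nm, the instrument's native range."""
    return np.arange(200.0, 900.0 + 1e-9, 0.5)
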