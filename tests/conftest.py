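import numpy as np
import pytest

from fracml import parameter_registry


@pytest.fixture(scope="session")
def params2d_class1():
    return parameter_registry("i", 2).params


@pytest.fixture(scope="session")
def params2d_class2():
    return parameter_registry("ii", 2).params


@pytest.fixture(scope="session")
def params3d():
    return {g: parameter_registry(g, 3).params for g in ("i", "ii", "iii")}


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
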