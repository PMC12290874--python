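import warnings

import numpy as np
import pytest

from sgmfc import SyntheticSpec, generate_connectome, preprocess_sc


@pytest.fixture(scope="session")
def sc16():
    """Preprocessed 16-region synthetic connectome (the desk-scale default)."""
    return preprocess_sc(generate_connectome(SyntheticSpec(n_regions=16, seed=0)))


@pytest.fixture(scope="session")
def sc8():
    return preprocess_sc(generate_connectome(SyntheticSpec(n_regions=8, seed=2)))


@pytest.fixture(scope="session")
def sc6():
    return preprocess_sc(generate_connectome(SyntheticSpec(n_regions=6, seed=7)))


@pytest.fixture(scope="session")
def sc4():
    return preprocess_sc(generate_connectome(SyntheticSpec(n_regions=4, seed=7)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Optimizer / filter warnings are irrelevant noise for the assertions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
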