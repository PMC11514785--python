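import numpy as np
import pytest

from swfe.design import CellSizes, add_clusters, make_stepped_design
from swfe.simulate import PopulationParams, replicate_rng, simulate_trial


@pytest.fixture(scope="session")
def wedge45():
    """Standard 4-cluster, 5-period wedge."""
    return make_stepped_design(4, 5)


@pytest.fixture(scope="session")
def design55(wedge45):
    """4 stepped clusters + 1 unexposed cluster over 5 periods."""
    return add_clusters(wedge45, n_unexposed=1)


@pytest.fixture(scope="session")
def beta55():
    """True parameters for the 5x5 binary setting at ICC 0.05."""
    return np.concatenate([
        [np.log(1.25)],
        0.1 * np.arange(1, 5),
        np.full(5, np.log(0.30 / 0.70)),
    ])


@pytest.fixture(scope="session")
def binary_params():
    return PopulationParams(
        delta=np.log(1.25),
        mu_alpha=float(np.log(0.30 / 0.70)),
        tau2=0.1731,
        family="binary",
        period_slope=0.1,
        size_shape=100.0,
    )


@pytest.fixture(scope="session")
def binary_trial(design55, binary_params):
    """One simulated binary trial on the 4+1 design (fixed stream)."""
    rng = replicate_rng(12345, 0, 0)
    return simulate_trial(design55, binary_params, rng)


@pytest.fixture(scope="session")
def sizes_const100(design55):
    return CellSizes.constant(design55, 100)
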