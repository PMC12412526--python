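import numpy as np
import pytest

from vesselquant import synthvasc as sv


@pytest.fixture(scope="session")
def straight_grid_truth():
    """Clean RAS−-style phantom: straight, parallel, evenly spaced ISVs."""
    params = sv.PhenotypeParams(n_isv=6, rng_seed=0)
    return sv.generate_network(params)


@pytest.fixture(scope="session")
def ras_plus_truth():
    params = sv.PhenotypeParams(
        n_isv=6, axis_bend_sigma_deg=7.5, wiggle_amplitude_px=2.5,
        wiggle_period_px=45.0, n_hyperbranches=5, perfused_fraction=0.4,
        rng_seed=7,
    )
    return sv.generate_network(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
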