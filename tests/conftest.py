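import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sulfidogen import bioenergetics, geochemistry, simulate, stoichiometry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def thermo_table():
    return bioenergetics.load_thermo_table()


@pytest.fixture(scope="session")
def reactions(thermo_table):
    return bioenergetics.load_reactions(table=thermo_table)


@pytest.fixture(scope="session")
def start_conditions():
    return bioenergetics.load_conditions()["microcosm_start"]


@pytest.fixture(scope="session")
def half_reactions():
    return stoichiometry.half_reaction_registry()


@pytest.fixture(scope="session")
def minerals():
    return geochemistry.load_minerals()


@pytest.fixture(scope="session")
def treatments():
    return simulate.default_treatments()


@pytest.fixture()
def noiseless_params():
    p = simulate.SimParams(
        qmax_mM_d=0.4, f_sulfate=1.0, lag_mean_d=13.0, inoculum_spread=0.0
    )
    p.noise_sigma = {k: 0.0 for k in p.noise_sigma}
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
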