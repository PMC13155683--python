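import numpy as np
import pytest

import repeco as rp


@pytest.fixture(scope="session")
def table1():
    """Ten-species pure-S study community."""
    return rp.table1_fixture()


@pytest.fixture(scope="session")
def table1_e():
    """Study community with species 3 made exponential (a = 0)."""
    return rp.table1_fixture(exponential_species_3=True)


@pytest.fixture(scope="session")
def env():
    """Reference environment of the worked example: m = 2, r = 1."""
    return rp.MassEnvironment(m=2.0, r=1.0)


def random_community(rng, n_max=10, n_min=2):
    """Random pure-S community drawn from the discrete rate grids."""
    n = int(rng.integers(n_min, n_max + 1))
    a_vals = np.linspace(50.0, 100.0, 21)
    b_vals = np.linspace(5.0, 10.0, 21)
    c_vals = np.linspace(1.0, 5.0, 21)
    return [
        rp.SpeciesKinetics(
            a=float(rng.choice(a_vals)),
            b=float(rng.choice(b_vals)),
            c=float(rng.choice(c_vals)),
            label=str(i + 1),
        )
        for i in range(n)
    ]


def random_environment(rng):
    m = float(np.exp(rng.uniform(np.log(0.1), np.log(10.0))))
    r = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
    return rp.MassEnvironment(m=m, r=r)


def integrate_mass(kins, env, x0=1.0e-3, **kw):
    """Integrate the mass-regulated model from the default dilute start."""
    n = len(kins)
    model = rp.MassRegulatedModel(kins, env)
    state0 = rp.CommunityState(np.full(n, x0), np.zeros(n))
    return rp.integrate(model, state0, **kw)
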