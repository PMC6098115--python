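import numpy as np
import pytest

from linmap.fixtures import load_fixture
from linmap.networks import build_nonlinear_network
from linmap.ssa import ssa_simulate

#: snapshot times used for the time-dependent comparisons
SNAPSHOTS = (1.0, 5.0, 10.0, 20.0)


@pytest.fixture(scope="session")
def fig2_ssa():
    """20k-realization SSA snapshots for the four time-dependent loop variants.

    Shared across tests: the Gillespie runs dominate the suite's runtime.
    """
    out = {}
    for i, name in enumerate(("fig2-loop", "fig2-burst", "fig2-coop", "fig2-osc")):
        spec = load_fixture(name)
        out[name] = ssa_simulate(
            build_nonlinear_network(spec), SNAPSHOTS, 20_000, seed=20_001 + i
        )
    return out


@pytest.fixture(scope="session")
def point_a():
    return load_fixture("fig1-pointA")


@pytest.fixture(scope="session")
def point_b():
    return load_fixture("fig1-pointB")


def poisson_pmf(lam, N):
    from scipy.stats import poisson

    from linmap.pmf import DiscretePMF

    p = poisson.pmf(np.arange(N + 1), lam)
    return DiscretePMF(p / p.sum(), tail_mass=1 - p.sum())
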