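import numpy as np
import pytest

from biofilmosc import ParameterSet, simulate


@pytest.fixture(scope="session")
def table1() -> ParameterSet:
    """Reference parameterization of the biofilm oscillator."""
    return ParameterSet()


@pytest.fixture(scope="session")
def cycle_traj(table1):
    """Standard oscillatory run: 35 h from (1,1,1) on the 0.025 h grid."""
    return simulate(table1, (1.0, 1.0, 1.0), t_end=35.0)


@pytest.fixture(scope="session")
def attractor_traj(table1):
    """Long run whose tail is converged onto the limit cycle."""
    return simulate(table1, (1.0, 1.0, 1.0), t_end=60.0)


@pytest.fixture(scope="session")
def ntss(table1):
    from biofilmosc.model import ntss_concentrations

    return ntss_concentrations(table1)


def random_physical_params(rng: np.random.Generator) -> ParameterSet:
    """A random parameter set whose non-trivial state is physical (k1*G_E > k4)."""
    while True:
        p = ParameterSet(
            k1=rng.uniform(0.05, 1.0),
            k2=rng.uniform(0.5, 10.0),
            k3=rng.uniform(0.5, 8.0),
            k4=rng.uniform(0.5, 5.0),
            k5=rng.uniform(0.5, 8.0),
            G_E=rng.uniform(1.0, 50.0),
            b=rng.uniform(0.01, 1.0),
        )
        if p.k > 1e-3:
            return p
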