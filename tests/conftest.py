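import numpy as np
import pytest

from vesselheal import VesselModel, default_registry
from vesselheal.constitutive import (
    DepositionStretches,
    FiberFamily,
    MixtureState,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def small_vessel(registry):
    """Homeostatic vessel on a coarse grid, equilibrated."""
    m = VesselModel.homeostatic(registry, n_theta=8, n_r=2)
    m.solve_equilibrium()
    return m


@pytest.fixture()
def hom_deposition(registry):
    return DepositionStretches(g_circ=1.0, g_ax=registry.g_ax, g_coll=registry.g_coll)


def make_random_state(rng: np.random.Generator, n_cohorts: int = 3) -> tuple:
    """Random but physically admissible mixture state and deposition
    stretches, for stress/energy consistency sweeps."""
    fam1 = FiberFamily(
        sign=1,
        tau=np.arange(n_cohorts),
        m=rng.uniform(0.01, 0.2, n_cohorts),
        q=rng.uniform(0.5, 1.0, n_cohorts),
        fdep_t=rng.uniform(0.9, 1.1, n_cohorts),
        fdep_z=rng.uniform(0.9, 1.1, n_cohorts),
        delta_zeta=np.zeros(n_cohorts),
    )
    fam2 = fam1.copy()
    fam2.sign = -1
    state = MixtureState(
        rho_elas=0.35,
        rho_csmc=0.30,
        rho_ssmc=0.05,
        families=[fam1, fam2],
        n_attached=0.6,
        n3=0.14,
        u_rs=float(rng.uniform(-0.3, 0.8)),
    )
    dep = DepositionStretches(
        g_circ=float(rng.uniform(0.7, 1.3)), g_ax=1.67, g_coll=1.1
    )
    return state, dep
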