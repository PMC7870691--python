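import math

import numpy as np
import pytest

from vesselheal.constitutive import (
    CohortRecord,
    DepositionStretches,
    FiberFamily,
    InvalidKinematicsError,
    Kinematics,
    MixtureState,
    StateCorruptionError,
    cauchy_stress,
    collagen_fiber_stress,
    homeostatic_fiber_stress,
    mixture_energy,
    mixture_stress_dev,
    psi_active,
    psi_collagen_fiber,
    psi_elastin,
)
from vesselheal.parameters import PassiveParams

from conftest import make_random_state


def _tensor_collagen_energy(F, Fdep, p, g, sign):
    """Independent oracle: evaluate the dispersed-fiber energy by
    explicit 3x3 tensor algebra instead of the closed forms."""
    c, s = math.cos(p.alpha), math.sin(p.alpha)
    M = np.array([0.0, c, sign * s])
    MM = np.outer(M, M)
    G = g * MM + (np.eye(3) - MM) / math.sqrt(g)
    Fc = F @ np.linalg.inv(Fdep) @ G
    C = Fc.T @ Fc
    I1 = np.trace(C)
    I4 = M @ (C @ M)
    E = p.kappa * I1 + (1 - 3 * p.kappa) * I4 - 1
    return p.k1 / (2 * p.k2) * (math.exp(p.k2 * E**2) - 1)


class TestElastin:
    def test_undeformed_identity_is_zero(self):
        p = PassiveParams()
        dep = DepositionStretches(g_circ=1.0, g_ax=1.0, g_coll=1.0)
        assert psi_elastin(Kinematics(1.0, 1.0), dep, p) == 0.0

    def test_deposition_stretch_hand_value(self):
        # G_elas = diag(1/(1.2*1.67), 1.2, 1.67) at F = I
        p = PassiveParams()
        dep = DepositionStretches(g_circ=1.2, g_ax=1.67)
        i1 = (1 / (1.2 * 1.67)) ** 2 + 1.2**2 + 1.67**2
        assert psi_elastin(Kinematics(1.0, 1.0), dep, p) == pytest.approx(
            0.04 * (i1 - 3), rel=1e-12
        )

    def test_invalid_kinematics_rejected(self):
        with pytest.raises(InvalidKinematicsError):
            Kinematics(-1.0, 1.0)


class TestCollagen:
    def test_no_deposition_stretch_no_dispersion_is_zero(self):
        p = PassiveParams(kappa=0.0)
        dep = DepositionStretches(g_circ=1.0, g_coll=1.0)
        cohort = CohortRecord(tau=0, m_dep=1.0)
        assert psi_collagen_fiber(Kinematics(1.0, 1.0), cohort, dep, p) == pytest.approx(0.0)

    @pytest.mark.parametrize("f_t,f_z,fdep_t,fdep_z", [
        (1.0, 1.0, 1.0, 1.0),
        (1.15, 0.95, 1.0, 1.0),
        (1.05, 1.0, 1.02, 0.99),
        (0.9, 1.1, 1.0, 1.0),   # circumferential compression still contributes
    ])
    def test_matches_tensor_oracle(self, f_t, f_z, fdep_t, fdep_z):
        p = PassiveParams()
        dep = DepositionStretches(g_circ=1.0, g_coll=1.1)
        cohort = CohortRecord(tau=0, m_dep=1.0, fdep_t=fdep_t, fdep_z=fdep_z)
        got = psi_collagen_fiber(Kinematics(f_t, f_z), cohort, dep, p)
        F = np.diag([1 / (f_t * f_z), f_t, f_z])
        Fd = np.diag([1 / (fdep_t * fdep_z), fdep_t, fdep_z])
        want = _tensor_collagen_energy(F, Fd, p, 1.1, +1)
        assert got == pytest.approx(want, rel=1e-10)
        # the -alpha family responds identically under diagonal kinematics
        assert got == pytest.approx(_tensor_collagen_energy(F, Fd, p, 1.1, -1), rel=1e-10)

    def test_steady_state_depends_only_on_deposition_stretch(self):
        p = PassiveParams()
        dep = DepositionStretches(g_circ=1.0, g_coll=1.1)
        vals = []
        for f in (1.0, 1.1, 0.95):
            cohort = CohortRecord(tau=0, m_dep=1.0, fdep_t=f, fdep_z=1.0)
            vals.append(psi_collagen_fiber(Kinematics(f, 1.0), cohort, dep, p))
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[0] == pytest.approx(vals[2], rel=1e-12)

    def test_deposition_tensors_are_isochoric(self):
        dep = DepositionStretches(g_circ=0.9, g_ax=1.67, g_coll=1.1)
        assert np.linalg.det(dep.G_elas) == pytest.approx(1.0, rel=1e-12)
        M = np.array([0.0, math.cos(math.pi / 8), math.sin(math.pi / 8)])
        assert np.linalg.det(dep.G_coll(M)) == pytest.approx(1.0, rel=1e-12)


class TestActive:
    def test_zero_when_detached_or_reference(self):
        assert psi_active(1.21, 0.0, -0.1, 0.42) == 0.0
        assert psi_active(1.0, 0.5, 0.0, 0.42) == 0.0

    def test_hand_value(self):
        assert psi_active(1.21, 0.5, -0.1, 0.42) == pytest.approx(1.2705e-3, rel=1e-10)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(StateCorruptionError):
            psi_active(1.0, 1.5, 0.0, 0.42)


class TestMixture:
    def test_energy_linear_in_densities(self, registry):
        rng = np.random.default_rng(0)
        state, dep = make_random_state(rng)
        kin = Kinematics(1.1, 0.97)
        w1 = mixture_energy(state, kin, dep, registry)
        doubled = state.copy()
        doubled.rho_elas *= 2
        doubled.rho_csmc *= 2
        doubled.rho_ssmc *= 2
        for fam in doubled.families:
            fam.m = fam.m * 2
        assert mixture_energy(doubled, kin, dep, registry) == pytest.approx(2 * w1, rel=1e-12)

    def test_all_zero_densities_zero_energy(self, registry):
        state = MixtureState(
            rho_elas=0.0, rho_csmc=0.0, rho_ssmc=0.0,
            families=[FiberFamily.initial(1, 0.0), FiberFamily.initial(-1, 0.0)],
        )
        assert mixture_energy(state, Kinematics(1.2, 0.9),
                              DepositionStretches(g_circ=1.1), registry) == 0.0

    def test_negative_density_rejected(self, registry):
        state = MixtureState(
            rho_elas=-0.1, rho_csmc=0.3, rho_ssmc=0.05,
            families=[FiberFamily.initial(1, 0.15), FiberFamily.initial(-1, 0.15)],
        )
        with pytest.raises(StateCorruptionError):
            mixture_energy(state, Kinematics(1.0, 1.0),
                           DepositionStretches(g_circ=1.0), registry)

    def test_stress_matches_energy_finite_difference(self, registry):
        """Analytic principal stresses agree with central differences of
        the mixture energy under incompressible perturbations."""
        rng = np.random.default_rng(42)
        eps = 1e-6
        worst = 0.0
        for _ in range(100):
            state, dep = make_random_state(rng)
            f_t, f_z = rng.uniform(0.8, 1.3, 2)
            sig = mixture_stress_dev(state, Kinematics(f_t, f_z), dep, registry)

            def W(a, b):
                return mixture_energy(state, Kinematics(a, b), dep, registry)

            fd_t = (W(f_t * (1 + eps), f_z) - W(f_t * (1 - eps), f_z)) / (2 * eps)
            fd_z = (W(f_t, f_z * (1 + eps)) - W(f_t, f_z * (1 - eps))) / (2 * eps)
            worst = max(
                worst,
                abs(sig[1] - sig[0] - fd_t) / max(abs(fd_t), 1e-8),
                abs(sig[2] - sig[0] - fd_z) / max(abs(fd_z), 1e-8),
            )
        assert worst < 1e-5

    def test_cauchy_stress_radial_condition_and_symmetry(self, registry):
        rng = np.random.default_rng(3)
        state, dep = make_random_state(rng)
        sig = cauchy_stress(state, Kinematics(1.1, 1.0), dep, registry)
        assert sig[0, 0] == 0.0
        assert np.allclose(sig, sig.T)

    def test_cohort_steady_state_collapse(self, registry):
        """When every cohort was deposited at the current deformation the
        collagen stress equals the single-cohort value scaled by total
        density, independent of the deposition history."""
        p = registry.passive
        dep = DepositionStretches(g_circ=1.0, g_coll=1.1)
        f_t, f_z = 1.08, 0.97
        many = FiberFamily(
            sign=1, tau=np.arange(5), m=np.full(5, 0.03), q=np.ones(5),
            fdep_t=np.full(5, f_t), fdep_z=np.full(5, f_z), delta_zeta=np.zeros(5),
        )
        one = FiberFamily(
            sign=1, tau=np.array([0]), m=np.array([0.15]), q=np.array([1.0]),
            fdep_t=np.array([f_t]), fdep_z=np.array([f_z]), delta_zeta=np.array([0.0]),
        )
        st_many = MixtureState(rho_elas=0.0, rho_csmc=0.0, rho_ssmc=0.0, families=[many])
        st_one = MixtureState(rho_elas=0.0, rho_csmc=0.0, rho_ssmc=0.0, families=[one])
        kin = Kinematics(f_t, f_z)
        assert np.allclose(
            mixture_stress_dev(st_many, kin, dep, registry),
            mixture_stress_dev(st_one, kin, dep, registry),
            rtol=1e-12,
        )


class TestFiberStress:
    def test_homeostatic_set_point_positive(self, hom_deposition, registry):
        assert homeostatic_fiber_stress(hom_deposition, registry.passive) > 0

    def test_overstretch_raises_fiber_stress(self, hom_deposition, registry):
        fam = FiberFamily.initial(1, 1.0)
        s_hom = homeostatic_fiber_stress(hom_deposition, registry.passive)
        s_hi = collagen_fiber_stress(1.2, 1.0, fam, hom_deposition, registry.passive)[0]
        s_lo = collagen_fiber_stress(0.95, 1.0, fam, hom_deposition, registry.passive)[0]
        assert s_hi > s_hom > s_lo
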