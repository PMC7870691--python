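"""Constrained-mixture constitutive model of the arterial wall.

The wall is an elastin / collagen / smooth-muscle mixture in which all
constituents deform together but each carries its own stress-free
deposition state:

* elastin — Neo-Hookean, deposited once with a fixed deposition stretch
  tensor ``G_elas`` (axial entry prescribed, circumferential entry solved
  by the homeostatic prestress balance, radial entry from
  incompressibility);
* collagen — two symmetric dispersed fiber families (GOH form), laid
  down in cohorts; every cohort remembers the mixture deformation at its
  deposition and is prestretched by ``g_coll`` along its fiber axis;
* contractile smooth muscle — an active energy quadratic in the
  circumferential filament overlap stretch, weighted by the attached
  crossbridge fraction (see :mod:`vesselheal.contractility`).

The reduced vessel keeps the mixture deformation gradient diagonal in the
local (radial, circumferential, axial) frame and fully incompressible
(J = 1 at all times; volume change from mass turnover is neglected).  The
deviatoric J^(-2/3) weights of the invariants are therefore identically
one and are dropped from the implementation.  All energies are MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterRegistry, PassiveParams

__all__ = [
    "Kinematics",
    "DepositionStretches",
    "CohortRecord",
    "FiberFamily",
    "MixtureState",
    "InvalidKinematicsError",
    "StateCorruptionError",
    "psi_elastin",
    "psi_collagen_fiber",
    "psi_active",
    "mixture_energy",
    "mixture_stress_dev",
    "cauchy_stress",
    "collagen_family_response",
    "collagen_fiber_stress",
    "homeostatic_fiber_stress",
]


class InvalidKinematicsError(ValueError):
    """Non-positive or non-physical stretch state."""


class StateCorruptionError(ValueError):
    """Mixture state violates a basic invariant (e.g. negative density)."""


@dataclass(frozen=True)
class Kinematics:
    """Diagonal, incompressible mixture deformation relative to the
    homeostatic reference: F = diag(1/(f_t f_z), f_t, f_z)."""

    f_t: float = 1.0
    f_z: float = 1.0

    def __post_init__(self) -> None:
        if self.f_t <= 0.0 or self.f_z <= 0.0:
            raise InvalidKinematicsError(
                f"stretches must be positive, got f_t={self.f_t}, f_z={self.f_z}"
            )

    @property
    def f_r(self) -> float:
        return 1.0 / (self.f_t * self.f_z)

    @property
    def F(self) -> np.ndarray:
        return np.diag([self.f_r, self.f_t, self.f_z])

    @property
    def J(self) -> float:
        return 1.0

    @property
    def lambda_tt(self) -> float:
        return self.f_t


@dataclass(frozen=True)
class DepositionStretches:
    """Deposition stretches of elastin and collagen.

    g_circ is the circumferential elastin deposition stretch solved by
    the homeostatic balance; g_ax is prescribed; the radial entry follows
    from det(G_elas) = 1.  g_coll prestretches every collagen cohort
    along its fiber axis, with 1/sqrt(g_coll) transversely so that
    det(G_coll) = 1.
    """

    g_circ: float
    g_ax: float = 1.67
    g_coll: float = 1.1

    def __post_init__(self) -> None:
        if self.g_circ <= 0 or self.g_ax <= 0:
            raise InvalidKinematicsError("elastin deposition stretches must be positive")
        if self.g_coll < 1.0:
            raise InvalidKinematicsError("collagen deposition stretch must be >= 1")

    @property
    def g_rad(self) -> float:
        return 1.0 / (self.g_circ * self.g_ax)

    @property
    def G_elas(self) -> np.ndarray:
        return np.diag([self.g_rad, self.g_circ, self.g_ax])

    def G_coll(self, M: np.ndarray) -> np.ndarray:
        M = np.asarray(M, dtype=float)
        MM = np.outer(M, M)
        return self.g_coll * MM + (np.eye(3) - MM) / math.sqrt(self.g_coll)


@dataclass
class CohortRecord:
    """One collagen cohort: deposition step tau (day index), deposited
    mass m_dep (referential density units), survival fraction q, and the
    mixture stretches (f_t, f_z) at deposition."""

    tau: int
    m_dep: float
    q: float = 1.0
    fdep_t: float = 1.0
    fdep_z: float = 1.0
    delta_zeta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise StateCorruptionError("survival fraction must lie in [0, 1]")
        if self.m_dep < 0.0:
            raise StateCorruptionError("cohort mass must be non-negative")


@dataclass
class FiberFamily:
    """Cohort ledger of one collagen fiber family (vectorized).

    ``sign`` selects the +alpha or -alpha family; under the diagonal
    kinematics of the reduced vessel both families respond identically,
    but both are carried so that the ledger mirrors the two-family
    mixture.
    """

    sign: int = 1
    tau: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    m: np.ndarray = field(default_factory=lambda: np.zeros(0))
    q: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fdep_t: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fdep_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    delta_zeta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def initial(cls, sign: int, mass: float) -> "FiberFamily":
        """Single homeostatic cohort at tau = 0 deposited at F = I."""
        return cls(
            sign=sign,
            tau=np.array([0]),
            m=np.array([mass]),
            q=np.array([1.0]),
            fdep_t=np.array([1.0]),
            fdep_z=np.array([1.0]),
            delta_zeta=np.array([0.0]),
        )

    @property
    def density(self) -> float:
        return float(np.sum(self.m * self.q))

    def deposit(self, tau: int, mass: float, f_t: float, f_z: float) -> None:
        self.tau = np.append(self.tau, tau)
        self.m = np.append(self.m, mass)
        self.q = np.append(self.q, 1.0)
        self.fdep_t = np.append(self.fdep_t, f_t)
        self.fdep_z = np.append(self.fdep_z, f_z)
        self.delta_zeta = np.append(self.delta_zeta, 0.0)

    def prune(self, tol: float = 1e-10) -> None:
        """Drop cohorts whose surviving mass is numerically negligible."""
        keep = self.m * self.q >= tol
        if not keep.all():
            for name in ("tau", "m", "q", "fdep_t", "fdep_z", "delta_zeta"):
                setattr(self, name, getattr(self, name)[keep])

    def records(self) -> list[CohortRecord]:
        return [
            CohortRecord(int(t), float(m), float(q), float(ft), float(fz), float(dz))
            for t, m, q, ft, fz, dz in zip(
                self.tau, self.m, self.q, self.fdep_t, self.fdep_z, self.delta_zeta
            )
        ]

    def copy(self) -> "FiberFamily":
        return FiberFamily(
            sign=self.sign, tau=self.tau.copy(), m=self.m.copy(), q=self.q.copy(),
            fdep_t=self.fdep_t.copy(), fdep_z=self.fdep_z.copy(),
            delta_zeta=self.delta_zeta.copy(),
        )


@dataclass
class MixtureState:
    """Full mixture state at one material point."""

    rho_elas: float
    rho_csmc: float
    rho_ssmc: float
    families: list[FiberFamily]
    beta_hist: float = 0.0
    d_csmc: float = 0.0
    d_coll: float = 0.0
    n_attached: float = 0.0  # n3 + n4 of the local filament population
    n3: float = 0.0
    u_rs: float = 0.0

    @property
    def rho_coll_total(self) -> float:
        return sum(f.density for f in self.families)

    def check(self) -> None:
        if min(self.rho_elas, self.rho_csmc, self.rho_ssmc) < 0:
            raise StateCorruptionError("negative constituent density")
        if not 0.0 <= self.d_csmc <= 1.0 or not 0.0 <= self.d_coll <= 1.0:
            raise StateCorruptionError("damage fraction outside [0, 1]")

    def copy(self) -> "MixtureState":
        return MixtureState(
            rho_elas=self.rho_elas, rho_csmc=self.rho_csmc, rho_ssmc=self.rho_ssmc,
            families=[f.copy() for f in self.families],
            beta_hist=self.beta_hist, d_csmc=self.d_csmc, d_coll=self.d_coll,
            n_attached=self.n_attached, n3=self.n3, u_rs=self.u_rs,
        )


# ---------------------------------------------------------------------------
# strain energies
# ---------------------------------------------------------------------------

def psi_elastin(kin: Kinematics, dep: DepositionStretches, p: PassiveParams) -> float:
    """Neo-Hookean elastin energy density C10 (I1_elas - 3) in MPa."""
    lr = kin.f_r * dep.g_rad
    lt = kin.f_t * dep.g_circ
    lz = kin.f_z * dep.g_ax
    return p.C10 * (lr * lr + lt * lt + lz * lz - 3.0)


def _family_constants(p: PassiveParams, g: float) -> tuple[float, float, float, float]:
    """Geometry constants of one fiber family (independent of the sign of
    alpha under diagonal kinematics)."""
    c2 = math.cos(p.alpha) ** 2
    s2 = 1.0 - c2
    B_t = g * g * c2 + s2 / g
    B_z = g * g * s2 + c2 / g
    return c2, s2, B_t, B_z


def collagen_family_response(
    f_t: float,
    f_z: float,
    fdep_t: np.ndarray,
    fdep_z: np.ndarray,
    dep: DepositionStretches,
    p: PassiveParams,
):
    """Vectorized invariants and energy of collagen cohorts of one family.

    Returns (psi, dpsi_dE, I1, I4, a_r, a_t, a_z) as arrays over cohorts,
    where E = kappa*I1 + (1-3 kappa)*I4 - 1 is the dispersion-weighted
    Green-Lagrange-like fiber strain measure.
    """
    g = dep.g_coll
    c2, s2, B_t, B_z = _family_constants(p, g)
    fdep_t = np.asarray(fdep_t, dtype=float)
    fdep_z = np.asarray(fdep_z, dtype=float)
    a_t = f_t / fdep_t
    a_z = f_z / fdep_z
    f_r = 1.0 / (f_t * f_z)
    a_r = f_r * fdep_t * fdep_z
    I1 = a_r * a_r / g + a_t * a_t * B_t + a_z * a_z * B_z
    I4 = g * g * (a_t * a_t * c2 + a_z * a_z * s2)
    E = p.kappa * I1 + (1.0 - 3.0 * p.kappa) * I4 - 1.0
    expo = np.exp(p.k2 * E * E)
    psi = p.k1 / (2.0 * p.k2) * (expo - 1.0)
    dpsi_dE = p.k1 * E * expo
    return psi, dpsi_dE, I1, I4, a_r, a_t, a_z


def psi_collagen_fiber(
    kin: Kinematics,
    cohort: CohortRecord,
    dep: DepositionStretches,
    p: PassiveParams,
    M=None,
) -> float:
    """GOH energy density (MPa) of a single collagen cohort.

    The fiber direction ``M`` only matters through its angle with the
    circumferential axis; both symmetric families give the same value
    under diagonal kinematics.  No tension-compression switch is applied:
    the energy is even in E and contributes for E < 0 as well.
    """
    psi, *_ = collagen_family_response(
        kin.f_t, kin.f_z, np.array([cohort.fdep_t]), np.array([cohort.fdep_z]), dep, p
    )
    return float(psi[0])


def psi_active(I4_smc: float, n_attached: float, u_rs: float, mu: float) -> float:
    """Active SMC energy density (mu/2) (n3+n4) (I4 + u_rs - 1)^2 in MPa."""
    if not 0.0 <= n_attached <= 1.0:
        raise StateCorruptionError("attached filament fraction must lie in [0, 1]")
    x = I4_smc + u_rs - 1.0
    return 0.5 * mu * n_attached * x * x


# ---------------------------------------------------------------------------
# mixture energy and stress
# ---------------------------------------------------------------------------

def mixture_energy(
    state: MixtureState,
    kin: Kinematics,
    dep: DepositionStretches,
    params: ParameterRegistry,
    include_active: bool = True,
) -> float:
    """Mass-averaged mixture energy density (MPa)."""
    state.check()
    w = state.rho_elas * psi_elastin(kin, dep, params.passive)
    for fam in state.families:
        psi, *_ = collagen_family_response(
            kin.f_t, kin.f_z, fam.fdep_t, fam.fdep_z, dep, params.passive
        )
        w += float(np.sum(fam.m * fam.q * psi))
    if include_active:
        I4 = kin.f_t * kin.f_t
        w += state.rho_csmc * psi_active(I4, state.n_attached, state.u_rs, params.smc.mu)
    return w


def mixture_stress_dev(
    state: MixtureState,
    kin: Kinematics,
    dep: DepositionStretches,
    params: ParameterRegistry,
    include_active: bool = True,
) -> np.ndarray:
    """Principal components f_i dPsi/df_i of the extra (deviatoric-like)
    Cauchy stress in the (r, t, z) frame, before the incompressibility
    pressure is subtracted.  Analytic; MPa."""
    state.check()
    p = params.passive
    f_r, f_t, f_z = kin.f_r, kin.f_t, kin.f_z

    lr = f_r * dep.g_rad
    lt = f_t * dep.g_circ
    lz = f_z * dep.g_ax
    sig = state.rho_elas * 2.0 * p.C10 * np.array([lr * lr, lt * lt, lz * lz])

    g = dep.g_coll
    c2, s2, B_t, B_z = _family_constants(p, g)
    for fam in state.families:
        _, dpsi_dE, _, _, a_r, a_t, a_z = collagen_family_response(
            f_t, f_z, fam.fdep_t, fam.fdep_z, dep, p
        )
        wq = fam.m * fam.q * dpsi_dE
        kap, aniso = p.kappa, 1.0 - 3.0 * p.kappa
        sig[0] += 2.0 * float(np.sum(wq * kap * a_r * a_r / g))
        sig[1] += 2.0 * float(
            np.sum(wq * (kap * B_t + aniso * g * g * c2) * a_t * a_t)
        )
        sig[2] += 2.0 * float(
            np.sum(wq * (kap * B_z + aniso * g * g * s2) * a_z * a_z)
        )

    if include_active and state.rho_csmc > 0.0 and state.n_attached > 0.0:
        I4 = f_t * f_t
        x = I4 + state.u_rs - 1.0
        sig[1] += state.rho_csmc * 2.0 * params.smc.mu * state.n_attached * x * I4
    return sig


def cauchy_stress(
    state: MixtureState,
    kin: Kinematics,
    dep: DepositionStretches,
    params: ParameterRegistry,
    include_active: bool = True,
) -> np.ndarray:
    """Diagonal Cauchy stress tensor (MPa) with the incompressibility
    pressure fixed by the thin-wall radial condition sigma_rr = 0."""
    sig = mixture_stress_dev(state, kin, dep, params, include_active)
    return np.diag(sig - sig[0])


def collagen_fiber_stress(
    f_t: float,
    f_z: float,
    fam: FiberFamily,
    dep: DepositionStretches,
    p: PassiveParams,
) -> np.ndarray:
    """Cauchy stress resolved along the deformed fiber direction, per
    cohort of one family (array, MPa, per unit cohort density).

    sigma_ff = m . sigma m with m the deformed unit fiber vector; used as
    the stress whose deviation from its homeostatic value drives collagen
    degradation and acute overload damage.
    """
    g = dep.g_coll
    c2, s2, _, _ = _family_constants(p, g)
    _, dpsi_dE, _, I4, a_r, a_t, a_z = collagen_family_response(
        f_t, f_z, fam.fdep_t, fam.fdep_z, dep, p
    )
    # G_coll^2 entries in the theta-z plane
    G2_tt = g * g * c2 + s2 / g
    G2_zz = g * g * s2 + c2 / g
    G2_tz = math.sqrt(c2 * s2) * (g * g - 1.0 / g)
    # f = F_coll M = g (0, a_t c, a_z s); fBf = f . (A G^2 A) f
    fBf = (g * g) * (
        a_t ** 4 * c2 * G2_tt
        + 2.0 * a_t ** 2 * a_z ** 2 * math.sqrt(c2 * s2) * G2_tz
        + a_z ** 4 * s2 * G2_zz
    )
    kap, aniso = p.kappa, 1.0 - 3.0 * p.kappa
    return 2.0 * dpsi_dE * (kap * fBf / I4 + aniso * I4)


def homeostatic_fiber_stress(dep: DepositionStretches, p: PassiveParams) -> float:
    """Fiber stress of a cohort evaluated at its own deposition state
    (F = F_dep), i.e. the homeostatic set point of the degradation law."""
    fam = FiberFamily.initial(sign=1, mass=1.0)
    return float(collagen_fiber_stress(1.0, 1.0, fam, dep, p)[0])
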