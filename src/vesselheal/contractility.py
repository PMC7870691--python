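"""Vasoactive-agent-dependent smooth muscle contraction.

Pipeline: bath concentrations of phenylephrine (PE, constrictor),
acetylcholine (ACh, endothelium-dependent dilator) and nitric oxide (NO,
endothelium-independent dilator, e.g. from SNP) set the intracellular
calcium level; calcium-calmodulin controls the myosin light-chain
phosphorylation rate k1 = k6 and NO additionally speeds dephosphorylation
(k2 = k5).  The four-state Hai–Murphy crossbridge model then yields the
fractions of attached filaments, and a viscous filament-sliding law
converts crossbridge drive into a quasi-static active stress.

State fractions: n1 detached dephosphorylated, n2 detached
phosphorylated, n3 attached phosphorylated (cycling), n4 attached
dephosphorylated (latch).  Kinetic time scale is seconds; the rest of the
simulator operates on the day scale and uses the steady states
(quasi-static separation of scales).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

from .parameters import AgentParams, KineticParams, SMCParams

__all__ = [
    "ChemEnv",
    "FilamentState",
    "hill_response",
    "endothelial_NO",
    "calcium",
    "phosphorylation_rates",
    "chemical_environment",
    "rate_matrix",
    "hai_murphy_step",
    "hai_murphy_steady",
    "sliding_evolution",
    "steady_sliding",
    "active_tone",
]


@dataclass
class FilamentState:
    """Hai–Murphy state fractions plus normalized filament sliding."""

    n: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    u_rs: float = 0.0

    @property
    def n_attached(self) -> float:
        return float(self.n[2] + self.n[3])

    @property
    def n3(self) -> float:
        return float(self.n[2])

    def copy(self) -> "FilamentState":
        return FilamentState(n=self.n.copy(), u_rs=self.u_rs)


@dataclass(frozen=True)
class ChemEnv:
    """Resolved chemical environment of the smooth muscle cells."""

    conc_PE: float
    conc_ACh: float
    conc_NO_applied: float
    conc_NO_ec: float
    R_NO: float
    R_PE: float
    Ca: float
    CaCaM: float
    k1: float
    k2: float

    @property
    def k6(self) -> float:
        return self.k1

    @property
    def k5(self) -> float:
        return self.k2


def hill_response(conc: float, K: float) -> float:
    """Normalized first-order Hill response c/(c+K) in [0, 1)."""
    if conc < 0.0:
        raise ValueError("concentration must be non-negative")
    return conc / (conc + K)


def endothelial_NO(conc_ACh: float, phi_ec: float, agents: AgentParams) -> float:
    """NO concentration (M) released by the endothelium in response to ACh.

    A saturating log-linear fit of measured NO release; the curve is only
    defined above [ACh] = 10^-offset M and is clipped to zero below
    (outside the fitted measurement range).  Release scales linearly with
    the intact endothelial fraction phi_ec: a denuded vessel produces no
    NO regardless of the ACh dose.
    """
    if conc_ACh < 0.0:
        raise ValueError("ACh concentration must be non-negative")
    if phi_ec <= 0.0 or conc_ACh == 0.0:
        return 0.0
    x = math.log10(conc_ACh) + agents.ach_no_offset
    if x <= 0.0:
        if x < -1e-12:
            warnings.warn(
                "ACh concentration below the fitted release range; "
                "endothelial NO clipped to 0",
                stacklevel=2,
            )
        return 0.0
    return phi_ec * agents.ach_no_amplitude * x / (agents.ach_no_shape + x)


def calcium(R_PE: float, R_NO: float, agents: AgentParams) -> float:
    """Intracellular calcium (M): homeostatic level shifted up by PE and
    down by NO, clipped at zero."""
    ca = agents.Ca_hom + agents.alpha_PE * R_PE - agents.alpha_NO * R_NO
    return max(ca, 0.0)


def phosphorylation_rates(Ca: float, R_NO: float, kin: KineticParams) -> tuple[float, float]:
    """(k1 = k6, k2 = k5) in 1/s from calcium and the NO response.

    CaCaM = alpha_Ca * Ca forms the calcium-calmodulin complex; k1
    follows second-order saturation kinetics in CaCaM; NO raises the
    dephosphorylation rate k2 on top of its homeostatic value.
    """
    if Ca < 0.0:
        raise ValueError("calcium concentration must be non-negative")
    cacam = kin.alpha_Ca * Ca
    k1 = cacam * cacam / (cacam * cacam + kin.K_CaCaM * kin.K_CaCaM)
    k2 = kin.k2_hom + kin.alpha2 * R_NO
    return k1, k2


def chemical_environment(
    conc_PE: float,
    conc_ACh: float,
    conc_NO: float,
    phi_ec: float,
    agents: AgentParams,
    kinetics: KineticParams,
) -> ChemEnv:
    """Resolve bath doses into calcium and kinetic rates.

    Applied NO (e.g. SNP-derived) and endothelial, ACh-triggered NO add.
    """
    no_ec = endothelial_NO(conc_ACh, phi_ec, agents)
    no_total = conc_NO + no_ec
    R_NO = hill_response(no_total, agents.K_NO)
    R_PE = hill_response(conc_PE, agents.K_PE)
    Ca = calcium(R_PE, R_NO, agents)
    k1, k2 = phosphorylation_rates(Ca, R_NO, kinetics)
    return ChemEnv(
        conc_PE=conc_PE, conc_ACh=conc_ACh, conc_NO_applied=conc_NO,
        conc_NO_ec=no_ec, R_NO=R_NO, R_PE=R_PE, Ca=Ca,
        CaCaM=kinetics.alpha_Ca * Ca, k1=k1, k2=k2,
    )


def rate_matrix(
    k1: float, k2: float, k3: float, k4: float,
    k5: float, k6: float, k7: float,
) -> np.ndarray:
    """Hai–Murphy transition matrix; column sums vanish so the total
    filament fraction is conserved."""
    return np.array(
        [
            [-k1, k2, 0.0, k7],
            [k1, -(k2 + k3), k4, 0.0],
            [0.0, k3, -(k4 + k5), k6],
            [0.0, 0.0, k5, -(k6 + k7)],
        ]
    )


def _rates_tuple(env: ChemEnv, kin: KineticParams) -> tuple:
    return (env.k1, env.k2, kin.k3, kin.k4, env.k5, env.k6, kin.k7)


def hai_murphy_step(fil: FilamentState, rates, dt_s: float) -> FilamentState:
    """Advance the state fractions by dt_s seconds.

    Uses the exact matrix exponential of the (constant-rate) linear
    system, which is unconditionally stable and conserves the total
    fraction to machine precision regardless of rate stiffness.
    """
    A = rate_matrix(*rates)
    n = expm(A * dt_s) @ fil.n
    return FilamentState(n=n, u_rs=fil.u_rs)


def hai_murphy_steady(rates) -> np.ndarray:
    """Normalized non-negative steady state of the crossbridge kinetics.

    The steady state is the one-dimensional nullspace of the rate matrix.
    If attachment is impossible and the detached states are degenerate
    (multiple stationary directions), the fully detached state n1 = 1 is
    returned with a warning.
    """
    A = rate_matrix(*rates)
    ns = null_space(A)
    if ns.shape[1] != 1:
        warnings.warn(
            "degenerate crossbridge kinetics; returning fully detached state",
            stacklevel=2,
        )
        return np.array([1.0, 0.0, 0.0, 0.0])
    v = ns[:, 0]
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-12):
        warnings.warn(
            "non-physical nullspace sign pattern; returning fully detached state",
            stacklevel=2,
        )
        return np.array([1.0, 0.0, 0.0, 0.0])
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def _p_mat(n3: float, n4: float, I4: float, u_rs: float, mu: float) -> float:
    """Matrix stress felt by the filaments (MPa, cell level)."""
    return mu * (n3 + n4) * (I4 + u_rs - 1.0)


def _p_smc(p_mat: float, n3: float, n4: float, kappa_c: float) -> float:
    """Three-branch crossbridge driving stress (MPa, cell level)."""
    lo, hi = kappa_c * n3, kappa_c * (n3 + n4)
    if p_mat < lo:
        return lo
    if p_mat > hi:
        return hi
    return p_mat


def sliding_evolution(
    fil: FilamentState,
    I4_smc: float,
    smc: SMCParams,
    dt_s: float,
    n_steps: int = 1,
) -> FilamentState:
    """Explicit viscous evolution du/dt = (P_smc - P_mat)/eta of the
    filament sliding at frozen state fractions."""
    n3, n4 = float(fil.n[2]), float(fil.n[3])
    u = fil.u_rs
    for _ in range(n_steps):
        pm = _p_mat(n3, n4, I4_smc, u, smc.mu)
        ps = _p_smc(pm, n3, n4, smc.kappa_c)
        u += dt_s / smc.eta * (ps - pm)
    out = fil.copy()
    out.u_rs = u
    return out


def steady_sliding(fil: FilamentState, I4_smc: float, smc: SMCParams) -> float:
    """Stationary filament sliding at the current deformation.

    If the matrix stress at the inherited sliding already lies between
    the crossbridge bounds kappa_c*n3 and kappa_c*(n3+n4), the sliding
    does not evolve; otherwise it converges to the bound it approaches,
    for which closed forms exist.
    """
    n3, n4 = float(fil.n[2]), float(fil.n[3])
    n34 = n3 + n4
    if n34 <= 0.0:
        return fil.u_rs
    pm = _p_mat(n3, n4, I4_smc, fil.u_rs, smc.mu)
    if pm < smc.kappa_c * n3:
        return smc.kappa_c * n3 / (smc.mu * n34) + 1.0 - I4_smc
    if pm > smc.kappa_c * n34:
        return smc.kappa_c / smc.mu + 1.0 - I4_smc
    return fil.u_rs


def active_tone(
    env: ChemEnv,
    I4_smc: float,
    rho_csmc_rel: float,
    kinetics: KineticParams,
    smc: SMCParams,
    fil: FilamentState | None = None,
) -> tuple[float, FilamentState]:
    """Quasi-static active circumferential stress (MPa).

    Chemistry -> rates -> steady crossbridge fractions -> stationary
    sliding -> matrix stress, scaled by the surviving relative density of
    contractile SMC.  Returns the stress and the updated filament state
    so that dose protocols can be chained.
    """
    if fil is None:
        fil = FilamentState()
        fresh = True
    else:
        fil = fil.copy()
        fresh = False
    n = hai_murphy_steady(_rates_tuple(env, kinetics))
    fil.n = n
    if fresh:
        # no inherited sliding state: start from the fully relaxed
        # configuration so the sliding converges from below
        fil.u_rs = -abs(I4_smc - 1.0) - 1.0
    fil.u_rs = steady_sliding(fil, I4_smc, smc)
    stress = rho_csmc_rel * _p_mat(float(n[2]), float(n[3]), I4_smc, fil.u_rs, smc.mu)
    return stress, fil


def basal_environment(agents: AgentParams, kinetics: KineticParams, phi_ec: float = 1.0) -> ChemEnv:
    """Agent-free bath: homeostatic calcium and rates."""
    return chemical_environment(0.0, 0.0, 0.0, phi_ec, agents, kinetics)
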