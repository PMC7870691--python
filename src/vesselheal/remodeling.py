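"""Day-scale healing: collagen turnover, SMC phenotype switching,
endothelial regrowth and inflammation.

Each remodeling step advances the tissue by ``dt`` days:

1. the mechanical equilibrium of the pressurized vessel is recomputed,
   giving the circumferential stretch deviation ``delta_lambda`` and the
   per-cohort fiber stress deviations ``delta_zeta``;
2. every collagen cohort decays through its survival fraction (faster
   when its fiber stress deviates from homeostasis) and one new cohort
   per family is deposited at the current deformation;
3. contractile SMC dedifferentiate (or redifferentiate) in proportion to
   the stretch deviation, synthetic SMC proliferate with stretch and
   inflammation, exchanging mass conservatively;
4. the endothelium heals logistically and the inflammation level is its
   complement.

Elastin is never produced or degraded.  Two model variants alter the
phenotype law (``no_redifferentiation``) or the collagen production
stimulus (``mech_independent_production``).
"""

from __future__ import annotations

import logging

import numpy as np

from .constitutive import FiberFamily, collagen_fiber_stress
from .parameters import InitialDensities, RemodelParams

__all__ = [
    "cohort_survival_step",
    "delta_zeta",
    "baseline_production_rate",
    "production_stimulus",
    "collagen_production",
    "smc_phenotype_step",
    "endothelium_heal_step",
    "inflammation",
    "remodeling_step",
]

log = logging.getLogger(__name__)


def cohort_survival_step(q, dz, p: RemodelParams):
    """One-step decay of collagen survival fractions.

    q <- q * exp(-K_qh dt (1 + dz^2)): at homeostasis (dz = 0) cohorts
    decay with half-life ln2/K_qh days; stress deviations of either sign
    accelerate degradation quadratically.
    """
    q = np.asarray(q, dtype=float)
    dz = np.asarray(dz, dtype=float)
    return q * np.exp(-p.K_qh * p.dt * (1.0 + dz * dz))


def delta_zeta(sigma_fiber, sigma_fiber_hom: float):
    """Normalized fiber-stress deviation (sigma - sigma_hom)/sigma_hom."""
    if sigma_fiber_hom <= 0.0:
        raise ValueError("homeostatic fiber stress must be positive")
    s = np.asarray(sigma_fiber, dtype=float)
    out = (s - sigma_fiber_hom) / sigma_fiber_hom
    return float(out) if out.ndim == 0 else out


def baseline_production_rate(rho0_family: float, p: RemodelParams) -> float:
    """Baseline collagen deposition rate m0 (density/day) per family.

    Chosen so that homeostasis is exactly stationary under the discrete
    turnover: the mass deposited per step balances the decay of the
    stationary total, m0 dt = rho0 (1 - exp(-K_qh dt)).
    """
    return rho0_family * (1.0 - np.exp(-p.K_qh * p.dt)) / p.dt


def production_stimulus(
    rho_csmc: float,
    rho_ssmc: float,
    delta_lambda: float,
    rho0: InitialDensities,
    p: RemodelParams,
) -> float:
    """Production stimulus Gamma (dimensionless, clamped >= 0).

    Original variant: synthetic cells produce collagen at a rate boosted
    by the stretch deviation sensed by the contractile cells.  Under
    ``mech_independent_production`` only the synthetic cell count
    matters.
    """
    rel_s = rho_ssmc / rho0.ssmc
    if p.variant == "mech_independent_production":
        return max(rel_s, 0.0)
    rel_c = rho_csmc / rho0.csmc
    return max((1.0 + rel_c * p.K_m * delta_lambda) * rel_s, 0.0)


def collagen_production(
    rho_csmc: float,
    rho_ssmc: float,
    delta_lambda: float,
    rho0: InitialDensities,
    p: RemodelParams,
    m0: float,
) -> float:
    """Deposition rate (density/day) of one new cohort: m = m0 Gamma."""
    return m0 * production_stimulus(rho_csmc, rho_ssmc, delta_lambda, rho0, p)


def smc_phenotype_step(
    rho_csmc: float,
    rho_ssmc: float,
    delta_lambda: float,
    phi_ic: float,
    rho_elas_rel: float,
    rho0: InitialDensities,
    p: RemodelParams,
) -> tuple[float, float]:
    """One step of SMC phenotype exchange and proliferation.

    Contractile cells dedifferentiate when stretched (delta_lambda > 0)
    and redifferentiate when compressed; the contractile pool is capped
    by the relative elastin available to grip, and its growth by the
    synthetic cells available to recruit.  Synthetic cells proliferate
    with stretch and with inflammation and receive/supply the exchanged
    mass, which is conserved exactly.

    Under ``no_redifferentiation`` the mechanical trigger only acts for
    delta_lambda >= 0; in compression only inflammation-driven
    proliferation remains.
    """
    if p.variant == "no_redifferentiation" and delta_lambda < 0.0:
        rho_ssmc_new = rho_ssmc * (1.0 + p.K_ic * p.dt * phi_ic)
        return rho_csmc, max(rho_ssmc_new, 0.0)

    growth = rho_ssmc * (delta_lambda * p.K_pl * p.dt + 1.0 + p.K_ic * p.dt * phi_ic)
    if growth < 0.0:
        log.warning("synthetic proliferation factor clipped to zero")
        growth = 0.0

    target = rho_csmc * (1.0 - delta_lambda * p.K_dd * p.dt)
    cap_grip = rho0.csmc * rho_elas_rel
    if target > cap_grip:
        log.debug("contractile pool capped by elastin grip: %.6g -> %.6g", target, cap_grip)
        target = cap_grip
    if target > rho_csmc + growth:
        log.debug("contractile growth capped by available synthetic cells")
        target = rho_csmc + growth
    if target < 0.0:
        log.warning("contractile density clipped to zero (was %.6g)", target)
        target = 0.0

    transferred = rho_csmc - target  # > 0: dedifferentiation into the synthetic pool
    return target, max(growth + transferred, 0.0)


def endothelium_heal_step(phi_ec: float, p: RemodelParams) -> float:
    """Discrete logistic healing phi' = (K_ec dt (1 - phi) + 1) phi.

    Fixed points at 0 (no cells left to regrow from) and 1 (intact); the
    forward-Euler update stays within [0, 1] for K_ec dt <= 1.
    """
    if not 0.0 <= phi_ec <= 1.0:
        raise ValueError("endothelial fraction must lie in [0, 1]")
    return (p.K_ec * p.dt * (1.0 - phi_ec) + 1.0) * phi_ec


def inflammation(phi_ec: float) -> float:
    """Inflammation level as the complement of the intact endothelium."""
    if not 0.0 <= phi_ec <= 1.0:
        raise ValueError("endothelial fraction must lie in [0, 1]")
    return 1.0 - phi_ec


def remodeling_step(model, p: RemodelParams) -> None:
    """Advance a vessel model by one remodeling step of ``p.dt`` days.

    ``model`` provides the reduced-kinematics mechanics: a
    ``solve_equilibrium()`` returning the circumferential stretch of the
    pressurized wall, the material-point states, the deposition
    stretches and the homeostatic fiber stress set point.  Elastin
    densities are left untouched.
    """
    lam = model.solve_equilibrium()
    dlam = lam - 1.0
    f_z = model.lambda_z
    rho0 = model.params.densities
    m0_family = baseline_production_rate(0.5 * rho0.collagen, p)
    tau = model.step_index + 1

    for pt in model.points:
        st = pt.state
        rate = collagen_production(st.rho_csmc, st.rho_ssmc, dlam, rho0, p, m0_family)
        for fam in st.families:
            sig = collagen_fiber_stress(lam, f_z, fam, model.dep, model.params.passive)
            dz = delta_zeta(sig, model.sigma_ff_hom)
            fam.delta_zeta = dz
            fam.q = cohort_survival_step(fam.q, dz, p)
            fam.deposit(tau, rate * p.dt, lam, f_z)
            fam.prune()
        st.rho_csmc, st.rho_ssmc = smc_phenotype_step(
            st.rho_csmc, st.rho_ssmc, dlam, model.phi_ic,
            st.rho_elas / rho0.elastin, rho0, p,
        )

    model.phi_ec = endothelium_heal_step(model.phi_ec, p)
    model.step_index += 1
    model.day += p.dt
    model.delta_lambda = dlam
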