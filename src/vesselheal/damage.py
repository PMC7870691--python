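"""Acute clamp damage to smooth muscle, collagen and endothelium.

Clamping overstretches the wall locally.  The damage drivers are

* ``beta`` — the running maximum over the loading history of the absolute
  circumferential stretch deviation |lambda_tt - 1|, evaluated per
  material point; it kills contractile SMC with an exponential
  saturation law and kills the local endothelium outright above a
  threshold;
* ``delta_zeta`` — the normalized deviation of the collagen fiber stress
  from its homeostatic value; positive (overload) deviations destroy a
  fraction of the collagen cohort mass.

Damage is irreversible: beta only grows, and the density conversion is
applied once at clamp release.
"""

from __future__ import annotations

import numpy as np

from .parameters import DamageParams

__all__ = [
    "update_beta",
    "smc_damage",
    "collagen_damage",
    "endothelium_damage",
]


def update_beta(beta_hist: float, lambda_tt: float) -> float:
    """Running maximum of |lambda_tt - 1| over the loading history."""
    if lambda_tt <= 0.0:
        raise ValueError("circumferential stretch must be positive")
    return max(beta_hist, abs(lambda_tt - 1.0))


def smc_damage(beta, m_csmc: float):
    """Fraction of contractile SMC killed: d = 1 - exp(-beta/m_csmc).

    Accepts scalars or arrays; monotone in beta, in [0, 1).
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0.0):
        raise ValueError("beta must be non-negative")
    d = 1.0 - np.exp(-beta / m_csmc)
    return float(d) if d.ndim == 0 else d


def collagen_damage(delta_zeta, m_coll: float):
    """Fraction of a collagen cohort destroyed by acute overload.

    d = 1 - exp(-delta_zeta/m_coll) for positive stress deviations;
    compressive (negative) deviations cause no damage.
    """
    dz = np.maximum(np.asarray(delta_zeta, dtype=float), 0.0)
    d = 1.0 - np.exp(-dz / m_coll)
    return float(d) if d.ndim == 0 else d


def endothelium_damage(beta_field, m_ec: float) -> float:
    """Surviving global endothelial fraction.

    The endothelium dies wherever the luminal overstretch history exceeds
    the threshold m_ec; since the modeled segment is short, only the
    segment-wide surviving fraction is retained as a single scalar.
    """
    beta_field = np.asarray(beta_field, dtype=float)
    if beta_field.size == 0:
        raise ValueError("empty luminal surface")
    return float(np.mean(beta_field < m_ec))


def apply_damage_params(beta, dz, p: DamageParams):
    """Convenience: (d_csmc, d_coll) from the two drivers."""
    return smc_damage(beta, p.m_csmc), collagen_damage(dz, p.m_coll)
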