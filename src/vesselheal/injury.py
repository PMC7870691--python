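"""Parametric clamp-injury profiles.

The true overstretch field of a clamped artery comes from 3D contact
mechanics and concentrates at the luminal surface near the clamp edges.
The reduced vessel replaces it by a deterministic parametric stand-in:
a Gaussian ridge of stretch-deviation history ``beta`` centered on the
clamp edge angle, decaying exponentially through the wall thickness.
The stretch deviation is tensile (overstretch) within a band around the
clamp edge and compressive elsewhere, reflecting that the flattened
contact zone is compressed circumferentially while the material at the
edge is pulled taut.  The three free parameters (peak beta, angular
width, tension-band half-width) are calibrated once per clamp load so
that the resulting global endothelial survival, overall contractile-SMC
survival and overall collagen survival match the acute post-clamp
state; everything downstream (remodeling, myograph response) follows
from the mechanics without further fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constitutive import DepositionStretches, FiberFamily, collagen_fiber_stress, homeostatic_fiber_stress
from .damage import collagen_damage
from .parameters import ParameterRegistry

__all__ = [
    "InjuryProfile",
    "fixture_beta",
    "calibrate_profile",
    "ACUTE_CASE_TARGETS",
]

# Acute post-clamp survival targets (endothelium fraction, overall
# relative contractile SMC, overall relative collagen) used to pin the
# profile parameters, keyed by clamp load in N per 2 mm clamp length.
ACUTE_CASE_TARGETS: dict[float, tuple[float, float, float]] = {
    0.6: (0.3113, 0.7170, 0.9076),
    1.27: (0.2719, 0.7190, 0.9071),
}

_EDGE_ANGLE = math.pi / 2.0  # clamp edge position on the half cylinder
_RADIAL_DECAY = 0.5          # e-folding depth of the injury, fraction of wall
_N_LUMEN = 4000              # fine luminal sampling for the endothelial count


@dataclass
class InjuryProfile:
    """Per-point stretch-deviation history field on the material grid
    plus a fine luminal trace used for the endothelial survival count.

    ``beta`` is the magnitude |lambda_tt - 1| of the circumferential
    stretch deviation reached during clamping; ``tensile`` marks the
    points where the deviation was an overstretch (lambda_tt = 1 + beta)
    rather than a compression (lambda_tt = 1 - beta).  Only tensile
    deviations damage collagen; beta magnitude drives SMC and
    endothelial loss either way.
    """

    thetas: np.ndarray
    rhats: np.ndarray
    beta: np.ndarray                       # shape (n_theta, n_r)
    tensile: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    luminal_beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    peak: float = 0.0
    width: float = float("nan")
    tension_halfwidth: float = math.pi

    def __post_init__(self) -> None:
        if np.any(self.beta < 0.0):
            raise ValueError("beta must be non-negative")
        if self.tensile.size == 0:
            self.tensile = np.ones_like(self.beta, dtype=bool)
        if self.luminal_beta.size == 0:
            self.luminal_beta = self.beta[:, 0].copy()

    def lambda_clamp(self) -> np.ndarray:
        """Signed circumferential stretch during the clamp hold."""
        lam = np.where(self.tensile, 1.0 + self.beta, 1.0 - self.beta)
        return np.clip(lam, 0.05, None)

    def to_csv(self, path: str | Path) -> None:
        n_t, n_r = self.beta.shape
        tt, rr = np.meshgrid(self.thetas, self.rhats, indexing="ij")
        pd.DataFrame(
            {
                "point_id": np.arange(n_t * n_r),
                "theta": tt.ravel(),
                "rhat": rr.ravel(),
                "beta": self.beta.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "InjuryProfile":
        df = pd.read_csv(path)
        if "beta" not in df.columns:
            raise ValueError(f"{path} has no 'beta' column")
        thetas = np.unique(df["theta"].to_numpy())
        rhats = np.unique(df["rhat"].to_numpy())
        beta = (
            df.sort_values(["theta", "rhat"])["beta"]
            .to_numpy()
            .reshape(thetas.size, rhats.size)
        )
        return cls(thetas=thetas, rhats=rhats, beta=beta)


def _beta_field(thetas, rhats, peak: float, width: float) -> np.ndarray:
    tt, rr = np.meshgrid(thetas, rhats, indexing="ij")
    return peak * np.exp(-(((tt - _EDGE_ANGLE) / width) ** 2)) * np.exp(-rr / _RADIAL_DECAY)


def fixture_beta(
    n_theta: int,
    n_r: int,
    peak: float,
    width: float,
    tension_halfwidth: float = math.pi,
) -> InjuryProfile:
    """Deterministic injury profile on an n_theta x n_r half-cylinder grid.

    The field is maximal at the luminal surface at the clamp-edge angle
    and decays with a Gaussian of angular ``width`` (rad) and an
    exponential through the wall.  Points within ``tension_halfwidth``
    rad of the clamp edge carry a tensile deviation, the rest a
    compressive one.  ``peak = 0`` yields the undamaged control field.
    """
    if peak < 0.0:
        raise ValueError("peak must be non-negative")
    thetas = grid_thetas(n_theta)
    rhats = grid_rhats(n_r)
    width = max(width, 1e-9)
    beta = _beta_field(thetas, rhats, peak, width)
    tt, _ = np.meshgrid(thetas, rhats, indexing="ij")
    tensile = np.abs(tt - _EDGE_ANGLE) <= tension_halfwidth
    lum = peak * np.exp(-(((grid_thetas(_N_LUMEN) - _EDGE_ANGLE) / width) ** 2))
    return InjuryProfile(
        thetas=thetas, rhats=rhats, beta=beta, tensile=tensile, luminal_beta=lum,
        peak=peak, width=width, tension_halfwidth=tension_halfwidth,
    )


def grid_thetas(n_theta: int) -> np.ndarray:
    """Midpoint angular grid on the half cylinder [0, pi]."""
    return (np.arange(n_theta) + 0.5) * math.pi / n_theta


def grid_rhats(n_r: int) -> np.ndarray:
    """Normalized radial positions, 0 = lumen, 1 = outer surface."""
    if n_r == 1:
        return np.array([0.5])
    return np.linspace(0.0, 1.0, n_r)


def _width_for_survival(peak: float, target_phi_ec: float, m_ec: float) -> float:
    """Width such that the luminal arc with beta >= m_ec equals the dead
    endothelial fraction 1 - target_phi_ec."""
    if peak <= m_ec:
        raise ValueError("peak must exceed the endothelial death threshold")
    half_arc = 0.5 * (1.0 - target_phi_ec) * math.pi
    return half_arc / math.sqrt(math.log(peak / m_ec))


def calibrate_profile(
    clamp_load: float,
    params: ParameterRegistry,
    n_theta: int,
    n_r: int,
    targets: tuple[float, float, float] | None = None,
) -> InjuryProfile:
    """Calibrate (peak, width, tension band) so the profile reproduces
    the acute post-clamp survival fractions for this load.

    The calibration is triangular and deterministic: the width is slaved
    to the endothelial survival (the dead arc is the set of luminal
    points above the death threshold); the peak is then solved so the
    grid-averaged SMC survival exp(-beta/m_csmc) hits its target; and
    finally the tension-band half-width is solved so the overall
    collagen survival (homeostatic cohort, overload damage only inside
    the band) matches its target.
    """
    dmg = params.damage
    if targets is None:
        try:
            targets = ACUTE_CASE_TARGETS[clamp_load]
        except KeyError:
            raise ValueError(
                f"no acute calibration targets for clamp load {clamp_load!r} N"
            ) from None
    phi_target, csmc_target, coll_target = targets
    thetas, rhats = grid_thetas(n_theta), grid_rhats(n_r)

    def csmc_survival(peak: float) -> float:
        w = _width_for_survival(peak, phi_target, dmg.m_ec)
        beta = _beta_field(thetas, rhats, peak, w)
        return float(np.mean(np.exp(-beta / dmg.m_csmc)))

    lo, hi = dmg.m_ec * 1.02, 60.0
    if not (csmc_survival(hi) <= csmc_target <= csmc_survival(lo)):
        raise ValueError("SMC survival target outside the reachable profile range")
    peak = brentq(lambda p: csmc_survival(p) - csmc_target, lo, hi, xtol=1e-12)
    width = _width_for_survival(peak, phi_target, dmg.m_ec)

    dep = DepositionStretches(g_circ=1.0, g_ax=params.g_ax, g_coll=params.g_coll)
    sigma_hom = homeostatic_fiber_stress(dep, params.passive)
    beta = _beta_field(thetas, rhats, peak, width)
    lam_tens = np.clip(1.0 + beta, 0.05, None)
    fam = FiberFamily.initial(1, 1.0)
    surv = np.empty_like(beta)
    for i in range(beta.shape[0]):
        for j in range(beta.shape[1]):
            sig = float(collagen_fiber_stress(
                lam_tens[i, j], 1.0, fam, dep, params.passive)[0])
            dz = (sig - sigma_hom) / sigma_hom
            surv[i, j] = 1.0 - collagen_damage(dz, dmg.m_coll)

    tt = np.abs(thetas - _EDGE_ANGLE)[:, None] * np.ones_like(beta)

    def coll_survival(band: float) -> float:
        return float(np.mean(np.where(tt <= band, surv, 1.0)))

    if coll_survival(math.pi) > coll_target:
        raise ValueError("collagen survival target below the reachable range")
    band = brentq(lambda b: coll_survival(b) - coll_target, 0.0, math.pi, xtol=1e-12)
    return fixture_beta(n_theta, n_r, peak, width, tension_halfwidth=band)
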