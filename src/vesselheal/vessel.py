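"""Reduced thin-walled vessel model and the five-step protocol.

A mouse descending thoracic aorta is idealized as a thin-walled half
cylinder (inner diameter 0.65 mm, thickness 0.04 mm) carrying a grid of
material points, each with its own constrained-mixture state.  The
deformation is uniform and diagonal (membrane kinematics); mechanical
equilibrium of the pressurized wall is the Laplace balance
sigma_tt = p r / h, with plane strain axially while pressurized.

The simulation protocol mirrors ex vivo clamping experiments:

1. homeostasis — solve the elastin circumferential deposition stretch so
   the reference geometry is in equilibrium at diastolic pressure;
2. clamp — impose an injury profile and convert the acute damage;
3. heal — daily remodeling with radial-only kinematics at constant
   pressure;
4. excise — release pressure and axial constraint;
5. myograph — mount the ring on two rods, preload, and run the
   vasoactive dose protocol isometrically.

Cases: A0/R0 (0.0 N control), A1/R1 (0.6 N), A2/R2 (1.27 N); "A" is
acute (no healing), "R" is remodeled (healed).  Everything is
deterministic: rerunning a case reproduces its outputs bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from . import remodeling as rm
from .constitutive import (
    DepositionStretches,
    FiberFamily,
    Kinematics,
    MixtureState,
    collagen_fiber_stress,
    homeostatic_fiber_stress,
    mixture_stress_dev,
)
from .contractility import (
    FilamentState,
    basal_environment,
    chemical_environment,
    hai_murphy_steady,
    steady_sliding,
)
from .damage import collagen_damage, endothelium_damage, smc_damage
from .injury import InjuryProfile, calibrate_profile
from .parameters import (
    MyographSetup,
    ParameterRegistry,
    RemodelParams,
    ScenarioConfig,
    config_hash,
    default_registry,
)

__all__ = [
    "MaterialPoint",
    "VesselModel",
    "MyographResult",
    "CaseResult",
    "EquilibriumError",
    "run_case",
]

_EQ_TOL = 1e-8  # MPa, Laplace residual tolerance


class EquilibriumError(RuntimeError):
    """Mechanical equilibrium could not be established."""

    def __init__(self, message: str, diagnostics: dict | None = None) -> None:
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class MaterialPoint:
    theta: float
    rhat: float
    weight: float
    state: MixtureState


@dataclass
class MyographResult:
    """Virtual wire-myograph output: preload gap, the force-displacement
    curve toward preload, and the isometric force per dose stage (N/mm)."""

    gap_preload: float
    displacement: np.ndarray
    force: np.ndarray
    stage_forces: dict[str, float]
    zones: tuple[float, float]  # (d_slack, d_taut): zone boundaries

    @property
    def normalized_force(self) -> np.ndarray:
        fmax = self.force.max()
        return self.force / fmax if fmax > 0 else self.force


@dataclass
class CaseResult:
    case_id: str
    acute_fractions: dict[str, float]
    final_fractions: dict[str, float]
    history: pd.DataFrame
    myograph: MyographResult
    config_hash: str


class VesselModel:
    """Thin-walled vessel carrying the mixture state grid."""

    def __init__(
        self,
        params: ParameterRegistry,
        dep: DepositionStretches,
        points: list[MaterialPoint],
        active_in_balance: bool = False,
    ) -> None:
        self.params = params
        self.geom = params.geometry
        self.dep = dep
        self.points = points
        # whether basal tone enters the in vivo pressure balance; the
        # myograph always includes the active response
        self.active_in_balance = active_in_balance
        self.sigma_ff_hom = homeostatic_fiber_stress(dep, params.passive)
        self.phi_ec = 1.0
        self.lambda_t = 1.0
        self.lambda_z = 1.0
        self.delta_lambda = 0.0
        self.day = 0.0
        self.step_index = 0
        self.pressurized = True
        self.history: list[dict] = []

    # -- construction ------------------------------------------------------

    @classmethod
    def homeostatic(
        cls,
        params: ParameterRegistry | None = None,
        n_theta: int = 48,
        n_r: int = 3,
        active_in_balance: bool = False,
    ) -> "VesselModel":
        """Build the homeostatic vessel (protocol step 1).

        Solves the elastin circumferential deposition stretch so that the
        mixture circumferential stress (passive by default; basal active
        tone optionally included via ``active_in_balance``) at the
        reference geometry equals the Laplace stress p r / h to better
        than 1e-8 MPa.  The axial elastin and collagen deposition
        stretches are prescribed.
        """
        params = params or default_registry()
        rho0 = params.densities

        # basal crossbridge population and stationary sliding at I4 = 1
        env = basal_environment(params.agents, params.kinetics)
        n = hai_murphy_steady((env.k1, env.k2, params.kinetics.k3,
                               params.kinetics.k4, env.k5, env.k6,
                               params.kinetics.k7))
        fil = FilamentState(n=n, u_rs=-1.0)  # start fully unloaded
        u_hom = steady_sliding(fil, 1.0, params.smc)

        def make_state() -> MixtureState:
            return MixtureState(
                rho_elas=rho0.elastin,
                rho_csmc=rho0.csmc,
                rho_ssmc=rho0.ssmc,
                families=[
                    FiberFamily.initial(+1, 0.5 * rho0.collagen),
                    FiberFamily.initial(-1, 0.5 * rho0.collagen),
                ],
                n_attached=float(n[2] + n[3]),
                n3=float(n[2]),
                u_rs=u_hom,
            )

        geom = params.geometry
        target = geom.pressure * geom.inner_radius / geom.thickness
        probe = make_state()

        def residual(g_circ: float) -> float:
            dep = DepositionStretches(g_circ=g_circ, g_ax=params.g_ax, g_coll=params.g_coll)
            sig = mixture_stress_dev(
                probe, Kinematics(1.0, 1.0), dep, params, active_in_balance
            )
            return (sig[1] - sig[0]) - target

        lo, hi = 0.1, 2.5
        if residual(lo) * residual(hi) > 0:
            raise EquilibriumError(
                "no homeostatic elastin deposition stretch in bracket "
                f"[{lo}, {hi}]",
                {"residual_lo": residual(lo), "residual_hi": residual(hi)},
            )
        g_circ = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16)
        dep = DepositionStretches(g_circ=g_circ, g_ax=params.g_ax, g_coll=params.g_coll)

        thetas = (np.arange(n_theta) + 0.5) * math.pi / n_theta
        rhats = np.array([0.5]) if n_r == 1 else np.linspace(0.0, 1.0, n_r)
        w = 1.0 / (n_theta * n_r)
        points = [
            MaterialPoint(theta=float(t), rhat=float(r), weight=w, state=make_state())
            for t in thetas
            for r in rhats
        ]
        return cls(params, dep, points, active_in_balance)

    # -- stress evaluation -------------------------------------------------

    def _point_sigma(
        self, st: MixtureState, f_t: float, f_z: float, include_active: bool
    ) -> np.ndarray:
        """Deviatoric principal stresses at one point, with the filament
        sliding taken at its stationary value for this trial stretch."""
        if include_active and st.rho_csmc > 0.0 and st.n_attached > 0.0:
            fil = FilamentState(
                n=np.array([0.0, 0.0, st.n3, st.n_attached - st.n3]), u_rs=st.u_rs
            )
            u = steady_sliding(fil, f_t * f_t, self.params.smc)
        else:
            u = st.u_rs
        trial = st.copy()
        trial.u_rs = u
        return mixture_stress_dev(
            trial, Kinematics(f_t, f_z), self.dep, self.params, include_active
        )

    def mean_sigma(self, f_t: float, f_z: float, include_active: bool | None = None) -> np.ndarray:
        if include_active is None:
            include_active = self.active_in_balance
        sig = np.zeros(3)
        wtot = 0.0
        for pt in self.points:
            sig += pt.weight * self._point_sigma(pt.state, f_t, f_z, include_active)
            wtot += pt.weight
        return sig / wtot

    def _commit_sliding(self, f_t: float) -> None:
        I4 = f_t * f_t
        for pt in self.points:
            st = pt.state
            if st.n_attached > 0.0:
                fil = FilamentState(
                    n=np.array([0.0, 0.0, st.n3, st.n_attached - st.n3]), u_rs=st.u_rs
                )
                st.u_rs = steady_sliding(fil, I4, self.params.smc)

    # -- equilibrium -------------------------------------------------------

    def laplace_target(self, f_t: float, f_z: float | None = None) -> float:
        """Thin-wall circumferential stress demanded by the pressure at
        the deformed geometry: p * r(f) / h(f)."""
        f_z = self.lambda_z if f_z is None else f_z
        g = self.geom
        return g.pressure * g.inner_radius * f_t * f_t * f_z / g.thickness

    def solve_equilibrium(self) -> float:
        """Circumferential stretch of the pressurized wall (radial-only
        kinematics, plane strain axially)."""
        f_z = self.lambda_z

        def residual(f_t: float) -> float:
            sig = self.mean_sigma(f_t, f_z)
            return (sig[1] - sig[0]) - self.laplace_target(f_t, f_z)

        lo, hi = 0.5, 2.0
        try:
            if residual(lo) * residual(hi) > 0:
                raise ValueError("equilibrium bracket does not straddle a root")
            lam = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
        except ValueError as exc:
            raise EquilibriumError(
                f"pressure equilibrium solve failed on day {self.day}: {exc}",
                {"day": self.day, "phi_ec": self.phi_ec,
                 "fractions": self.constituent_fractions()},
            ) from exc
        res = residual(lam)
        if abs(res) > _EQ_TOL:
            raise EquilibriumError(
                f"Laplace residual {res:.3e} MPa exceeds tolerance",
                {"lambda_t": lam, "day": self.day},
            )
        self.lambda_t = lam
        self._commit_sliding(lam)
        return lam

    # -- step 2: clamp -----------------------------------------------------

    def apply_clamp(self, profile: InjuryProfile | None) -> None:
        """Convert acute clamp damage (protocol step 2).

        The per-point overstretch history beta kills contractile SMC
        exponentially; the per-cohort positive fiber-stress deviation at
        the clamp overstretch destroys collagen mass; endothelium
        survives only where the luminal beta stays below its threshold.
        A zero/absent profile (0.0 N control) leaves the state bitwise
        untouched.  Damage is applied once and held thereafter.
        """
        if profile is None:
            return
        dmg = self.params.damage
        lam_field = profile.lambda_clamp()
        beta_grid = {}
        for i, t in enumerate(profile.thetas):
            for j, r in enumerate(profile.rhats):
                key = (round(float(t), 9), round(float(r), 9))
                beta_grid[key] = (
                    profile.beta[i, j], lam_field[i, j], profile.tensile[i, j]
                )
        for pt in self.points:
            key = (round(pt.theta, 9), round(pt.rhat, 9))
            try:
                beta, lam_clamp, tensile = beta_grid[key]
            except KeyError:
                raise ValueError(
                    "injury profile grid does not match the vessel grid"
                ) from None
            st = pt.state
            st.beta_hist = max(st.beta_hist, float(beta))
            st.d_csmc = smc_damage(st.beta_hist, dmg.m_csmc)
            st.rho_csmc = self.params.densities.csmc * (1.0 - st.d_csmc)
            if not tensile:
                # circumferential compression unloads the fibers; no
                # overload damage to collagen there
                st.d_coll = 0.0
                continue
            dcolls = []
            for fam in st.families:
                sig = collagen_fiber_stress(
                    lam_clamp, 1.0, fam, self.dep, self.params.passive
                )
                dz = rm.delta_zeta(sig, self.sigma_ff_hom)
                d = collagen_damage(dz, dmg.m_coll)
                fam.m = fam.m * (1.0 - d)
                dcolls.append(float(np.mean(d)))
            st.d_coll = float(np.mean(dcolls))
        self.phi_ec = endothelium_damage(profile.luminal_beta, dmg.m_ec)
        self.solve_equilibrium()

    def init_from_acute_fractions(
        self,
        collagen: float,
        csmc: float,
        ssmc: float,
        endothelium: float,
    ) -> None:
        """Initialize a uniform post-clamp state from overall constituent
        fractions (relative to homeostatic) instead of an injury profile.

        Stands in for the clamp step when only segment-averaged acute
        damage is known; elastin is untouched by construction.
        """
        rho0 = self.params.densities
        for pt in self.points:
            st = pt.state
            for fam in st.families:
                fam.m = fam.m * collagen
            st.rho_csmc = rho0.csmc * csmc
            st.rho_ssmc = rho0.ssmc * ssmc
            st.d_csmc = 1.0 - csmc
            st.d_coll = 1.0 - collagen
        self.phi_ec = endothelium
        self.solve_equilibrium()

    # -- step 3: heal ------------------------------------------------------

    @property
    def phi_ic(self) -> float:
        return rm.inflammation(self.phi_ec)

    def heal(self, days: float, rp: RemodelParams | None = None) -> pd.DataFrame:
        """Run daily remodeling for ``days`` days (protocol step 3)."""
        rp = rp or self.params.remodeling
        n_steps = int(round(days / rp.dt))
        if not self.history:
            self._record()
        for _ in range(n_steps):
            rm.remodeling_step(self, rp)
            self._record()
        return self.timeseries()

    def _record(self) -> None:
        row = {"day": self.day, "lambda_t": self.lambda_t,
               "delta_lambda": self.delta_lambda,
               "phi_ec": self.phi_ec, "phi_ic": self.phi_ic}
        row.update(self.constituent_fractions())
        self.history.append(row)

    def timeseries(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def constituent_fractions(self) -> dict[str, float]:
        """Segment-averaged constituent content relative to homeostasis."""
        rho0 = self.params.densities
        w = np.array([pt.weight for pt in self.points])
        # averaging per-point relative fractions keeps a constituent that
        # is exactly homeostatic everywhere at exactly 1.0
        def avg(values):
            return float(np.average(np.asarray(values), weights=w))

        return {
            "elastin": avg([pt.state.rho_elas / rho0.elastin for pt in self.points]),
            "collagen": avg([pt.state.rho_coll_total / rho0.collagen for pt in self.points]),
            "csmc": avg([pt.state.rho_csmc / rho0.csmc for pt in self.points]),
            "ssmc": avg([pt.state.rho_ssmc / rho0.ssmc for pt in self.points]),
            "endothelium": self.phi_ec,
            "inflammation": self.phi_ic,
        }

    # -- step 4: excision --------------------------------------------------

    def excise(self) -> tuple[float, float]:
        """Release pressure and axial constraint (protocol step 4).

        Solves the traction-free recoil (sigma_tt = sigma_zz = 0 with
        sigma_rr = 0) for the circumferential and axial stretches of the
        unloaded ring, basal tone included.
        """

        def residual(x):
            f_t, f_z = x
            if f_t <= 0.05 or f_z <= 0.05:
                return [1e3, 1e3]
            sig = self.mean_sigma(f_t, f_z, include_active=True)
            return [sig[1] - sig[0], sig[2] - sig[0]]

        sol = root(residual, x0=[0.85, 0.8], method="hybr", tol=1e-12)
        if not sol.success or np.max(np.abs(sol.fun)) > 1e-7:
            raise EquilibriumError(
                f"excision recoil solve failed: {sol.message}",
                {"residual": list(map(float, np.atleast_1d(sol.fun)))},
            )
        self.lambda_t, self.lambda_z = float(sol.x[0]), float(sol.x[1])
        self._commit_sliding(self.lambda_t)
        self.pressurized = False
        return self.lambda_t, self.lambda_z

    # -- step 5: myograph --------------------------------------------------

    def _axial_free_stretch(self, f_t: float) -> float:
        """Axial stretch with zero axial stress at given circumferential
        stretch (the ring is axially unconstrained on the rods)."""

        def res(f_z: float) -> float:
            sig = self.mean_sigma(f_t, f_z, include_active=True)
            return sig[2] - sig[0]

        return brentq(res, 0.3, 1.6, xtol=1e-12)

    def _wall_force_per_length(self, f_t: float) -> float:
        """Circumferential wall force per unit axial length (N/mm) of the
        two load-bearing ring segments."""
        f_z = self._axial_free_stretch(f_t)
        sig = self.mean_sigma(f_t, f_z, include_active=True)
        h_cur = self.geom.thickness / (f_t * f_z)
        return 2.0 * (sig[1] - sig[0]) * h_cur

    def myograph(
        self,
        setup: MyographSetup | None = None,
        doses: tuple = (("PE", 1e-6), ("ACh", 1e-5), ("NO", 1e-6)),
        n_curve: int = 60,
    ) -> MyographResult:
        """Virtual wire myograph (protocol step 5).

        The excised ring hangs on two rigid rods.  As the rods separate
        (center distance d), three zones follow: no contact (zero
        force), straightening of the circular ring into a stadium at
        constant perimeter (only a small bending force), and stretching
        once the perimeter is taut.  The moving rod stops at the
        prescribed preload; the dose protocol is then applied
        isometrically and the force recorded per stage.  Wall tension is
        idealized as two load-bearing wall segments: F/L = 2 sigma_tt h.
        """
        setup = setup or self.params.myograph
        if self.pressurized:
            self.excise()
        g = self.geom
        C_hom = 2.0 * math.pi * g.inner_radius
        C_ex = self.lambda_t * C_hom
        r_rod = setup.rod_radius
        if C_ex <= 2.0 * math.pi * r_rod:
            raise EquilibriumError("rod does not fit inside the excised ring")
        d_taut = 0.5 * (C_ex - 2.0 * math.pi * r_rod)
        d_slack = max(self.lambda_t * 2.0 * g.inner_radius - 2.0 * r_rod, 0.0)
        d_slack = min(d_slack, d_taut)

        # bending scale of the straightening zone (thin shell, small)
        R_ex = C_ex / (2.0 * math.pi)
        EI = 6.0 * self.params.passive.C10 * g.thickness ** 3 / 12.0
        U_bend = 0.5 * EI * (
            2.0 * math.pi * r_rod * (1.0 / r_rod - 1.0 / R_ex) ** 2
            + 2.0 * d_taut * (1.0 / R_ex) ** 2
        )
        span = max(d_taut - d_slack, 1e-9)

        def f_bend(d: float) -> float:
            s = min(max((d - d_slack) / span, 0.0), 1.0)
            return 2.0 * U_bend * s / span

        def force(d: float) -> float:
            if d <= d_slack:
                return 0.0
            if d <= d_taut:
                return f_bend(d)
            f_t = (2.0 * d + 2.0 * math.pi * r_rod) / C_hom
            return self._wall_force_per_length(f_t) + f_bend(d_taut)

        # preload solve on the stretching branch
        d_hi = d_taut + 2.0 * g.inner_radius
        if force(d_hi) < setup.preload_per_length:
            raise EquilibriumError(
                "preload unreachable within the stretch bound",
                {"force_at_bound": force(d_hi)},
            )
        d_pre = brentq(
            lambda d: force(d) - setup.preload_per_length,
            d_taut, d_hi, xtol=1e-12,
        )
        self._commit_sliding((2.0 * d_pre + 2.0 * math.pi * r_rod) / C_hom)

        disp = np.linspace(0.0, 1.05 * d_pre, n_curve)
        curve = np.array([force(d) for d in disp])

        stage_forces = self._isometric_doses(
            d_pre, C_hom, r_rod, doses, f_offset=f_bend(d_taut)
        )
        return MyographResult(
            gap_preload=d_pre,
            displacement=disp,
            force=curve,
            stage_forces=stage_forces,
            zones=(d_slack, d_taut),
        )

    def _isometric_doses(
        self, d_pre, C_hom, r_rod, doses, f_offset: float = 0.0
    ) -> dict[str, float]:
        """Isometric force per dose stage at the preload gap.

        PE pre-constricts; each dilator (NO or ACh) is then added on top
        of the PE bath in an independent branch, mirroring separate
        myograph runs.  ``f_offset`` carries the constant bending force
        of the straightened ring shape.
        """
        f_t = (2.0 * d_pre + 2.0 * math.pi * r_rod) / C_hom
        f_z = self._axial_free_stretch(f_t)
        I4 = f_t * f_t
        h_cur = self.geom.thickness / (f_t * f_z)
        sig = self.mean_sigma(f_t, f_z, include_active=True)
        sig_pass = (sig[1] - sig[0]) - self._active_sigma_tt(I4, None)[0]

        def total_force(sig_act: float) -> float:
            return 2.0 * (sig_pass + sig_act) * h_cur + f_offset

        rho0 = self.params.densities
        w = np.array([pt.weight for pt in self.points])
        rho_rel = sum(
            wi * pt.state.rho_csmc for wi, pt in zip(w / w.sum(), self.points)
        ) / rho0.csmc

        conc = {"PE": 0.0, "ACh": 0.0, "NO": 0.0}
        env0 = chemical_environment(0.0, 0.0, 0.0, self.phi_ec,
                                    self.params.agents, self.params.kinetics)
        sig_act, fil = self._active_sigma_tt(I4, env0)
        out = {"baseline": total_force(sig_act)}
        for agent, dose in doses:
            if agent == "PE":
                conc["PE"] = dose
                env = chemical_environment(conc["PE"], 0.0, 0.0, self.phi_ec,
                                           self.params.agents, self.params.kinetics)
                sig_act, fil = self._active_sigma_tt(I4, env, fil, rho_rel)
                out["PE"] = total_force(sig_act)
            else:
                env = chemical_environment(
                    conc["PE"],
                    dose if agent == "ACh" else 0.0,
                    dose if agent == "NO" else 0.0,
                    self.phi_ec, self.params.agents, self.params.kinetics,
                )
                sig_d, _ = self._active_sigma_tt(I4, env, fil, rho_rel)
                out[f"PE+{agent}"] = total_force(sig_d)
        return out

    def _active_sigma_tt(self, I4, env, fil=None, rho_rel=None):
        """Energy-consistent active Cauchy stress contribution (MPa) of
        the surviving contractile SMC at stretch I4 = lambda_t^2."""
        p = self.params
        if rho_rel is None:
            rho0 = p.densities
            w = np.array([pt.weight for pt in self.points])
            rho_rel = sum(
                wi * pt.state.rho_csmc for wi, pt in zip(w / w.sum(), self.points)
            ) / rho0.csmc
        if env is None:
            # current committed state of the points
            st = self.points[0].state
            n3, n34, u = st.n3, st.n_attached, st.u_rs
            # average attached machinery is identical across points
            x = I4 + u - 1.0
            return rho_rel * p.densities.csmc * 2.0 * p.smc.mu * n34 * x * I4, None
        n = hai_murphy_steady((env.k1, env.k2, p.kinetics.k3, p.kinetics.k4,
                               env.k5, env.k6, p.kinetics.k7))
        if fil is None:
            st = self.points[0].state
            fil2 = FilamentState(
                n=np.array([0.0, 0.0, st.n3, st.n_attached - st.n3]), u_rs=st.u_rs
            )
        else:
            fil2 = fil.copy()
        fil2.n = n
        fil2.u_rs = steady_sliding(fil2, I4, p.smc)
        n34 = float(n[2] + n[3])
        x = I4 + fil2.u_rs - 1.0
        sig = rho_rel * p.densities.csmc * 2.0 * p.smc.mu * n34 * x * I4
        return sig, fil2


def run_case(
    config: ScenarioConfig,
    params: ParameterRegistry | None = None,
) -> CaseResult:
    """Execute the full protocol for one of the six cases."""
    params = params or default_registry()
    rp = RemodelParams(
        K_qh=params.remodeling.K_qh, K_m=params.remodeling.K_m,
        K_pl=params.remodeling.K_pl, K_ec=params.remodeling.K_ec,
        K_dd=params.remodeling.K_dd, K_ic=params.remodeling.K_ic,
        dt=config.dt_day, variant=config.variant,
    )
    model = VesselModel.homeostatic(
        params, n_theta=config.n_theta, n_r=config.n_r,
        active_in_balance=config.active_in_balance,
    )
    model.solve_equilibrium()
    if config.clamp_load and config.clamp_load > 0.0:
        profile = calibrate_profile(
            config.clamp_load, params, config.n_theta, config.n_r
        )
        model.apply_clamp(profile)
    acute = model.constituent_fractions()
    if config.heals:
        model.heal(config.healing_days, rp)
    final = model.constituent_fractions()
    myo = model.myograph(doses=config.doses)
    return CaseResult(
        case_id=config.case_id,
        acute_fractions=acute,
        final_fractions=final,
        history=model.timeseries(),
        myograph=myo,
        config_hash=config_hash(params, config),
    )
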