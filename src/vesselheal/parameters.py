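"""Parameter registry and scenario configuration.

All quantities are normalized to the internal unit system MPa / mm / N /
day / s / M.  The default registry ships with the package as
``data/default_params.yaml`` and covers constituent densities, passive
and active material constants, deposition prestretches, damage constants,
remodeling rates, the smooth-muscle contractility constants, the vessel
geometry and the myograph protocol.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PassiveParams",
    "SMCParams",
    "DamageParams",
    "RemodelParams",
    "KineticParams",
    "AgentParams",
    "InitialDensities",
    "VesselGeometry",
    "MyographSetup",
    "NumericSettings",
    "ParameterRegistry",
    "ScenarioConfig",
    "ParameterError",
    "load_params",
    "save_params",
    "default_registry",
    "config_hash",
]


class ParameterError(ValueError):
    """Raised when a parameter file is incomplete or inconsistent."""


@dataclass(frozen=True)
class PassiveParams:
    """Gasser–Ogden–Holzapfel constants for the passive mixture.

    C10 (MPa) is the Neo-Hookean elastin stiffness; k1 (MPa) and k2 (-)
    set the exponential collagen response; kappa in [0, 1/3] is the fiber
    dispersion and alpha (rad) the fiber angle of the two symmetric
    collagen families measured from the circumferential direction.
    """

    C10: float = 0.04
    k1: float = 1.0
    k2: float = 1.5
    kappa: float = 0.1
    alpha: float = math.pi / 8

    def __post_init__(self) -> None:
        if self.C10 <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ParameterError("C10, k1, k2 must be positive")
        if not 0.0 <= self.kappa <= 1.0 / 3.0:
            raise ParameterError("fiber dispersion kappa must lie in [0, 1/3]")

    @property
    def fiber_dirs(self):
        """Unit fiber vectors in the (radial, circ, axial) frame."""
        c, s = math.cos(self.alpha), math.sin(self.alpha)
        return ((0.0, c, s), (0.0, c, -s))


@dataclass(frozen=True)
class SMCParams:
    """Active smooth-muscle stiffness mu (MPa), crossbridge stress scale
    kappa_c (MPa) and filament sliding viscosity eta (MPa s)."""

    mu: float = 0.42
    kappa_c: float = 1.55
    eta: float = 60.0


@dataclass(frozen=True)
class DamageParams:
    """Acute clamp damage constants: exponential-saturation constants for
    contractile SMC (m_csmc) and collagen (m_coll), and the overstretch
    threshold m_ec above which local endothelium dies."""

    m_csmc: float = 1.0
    m_coll: float = 20.0
    m_ec: float = 0.38

    def __post_init__(self) -> None:
        if min(self.m_csmc, self.m_coll, self.m_ec) <= 0:
            raise ParameterError("damage constants must be positive")


VARIANTS = ("original", "no_redifferentiation", "mech_independent_production")


@dataclass
class RemodelParams:
    """Day-scale remodeling rates.

    K_qh (1/day) homeostatic collagen decay (half-life ln2/K_qh days);
    K_m (-) gain of stretch-driven collagen production; K_pl (1/day)
    stretch-driven synthetic-SMC proliferation; K_ec (1/day) logistic
    endothelial healing rate; K_dd (1/day) phenotype differentiation
    rate; K_ic (1/day) inflammation-driven proliferation; dt (day) the
    remodeling time step.  ``variant`` selects the original phenotype /
    production laws or one of the two modified couplings.
    """

    K_qh: float = math.log(2.0) / 100.0
    K_m: float = 26.64
    K_pl: float = 4.0
    K_ec: float = 0.08
    K_dd: float = 1.6
    K_ic: float = 0.01
    dt: float = 1.0
    variant: str = "original"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("remodeling time step must be positive")
        if min(self.K_qh, self.K_m, self.K_pl, self.K_ec, self.K_dd, self.K_ic) < 0:
            raise ParameterError("remodeling rates must be non-negative")
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown remodeling variant {self.variant!r}")


@dataclass(frozen=True)
class KineticParams:
    """Hai–Murphy crossbridge rate constants (1/s) and the calcium
    dependence of the phosphorylation rate."""

    k3: float = 0.4
    k4: float = 0.1
    k7: float = 0.01
    k2_hom: float = 0.5
    alpha2: float = 0.1
    K_CaCaM: float = 1.78e-7
    alpha_Ca: float = 0.24


@dataclass(frozen=True)
class AgentParams:
    """Vasoactive agent chemistry: Hill constants of the NO and PE
    responses (M), the maximal calcium shifts they cause (M), the
    homeostatic intracellular calcium (M) and the saturating log-linear
    ACh -> endothelial NO release curve."""

    K_NO: float = 8.0e-8
    K_PE: float = 2.0e-7
    alpha_NO: float = 1.4e-7
    alpha_PE: float = 1.28e-7
    Ca_hom: float = 2.7e-7
    ach_no_amplitude: float = 2.8e-7
    ach_no_offset: float = 8.2
    ach_no_shape: float = 0.9


@dataclass(frozen=True)
class InitialDensities:
    """Homeostatic referential mass densities, normalized so that the
    four constituents sum to one."""

    elastin: float = 0.35
    collagen: float = 0.30
    csmc: float = 0.30
    ssmc: float = 0.05


@dataclass(frozen=True)
class VesselGeometry:
    """Reduced thin-walled half-cylinder geometry (mm) and diastolic
    pressure (MPa)."""

    inner_diameter: float = 0.65
    thickness: float = 0.04
    segment_length: float = 0.04
    pressure: float = 0.01

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ParameterError("pressure must be non-negative")

    @property
    def inner_radius(self) -> float:
        return 0.5 * self.inner_diameter


@dataclass(frozen=True)
class MyographSetup:
    """Wire-myograph rig: rod radius (mm) and isometric preload per unit
    axial length of the ring (N/mm)."""

    rod_radius: float = 0.15
    preload_per_length: float = 0.0133


@dataclass(frozen=True)
class NumericSettings:
    dt_day: float = 1.0
    dt_s: float = 0.01


@dataclass
class ParameterRegistry:
    """Complete, validated parameter set for one simulation."""

    densities: InitialDensities = field(default_factory=InitialDensities)
    passive: PassiveParams = field(default_factory=PassiveParams)
    smc: SMCParams = field(default_factory=SMCParams)
    damage: DamageParams = field(default_factory=DamageParams)
    remodeling: RemodelParams = field(default_factory=RemodelParams)
    kinetics: KineticParams = field(default_factory=KineticParams)
    agents: AgentParams = field(default_factory=AgentParams)
    geometry: VesselGeometry = field(default_factory=VesselGeometry)
    myograph: MyographSetup = field(default_factory=MyographSetup)
    numerics: NumericSettings = field(default_factory=NumericSettings)
    g_ax: float = 1.67
    g_coll: float = 1.1
    provenance: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("provenance", None)
        return d


# Registry symbol -> (yaml section, yaml key, expected units).  The load
# fails naming the symbol if any entry is absent or its unit disagrees.
_SCHEMA = {
    "rho0elas": ("initial_densities", "rho0elas", "-"),
    "rho0coll": ("initial_densities", "rho0coll", "-"),
    "rho0csmc": ("initial_densities", "rho0csmc", "-"),
    "rho0ssmc": ("initial_densities", "rho0ssmc", "-"),
    "C10": ("passive", "C10", "MPa"),
    "k1": ("passive", "k1", "MPa"),
    "k2": ("passive", "k2", "-"),
    "kappa": ("passive", "kappa", "-"),
    "alpha": ("passive", "alpha", "rad"),
    "mucsmc": ("smc", "mucsmc", "MPa"),
    "kappac": ("smc", "kappac", "MPa"),
    "eta": ("contractility", "eta", "MPa*s"),
    "gax": ("prestretch", "gax", "-"),
    "gcoll": ("prestretch", "gcoll", "-"),
    "mcsmc": ("damage", "mcsmc", "-"),
    "mcoll": ("damage", "mcoll", "-"),
    "mec": ("damage", "mec", "-"),
    "Kqhcoll": ("remodeling", "Kqhcoll", "1/day"),
    "Kmcoll": ("remodeling", "Kmcoll", "-"),
    "Kplsmc": ("remodeling", "Kplsmc", "1/day"),
    "Kec": ("remodeling", "Kec", "1/day"),
    "Kddsmc": ("remodeling", "Kddsmc", "1/day"),
    "Kicsmc": ("remodeling", "Kicsmc", "1/day"),
    "k3": ("contractility", "k3", "1/s"),
    "k4": ("contractility", "k4", "1/s"),
    "k7": ("contractility", "k7", "1/s"),
    "k2hom": ("contractility", "k2hom", "1/s"),
    "alpha2": ("contractility", "alpha2", "1/s"),
    "KNO": ("contractility", "KNO", "M"),
    "KPE": ("contractility", "KPE", "M"),
    "Cahom": ("contractility", "Cahom", "M"),
    "alphaNO": ("contractility", "alphaNO", "M"),
    "alphaPE": ("contractility", "alphaPE", "M"),
    "alphaCa": ("contractility", "alphaCa", "-"),
    "KCaCaM": ("contractility", "KCaCaM", "M"),
    "ach_no_amplitude": ("contractility", "ach_no_amplitude", "M"),
    "ach_no_offset": ("contractility", "ach_no_offset", "-"),
    "ach_no_shape": ("contractility", "ach_no_shape", "-"),
    "inner_diameter": ("geometry", "inner_diameter", "mm"),
    "thickness": ("geometry", "thickness", "mm"),
    "segment_length": ("geometry", "segment_length", "mm"),
    "pressure": ("geometry", "pressure", "MPa"),
    "rod_radius": ("myograph", "rod_radius", "mm"),
    "preload_per_length": ("myograph", "preload_per_length", "N/mm"),
    "dt_day": ("numerics", "dt_day", "day"),
    "dt_s": ("numerics", "dt_s", "s"),
}

_RATE_SYMBOLS = {
    "Kqhcoll", "Kmcoll", "Kplsmc", "Kec", "Kddsmc", "Kicsmc",
    "k3", "k4", "k7", "k2hom", "alpha2",
}


def _extract(raw: dict) -> tuple[dict, dict]:
    values, provenance = {}, {}
    for symbol, (section, key, units) in _SCHEMA.items():
        try:
            entry = raw[section][key]
        except (KeyError, TypeError):
            raise ParameterError(f"parameter file is missing {symbol!r}") from None
        if not isinstance(entry, dict) or "value" not in entry:
            raise ParameterError(f"entry for {symbol!r} must be a mapping with a 'value'")
        got_units = entry.get("units", "-")
        if got_units != units:
            raise ParameterError(
                f"unit mismatch for {symbol!r}: expected {units!r}, got {got_units!r}"
            )
        v = float(entry["value"])
        if symbol in _RATE_SYMBOLS and v < 0:
            raise ParameterError(f"rate {symbol!r} must be non-negative, got {v}")
        values[symbol] = v
        provenance[symbol] = entry.get("provenance")
    return values, provenance


def _registry_from_values(values: dict, provenance: dict) -> ParameterRegistry:
    return ParameterRegistry(
        densities=InitialDensities(
            elastin=values["rho0elas"], collagen=values["rho0coll"],
            csmc=values["rho0csmc"], ssmc=values["rho0ssmc"]),
        passive=PassiveParams(
            C10=values["C10"], k1=values["k1"], k2=values["k2"],
            kappa=values["kappa"], alpha=values["alpha"]),
        smc=SMCParams(mu=values["mucsmc"], kappa_c=values["kappac"], eta=values["eta"]),
        damage=DamageParams(
            m_csmc=values["mcsmc"], m_coll=values["mcoll"], m_ec=values["mec"]),
        remodeling=RemodelParams(
            K_qh=values["Kqhcoll"], K_m=values["Kmcoll"], K_pl=values["Kplsmc"],
            K_ec=values["Kec"], K_dd=values["Kddsmc"], K_ic=values["Kicsmc"],
            dt=values["dt_day"]),
        kinetics=KineticParams(
            k3=values["k3"], k4=values["k4"], k7=values["k7"],
            k2_hom=values["k2hom"], alpha2=values["alpha2"],
            K_CaCaM=values["KCaCaM"], alpha_Ca=values["alphaCa"]),
        agents=AgentParams(
            K_NO=values["KNO"], K_PE=values["KPE"], alpha_NO=values["alphaNO"],
            alpha_PE=values["alphaPE"], Ca_hom=values["Cahom"],
            ach_no_amplitude=values["ach_no_amplitude"],
            ach_no_offset=values["ach_no_offset"],
            ach_no_shape=values["ach_no_shape"]),
        geometry=VesselGeometry(
            inner_diameter=values["inner_diameter"], thickness=values["thickness"],
            segment_length=values["segment_length"], pressure=values["pressure"]),
        myograph=MyographSetup(
            rod_radius=values["rod_radius"],
            preload_per_length=values["preload_per_length"]),
        numerics=NumericSettings(dt_day=values["dt_day"], dt_s=values["dt_s"]),
        g_ax=values["gax"],
        g_coll=values["gcoll"],
        provenance=provenance,
    )


def load_params(path: str | Path) -> ParameterRegistry:
    """Load and validate a YAML parameter file into a registry."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path} does not contain a parameter mapping")
    values, provenance = _extract(raw)
    return _registry_from_values(values, provenance)


def save_params(registry: ParameterRegistry, path: str | Path) -> None:
    """Write a registry back to YAML in the shipped file's layout."""
    sections: dict[str, dict] = {}
    values = _registry_values(registry)
    for symbol, (section, key, units) in _SCHEMA.items():
        entry = {"value": values[symbol], "units": units}
        prov = registry.provenance.get(symbol)
        if prov is not None:
            entry["provenance"] = prov
        sections.setdefault(section, {})[key] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(sections, fh, sort_keys=False)


def _registry_values(r: ParameterRegistry) -> dict:
    return {
        "rho0elas": r.densities.elastin, "rho0coll": r.densities.collagen,
        "rho0csmc": r.densities.csmc, "rho0ssmc": r.densities.ssmc,
        "C10": r.passive.C10, "k1": r.passive.k1, "k2": r.passive.k2,
        "kappa": r.passive.kappa, "alpha": r.passive.alpha,
        "mucsmc": r.smc.mu, "kappac": r.smc.kappa_c, "eta": r.smc.eta,
        "gax": r.g_ax, "gcoll": r.g_coll,
        "mcsmc": r.damage.m_csmc, "mcoll": r.damage.m_coll, "mec": r.damage.m_ec,
        "Kqhcoll": r.remodeling.K_qh, "Kmcoll": r.remodeling.K_m,
        "Kplsmc": r.remodeling.K_pl, "Kec": r.remodeling.K_ec,
        "Kddsmc": r.remodeling.K_dd, "Kicsmc": r.remodeling.K_ic,
        "k3": r.kinetics.k3, "k4": r.kinetics.k4, "k7": r.kinetics.k7,
        "k2hom": r.kinetics.k2_hom, "alpha2": r.kinetics.alpha2,
        "KNO": r.agents.K_NO, "KPE": r.agents.K_PE,
        "Cahom": r.agents.Ca_hom, "alphaNO": r.agents.alpha_NO,
        "alphaPE": r.agents.alpha_PE, "alphaCa": r.kinetics.alpha_Ca,
        "KCaCaM": r.kinetics.K_CaCaM,
        "ach_no_amplitude": r.agents.ach_no_amplitude,
        "ach_no_offset": r.agents.ach_no_offset,
        "ach_no_shape": r.agents.ach_no_shape,
        "inner_diameter": r.geometry.inner_diameter,
        "thickness": r.geometry.thickness,
        "segment_length": r.geometry.segment_length,
        "pressure": r.geometry.pressure,
        "rod_radius": r.myograph.rod_radius,
        "preload_per_length": r.myograph.preload_per_length,
        "dt_day": r.numerics.dt_day, "dt_s": r.numerics.dt_s,
    }


def default_registry() -> ParameterRegistry:
    """Registry loaded from the packaged default parameter file."""
    with importlib.resources.as_file(
        importlib.resources.files("vesselheal.data") / "default_params.yaml"
    ) as p:
        return load_params(p)


@dataclass
class ScenarioConfig:
    """One simulation scenario: which of the six clamp/healing cases to
    run and with what numerical settings.

    case_id is one of A0/R0 (0.0 N control), A1/R1 (0.6 N) or A2/R2
    (1.27 N); the A cases stop acutely after clamping, the R cases add a
    healing period (31 days by default).
    """

    case_id: str = "R1"
    clamp_load: float | None = None
    healing_days: int = 31
    variant: str = "original"
    dt_day: float = 1.0
    n_theta: int = 48
    n_r: int = 3
    active_in_balance: bool = False
    doses: tuple = (("PE", 1e-6), ("ACh", 1e-5), ("NO", 1e-6))

    _CASE_LOADS = {"A0": 0.0, "R0": 0.0, "A1": 0.6, "R1": 0.6, "A2": 1.27, "R2": 1.27}

    def __post_init__(self) -> None:
        if self.case_id not in self._CASE_LOADS:
            raise ParameterError(f"unknown case id {self.case_id!r}")
        if self.clamp_load is None:
            self.clamp_load = self._CASE_LOADS[self.case_id]
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown remodeling variant {self.variant!r}")

    @property
    def heals(self) -> bool:
        return self.case_id.startswith("R")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_hash(registry: ParameterRegistry, scenario: ScenarioConfig | None = None) -> str:
    """Deterministic sha256 hash of the fully resolved configuration."""
    payload = {"parameters": _registry_values(registry)}
    if scenario is not None:
        payload["scenario"] = scenario.to_dict()
    blob = yaml.safe_dump(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
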