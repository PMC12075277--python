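"""Forward biphasic model for spherical creep indentation of cartilage.

Articular cartilage is modelled as a biphasic (poroelastic) layer: a porous
elastic solid saturated with interstitial fluid.  When a rigid sphere applies
a step load, the tissue responds instantaneously as an incompressible solid,
then creeps toward a drained (equilibrium) Hertzian deflection as fluid is
exuded from the contact region.  With a drained Poisson's ratio of zero — the
contract of the curve-fitting model used throughout this package — the
equilibrium contact modulus E equals the aggregate modulus, and the creep
transient is governed by the consolidation diffusivity D = E*k, where k is
the hydraulic permeability.

The transient is expressed through a dimensionless master curve g(tau),

    delta(t) = delta_eq - (delta_eq - delta_0) * g(tau),
    tau      = E * k * t / a_eq**2,

with a_eq the equilibrium Hertzian contact radius, delta_0 the instantaneous
(incompressible-limit) deflection, and g falling from g(0) = 1 to 0.  The
adopted g is the published two-exponential spherical poroelastic master
function

    g(tau) = 1.304 * exp(-sqrt(tau)) - 0.304 * exp(-0.254 * tau),

a closed form that honours both limits exactly; it is kept as a swappable
strategy (`master_curve_g` is a plain function of tau).

Units: the public API uses bench units (uN, um, mm, MPa, s); permeability is
SI m^4/(N s).  See `cartmap.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from . import units

__all__ = [
    "IndentationProtocol",
    "MaterialState",
    "CreepCurve",
    "STUDY_PROTOCOL",
    "hertz_equilibrium_deflection",
    "contact_radius",
    "master_curve_g",
    "master_curve_tau_at",
    "thickness_correction_factor",
    "forward_creep",
    "INSTANT_TO_EQ_RATIO",
]

#: delta_0 / delta_eq for a step load at drained nu = 0.  The instantaneous
#: response is incompressible (effective Poisson's ratio 1/2), which doubles
#: the effective contact modulus at fixed shear modulus; Hertz deflection
#: scales as E^(-2/3), hence the ratio 2**(-2/3).  A model consequence, not a
#: free parameter.
INSTANT_TO_EQ_RATIO: float = 2.0 ** (-2.0 / 3.0)

# Bonded-layer finite-thickness stiffening polynomial in alpha = a/h
# (published correction for a sphere on a thin bonded sample).
_BONDED_LAYER_COEFFS = (1.133, 1.283, 0.769, 0.0975)


@dataclass(frozen=True)
class IndentationProtocol:
    """Fixed experimental contract of the creep-indentation protocol.

    Defaults are the bench settings used throughout: a 100 uN preload held
    400 s to seat the probe, then a 5000 uN creep load held 600 s, with a
    0.5 mm ruby sphere.
    """

    probe_radius_mm: float = 0.5
    preload_un: float = 100.0
    preload_duration_s: float = 400.0
    creep_load_un: float = 5000.0
    creep_duration_s: float = 600.0
    sampling_rate_hz: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "probe_radius_mm",
            "preload_un",
            "preload_duration_s",
            "creep_load_un",
            "creep_duration_s",
            "sampling_rate_hz",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.creep_load_un > self.preload_un:
            raise ValueError("creep load must exceed preload")

    def creep_times(self) -> np.ndarray:
        """Default sampling grid for the creep phase, starting at t = 0."""
        n = int(round(self.creep_duration_s * self.sampling_rate_hz)) + 1
        return np.linspace(0.0, self.creep_duration_s, n)


#: The study protocol (module-level singleton used as the default everywhere).
STUDY_PROTOCOL = IndentationProtocol()


@dataclass(frozen=True)
class MaterialState:
    """Biphasic material parameters of one cartilage region.

    eq_modulus_mpa
        Equilibrium contact modulus E (MPa).  With drained nu = 0 it equals
        the aggregate modulus.
    permeability_m4_ns
        Hydraulic permeability k in m^4/(N s).
    thickness_mm
        Cartilage layer thickness h (mm); used for the thin-layer validity
        flag and the optional bonded-layer correction.
    poisson_nu
        Drained Poisson's ratio; fixed at 0 by the model contract.
    """

    eq_modulus_mpa: float
    permeability_m4_ns: float
    thickness_mm: float
    poisson_nu: float = 0.0

    def __post_init__(self) -> None:
        if not self.eq_modulus_mpa > 0:
            raise ValueError("eq_modulus_mpa must be positive")
        if not self.permeability_m4_ns > 0:
            raise ValueError("permeability_m4_ns must be positive")
        if not self.thickness_mm > 0:
            raise ValueError("thickness_mm must be positive")
        if self.poisson_nu != 0.0:
            raise ValueError("model contract requires poisson_nu = 0")


@dataclass(frozen=True)
class CreepCurve:
    """Sampled deformation-vs-time series for one creep experiment.

    Deformation is referenced to the preload-equilibrium state; time is
    seconds since application of the creep load.
    """

    time_s: np.ndarray
    deformation_um: np.ndarray
    protocol: IndentationProtocol = field(default=STUDY_PROTOCOL)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.deformation_um, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "deformation_um", d)
        if t.ndim != 1 or d.ndim != 1 or t.size != d.size:
            raise ValueError("time and deformation must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a creep curve needs at least 2 samples")
        if t[0] != 0.0:
            raise ValueError("time must start at 0 (creep-load application)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(d)):
            raise ValueError("deformation contains non-finite values")

    @property
    def n_points(self) -> int:
        return int(self.time_s.size)


def hertz_equilibrium_deflection(
    creep_load_un: float, probe_radius_mm: float, eq_modulus_mpa: float
) -> float:
    """Drained (equilibrium) Hertz deflection in micrometres.

    Closed-form inversion of the Hertz force relation at nu = 0,
    F = (4/3) E sqrt(R) delta^(3/2), i.e.

        delta_eq = (3 F / (4 E sqrt(R)))**(2/3).

    Semi-infinite half-space; no finite-thickness correction.
    """
    if not (creep_load_un > 0 and probe_radius_mm > 0 and eq_modulus_mpa > 0):
        raise ValueError("force, radius and modulus must all be positive")
    F = units.force_si(creep_load_un)
    R = units.length_si_from_mm(probe_radius_mm)
    E = units.pressure_si(eq_modulus_mpa)
    delta = (3.0 * F / (4.0 * E * np.sqrt(R))) ** (2.0 / 3.0)
    return float(units.length_um(delta))


def contact_radius(probe_radius_mm: float, deflection_um: float) -> float:
    """Hertzian contact radius a = sqrt(R * delta), in millimetres."""
    if not probe_radius_mm > 0:
        raise ValueError("probe radius must be positive")
    if deflection_um < 0:
        raise ValueError("deflection must be non-negative")
    R = units.length_si_from_mm(probe_radius_mm)
    delta = units.length_si_from_um(deflection_um)
    return float(units.length_mm(np.sqrt(R * delta)))


def master_curve_g(tau):
    """Normalized creep transient g(tau) = 1.304 e^(-sqrt tau) - 0.304 e^(-0.254 tau).

    g(0) = 1 exactly (1.304 - 0.304); g -> 0 as tau -> inf; nonincreasing.
    Accepts scalars or arrays of dimensionless time tau >= 0.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be non-negative")
    out = 1.304 * np.exp(-np.sqrt(tau_arr)) - 0.304 * np.exp(-0.254 * tau_arr)
    if np.isscalar(tau) or tau_arr.ndim == 0:
        return float(out)
    return out


_tau_cache: dict[float, float] = {}


def master_curve_tau_at(g_value: float) -> float:
    """Dimensionless time at which the master curve crosses ``g_value``.

    Used by the fit initializer (g = 0.5 gives the half-creep time).
    """
    if not 0.0 < g_value < 1.0:
        raise ValueError("g_value must lie strictly between 0 and 1")
    if g_value not in _tau_cache:
        _tau_cache[g_value] = brentq(
            lambda t: master_curve_g(t) - g_value, 1e-12, 1e4, xtol=1e-14
        )
    return _tau_cache[g_value]


def thickness_correction_factor(a_over_h: float, enabled: bool = False) -> float:
    """Multiplicative stiffening factor chi(a/h) on the Hertz force.

    Finite cartilage thickness stiffens the apparent contact response once
    the contact radius becomes comparable to the layer thickness.  When
    enabled, the published bonded-layer polynomial

        chi(x) = 1 + 1.133 x + 1.283 x^2 + 0.769 x^3 + 0.0975 x^4

    is applied; disabled (the default), chi is identically 1 and the model is
    the semi-infinite half-space.  chi(0) = 1 in either case.
    """
    if a_over_h < 0:
        raise ValueError("a/h must be non-negative")
    if not enabled:
        return 1.0
    c1, c2, c3, c4 = _BONDED_LAYER_COEFFS
    x = a_over_h
    return 1.0 + c1 * x + c2 * x * x + c3 * x**3 + c4 * x**4


def _equilibrium_deflection_um(
    creep_load_un: float,
    probe_radius_mm: float,
    eq_modulus_mpa: float,
    thickness_mm: float,
    thickness_correction: bool,
) -> float:
    """Equilibrium deflection, optionally with the bonded-layer correction.

    With the correction enabled the force balance
    F = (4/3) E sqrt(R) delta^(3/2) chi(sqrt(R delta)/h) is solved for delta
    by bracketing (chi >= 1 so the corrected deflection never exceeds the
    semi-infinite one).
    """
    d0 = hertz_equilibrium_deflection(creep_load_un, probe_radius_mm, eq_modulus_mpa)
    if not thickness_correction:
        return d0

    def imbalance(delta_um: float) -> float:
        a_mm = contact_radius(probe_radius_mm, delta_um)
        chi = thickness_correction_factor(a_mm / thickness_mm, enabled=True)
        # F(delta)/F_applied - 1, in semi-infinite-deflection units
        return chi * (delta_um / d0) ** 1.5 - 1.0

    return brentq(imbalance, 1e-9 * d0, d0, xtol=1e-12 * d0)


def forward_creep(
    material: MaterialState,
    protocol: IndentationProtocol = STUDY_PROTOCOL,
    times_s: Sequence[float] | np.ndarray | None = None,
    thickness_correction: bool = False,
) -> CreepCurve:
    """Predict the creep deformation-time response under a step creep load.

    delta(t) = delta_eq - (delta_eq - delta_0) * g(E k t / a_eq^2) with
    delta_0 = 2^(-2/3) delta_eq.  The load step is idealized as instantaneous
    at t = 0, and deformation is creep-phase only (referenced to the preload
    equilibrium; the preload's own Hertzian deformation, ~2 %% of the creep
    load's, is not modelled).
    """
    if times_s is None:
        t = protocol.creep_times()
    else:
        t = np.asarray(times_s, dtype=float)
    if t.size == 0:
        raise ValueError("empty time vector")
    if t[0] != 0.0:
        raise ValueError("times must start at 0")

    delta_eq_um = _equilibrium_deflection_um(
        protocol.creep_load_un,
        protocol.probe_radius_mm,
        material.eq_modulus_mpa,
        material.thickness_mm,
        thickness_correction,
    )
    a_eq_mm = contact_radius(protocol.probe_radius_mm, delta_eq_um)
    if a_eq_mm <= 0:
        raise ValueError("degenerate parameters: zero equilibrium contact radius")

    a_eq_m = units.length_si_from_mm(a_eq_mm)
    diffusivity = units.pressure_si(material.eq_modulus_mpa) * material.permeability_m4_ns
    tau = diffusivity * t / a_eq_m**2
    delta_0_um = INSTANT_TO_EQ_RATIO * delta_eq_um
    g = master_curve_g(tau)
    deformation = delta_eq_um - (delta_eq_um - delta_0_um) * np.atleast_1d(g)
    if t.size == 1:
        # CreepCurve requires >= 2 samples; single-time evaluation returns a
        # curve padded with an epsilon step so the container stays valid.
        t = np.array([0.0, np.finfo(float).eps])
        deformation = np.array([deformation[0], deformation[0]])
    return CreepCurve(time_s=t, deformation_um=deformation, protocol=protocol)


def predict_deformation_um(
    eq_modulus_mpa: float,
    permeability_m4_ns: float,
    times_s: np.ndarray,
    protocol: IndentationProtocol = STUDY_PROTOCOL,
) -> np.ndarray:
    """Vectorized transient evaluation used by the fitter (no container)."""
    delta_eq_um = hertz_equilibrium_deflection(
        protocol.creep_load_un, protocol.probe_radius_mm, eq_modulus_mpa
    )
    a_eq_m = units.length_si_from_mm(
        contact_radius(protocol.probe_radius_mm, delta_eq_um)
    )
    tau = units.pressure_si(eq_modulus_mpa) * permeability_m4_ns * times_s / a_eq_m**2
    g = 1.304 * np.exp(-np.sqrt(tau)) - 0.304 * np.exp(-0.254 * tau)
    return delta_eq_um * (1.0 - (1.0 - INSTANT_TO_EQ_RATIO) * g)
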