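"""Recover biphasic properties from a measured creep curve.

Nonlinear least squares of the forward creep model against a measured
deformation-time series yields the equilibrium contact modulus E and the
hydraulic permeability k.  Two validity gates accompany every fit:

* whole-curve goodness of fit r^2 >= 0.70 — below it the transient (and with
  it the permeability) is not trusted;
* thin-layer geometry a_eq / h <= 0.55 — when the equilibrium contact radius
  exceeds 55 % of the cartilage thickness the semi-infinite contact
  assumption is violated.

Permeability is reported as valid only when both gates pass.  The
equilibrium modulus is reported whenever the optimizer converges, because
the equilibrium plateau is well fit even on curves whose transient is not:
no modulus data point is dropped by the gates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import units
from .biphasic import (
    CreepCurve,
    MaterialState,
    contact_radius,
    hertz_equilibrium_deflection,
    master_curve_tau_at,
    predict_deformation_um,
)

__all__ = ["FitConfig", "BiphasicFit", "goodness_of_fit_r2", "initial_guess",
           "fit_biphasic", "evaluate_gates"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the creep fit; defaults are the package's fixed contract.

    r2_gate / ah_gate are the permeability validity thresholds.  The
    fallback guesses are used when a curve carries no usable transient
    information (e.g. already at equilibrium).  decrease_tol_um rejects
    non-physical curves whose deformation drops by more than instrument
    noise plausibly allows.
    """

    r2_gate: float = 0.70
    ah_gate: float = 0.55
    thickness_correction: bool = False
    fallback_eq_modulus_mpa: float = 0.5
    fallback_permeability_m4_ns: float = 5e-15
    decrease_tol_um: float = 5.0
    max_nfev: int = 200
    xtol: float = 1e-12
    ftol: float = 1e-12

    def __post_init__(self) -> None:
        if not 0 < self.r2_gate <= 1:
            raise ValueError("r2_gate must lie in (0, 1]")
        if not 0 < self.ah_gate <= 1:
            raise ValueError("ah_gate must lie in (0, 1]")


@dataclass(frozen=True)
class BiphasicFit:
    """Result of fitting one creep curve.

    permeability_valid is True only when the whole-curve r^2 passes the gate
    AND the thin-layer flag is clear; eq_modulus is meaningful whenever
    ``converged`` is True, independent of the gates.
    """

    eq_modulus_mpa: float
    permeability_m4_ns: float
    r_squared: float
    contact_radius_mm: float
    a_over_h: float
    thin_layer_flag: bool
    permeability_valid: bool
    n_points: int
    converged: bool
    message: str = ""


def goodness_of_fit_r2(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Equals 1 iff predicted == observed; can be negative for fits worse than
    the mean.  Raises if the observations carry no variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length 1-D sequences")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed sequence has zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def evaluate_gates(
    r_squared: float, a_over_h: float, config: FitConfig = FitConfig()
) -> tuple[bool, bool]:
    """(thin_layer_flag, permeability_valid) from the two validity rules."""
    thin_layer = bool(a_over_h > config.ah_gate)
    valid = bool(r_squared >= config.r2_gate) and not thin_layer
    return thin_layer, valid


def initial_guess(
    curve: CreepCurve, thickness_mm: float, config: FitConfig = FitConfig()
) -> MaterialState:
    """Starting point for the optimizer.

    E: invert the Hertz relation at the mean of the last 10 % of deformation
    samples (the near-equilibrium plateau).  k: locate the time t_half at
    which the deformation crosses halfway between its first and last values
    and map it through the master curve's half-creep time tau_half, using
    tau = E k t / a_eq^2.  Curves with no usable transient fall back to the
    configured defaults with a logged warning.
    """
    if not thickness_mm > 0:
        raise ValueError("thickness must be positive")
    d = curve.deformation_um
    t = curve.time_s
    n_tail = max(1, int(round(0.1 * d.size)))
    d_end = float(np.mean(d[-n_tail:]))

    proto = curve.protocol
    if d_end <= 0:
        log.warning("non-positive plateau deformation; falling back to default E")
        e_guess = config.fallback_eq_modulus_mpa
    else:
        # invert delta_eq = (3F/(4 E sqrt(R)))^(2/3) for E
        F = units.force_si(proto.creep_load_un)
        R = units.length_si_from_mm(proto.probe_radius_mm)
        delta = units.length_si_from_um(d_end)
        e_guess = units.pressure_mpa(3.0 * F / (4.0 * np.sqrt(R) * delta**1.5))

    half_level = 0.5 * (d[0] + d[-1])
    above = np.nonzero(d >= half_level)[0]
    # need a genuine crossing strictly inside the record
    if d[-1] - d[0] < 1e-9 or above.size == 0 or above[0] == 0:
        log.warning("flat or degenerate transient; falling back to default k")
        k_guess = config.fallback_permeability_m4_ns
    else:
        t_half = float(t[above[0]])
        tau_half = master_curve_tau_at(0.5)
        delta_eq_um = hertz_equilibrium_deflection(
            proto.creep_load_un, proto.probe_radius_mm, e_guess
        )
        a_eq_m = units.length_si_from_mm(
            contact_radius(proto.probe_radius_mm, delta_eq_um)
        )
        k_guess = tau_half * a_eq_m**2 / (units.pressure_si(e_guess) * t_half)

    return MaterialState(
        eq_modulus_mpa=float(e_guess),
        permeability_m4_ns=float(k_guess),
        thickness_mm=thickness_mm,
    )


def fit_biphasic(
    curve: CreepCurve, thickness_mm: float, config: FitConfig = FitConfig()
) -> BiphasicFit:
    """Fit (E, k) to a creep curve by least squares in log-parameter space.

    Ordinary least squares on raw deformation (micrometres, unweighted);
    positivity of both parameters is enforced by optimizing (ln E, ln k)
    with Levenberg-Marquardt.  Deterministic for fixed inputs and config.
    """
    if curve.n_points < 10:
        raise ValueError("need at least 10 samples spanning the creep phase")
    drop = float(np.max(np.maximum.accumulate(curve.deformation_um) - curve.deformation_um))
    if drop > config.decrease_tol_um:
        raise ValueError(
            f"deformation decreases by {drop:.2f} um (> {config.decrease_tol_um} um): "
            "non-physical creep record"
        )

    guess = initial_guess(curve, thickness_mm, config)
    t = curve.time_s
    obs = curve.deformation_um
    proto = curve.protocol

    def residuals(theta: np.ndarray) -> np.ndarray:
        e_mpa, k = np.exp(theta)
        return predict_deformation_um(e_mpa, k, t, proto) - obs

    x0 = np.log([guess.eq_modulus_mpa, guess.permeability_m4_ns])
    res = least_squares(
        residuals,
        x0,
        method="lm",
        xtol=config.xtol,
        ftol=config.ftol,
        max_nfev=config.max_nfev,
    )

    e_mpa, k = np.exp(res.x)
    converged = bool(res.success) and np.all(np.isfinite(res.x))
    if not converged:
        log.warning("creep fit failed to converge: %s", res.message)
        return BiphasicFit(
            eq_modulus_mpa=float("nan"),
            permeability_m4_ns=float("nan"),
            r_squared=float("nan"),
            contact_radius_mm=float("nan"),
            a_over_h=float("nan"),
            thin_layer_flag=False,
            permeability_valid=False,
            n_points=curve.n_points,
            converged=False,
            message=str(res.message),
        )

    pred = predict_deformation_um(e_mpa, k, t, proto)
    r2 = goodness_of_fit_r2(obs, pred)
    delta_eq_um = hertz_equilibrium_deflection(
        proto.creep_load_un, proto.probe_radius_mm, e_mpa
    )
    a_eq_mm = contact_radius(proto.probe_radius_mm, delta_eq_um)
    a_over_h = a_eq_mm / thickness_mm
    thin_layer, valid = evaluate_gates(r2, a_over_h, config)
    return BiphasicFit(
        eq_modulus_mpa=float(e_mpa),
        permeability_m4_ns=float(k),
        r_squared=float(r2),
        contact_radius_mm=float(a_eq_mm),
        a_over_h=float(a_over_h),
        thin_layer_flag=thin_layer,
        permeability_valid=valid,
        n_points=curve.n_points,
        converged=True,
        message=str(res.message),
    )
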