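"""Synthetic cadaver-cohort generator.

Emulates the study design end to end so every pipeline stage can run without
any specimen data: three disease groups (younger healthy/early-stage, elder
healthy/early-stage, advanced OA), up to N donors per group, two bones
(metacarpal, trapezium), six regions per bone.  For every (donor, bone,
region) sample the generator draws ground-truth biphasic parameters and
thickness, synthesizes a creep curve from the forward model plus Gaussian
instrument noise, and produces gravimetric weights consistent with a target
porosity.  Per-donor VLC stiffness is drawn jointly with the donor's
volar-trapezium modulus offset through a bivariate-normal construction so a
target correlation can be imposed (negative in the advanced-OA group, where
ligament attenuation accompanies volar eburnation).

Distributions: truncated normal for modulus, thickness and porosity;
log-normal for permeability.  Group/region means follow the study's
regional pattern — advanced-stage thinning and stiffening concentrated in
the volar-ulnar metacarpal and the volar-central/volar-ulnar trapezium.
Within-group modulus dispersion in the healthy groups is deliberately small
(donor intercept 0.02 MPa, residual 0.02 MPa): it is calibrated so that
healthy equilibrium deformations fall predominantly inside the instrument's
50-80 um healthy window, which bounds the realistic spread around the group
means.  The advanced group is far more heterogeneous (residual 0.15 MPa,
plus a 0.25 MPa donor-level volar-trapezium component), reflecting mixed
cartilage/eburnated-bone surfaces.

Permeability defaults (median 6e-15 m^4/(N s)) are chosen so characteristic
creep times fall well inside the 600-s hold, consistent with the protocol
having been benchmarked to reach equilibrium.

Reproducibility: a single global seed fans out to per-donor substreams
keyed by (seed, group index, donor index), so changing the cohort size
never reshuffles existing donors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .biphasic import (
    CreepCurve,
    IndentationProtocol,
    MaterialState,
    STUDY_PROTOCOL,
    contact_radius,
    forward_creep,
    hertz_equilibrium_deflection,
)
from .composition import DEFAULT_RHO_RATIO, GravimetrySample
from .fitting import BiphasicFit, FitConfig, evaluate_gates
from .stats import BONES, GROUPS, REGIONS, VOLAR_REGIONS, LigamentRecord, RegionalRecord

__all__ = ["CellMeans", "LigamentParams", "CohortSpec", "CohortData",
           "default_spec", "generate_cohort", "records_with_truth_fits"]

log = logging.getLogger(__name__)

Key = tuple[str, str, str]  # (group, bone, region)


@dataclass(frozen=True)
class CellMeans:
    """Target means for one (group, bone, region) cell."""

    e_mpa: float
    thickness_mm: float
    porosity: float


@dataclass(frozen=True)
class LigamentParams:
    """Per-group VLC stiffness distribution and its coupling to cartilage.

    rho is the target correlation between donor-level VLC stiffness and the
    donor's volar-trapezium modulus offset; volar_e_donor_sd_mpa is the
    standard deviation of that offset (the channel through which the
    correlation is realized).
    """

    mean_n_per_mm: float
    sd_n_per_mm: float
    rho: float = 0.0
    volar_e_donor_sd_mpa: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_n_per_mm > 0 or self.sd_n_per_mm < 0:
            raise ValueError("ligament mean must be positive, sd non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("|rho| must be <= 1")
        if self.volar_e_donor_sd_mpa < 0:
            raise ValueError("volar_e_donor_sd_mpa must be non-negative")


def _fill_unprinted(overall_mean: float, fixed: Mapping[tuple[str, str], float],
                    n_cells: int = 12) -> float:
    """Value for cells without a stated mean so the 12-cell average hits the
    stated overall group mean exactly."""
    return (n_cells * overall_mean - sum(fixed.values())) / (n_cells - len(fixed))


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of the synthetic cohort.

    All standard deviations are >= 0; residual sds are per group (healthy
    tissue is far more homogeneous than mixed cartilage/eburnated surfaces).
    """

    n_donors_per_group: int = 6
    seed: int = 0
    noise_sd_um: float = 0.5
    protocol: IndentationProtocol = STUDY_PROTOCOL
    cell_means: Mapping[Key, CellMeans] = field(default_factory=dict)
    donor_sd_e_mpa: float = 0.02
    donor_sd_thickness_mm: float = 0.03
    donor_sd_porosity: float = 0.02
    donor_sd_log_k: float = 0.08
    residual_sd_e_mpa: Mapping[str, float] = field(
        default_factory=lambda: {"younger_healthy_early": 0.02,
                                 "elder_healthy_early": 0.02,
                                 "advanced_oa": 0.15})
    residual_sd_thickness_mm: Mapping[str, float] = field(
        default_factory=lambda: {"younger_healthy_early": 0.04,
                                 "elder_healthy_early": 0.04,
                                 "advanced_oa": 0.06})
    residual_sd_porosity: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.04 for g in GROUPS})
    residual_sd_log_k: float = 0.18
    k_median_m4_ns: float = 6e-15
    # advanced-OA regions often retain little cartilage; their wet weights
    # run small enough that some fall below the balance-reliability floor
    wet_weight_median_mg: Mapping[str, float] = field(
        default_factory=lambda: {"younger_healthy_early": 6.0,
                                 "elder_healthy_early": 5.0,
                                 "advanced_oa": 1.5})
    wet_weight_log_sd: float = 0.6
    rho_ratio: float = DEFAULT_RHO_RATIO
    ligament_params: Mapping[str, LigamentParams] = field(
        default_factory=lambda: {
            "younger_healthy_early": LigamentParams(72.0, 12.0),
            "elder_healthy_early": LigamentParams(58.0, 12.0),
            "advanced_oa": LigamentParams(34.0, 10.0, rho=-0.8,
                                          volar_e_donor_sd_mpa=0.25),
        })

    def __post_init__(self) -> None:
        if self.n_donors_per_group < 1:
            raise ValueError("need at least one donor per group")
        for name in ("noise_sd_um", "donor_sd_e_mpa", "donor_sd_thickness_mm",
                     "donor_sd_porosity", "donor_sd_log_k", "residual_sd_log_k",
                     "wet_weight_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.k_median_m4_ns > 0:
            raise ValueError("k_median_m4_ns must be positive")


# --- default cell means -----------------------------------------------------
# Stated per-region group means where available; remaining cells are filled so
# each group's 12-cell average equals the stated overall group mean (modulus,
# porosity) or a plausible healthy/degenerate level (thickness).

_E_PRINTED: dict[str, dict[tuple[str, str], float]] = {
    "younger_healthy_early": {("metacarpal", "VU"): 0.29,
                              ("trapezium", "VC"): 0.64,
                              ("trapezium", "VU"): 0.42},
    "elder_healthy_early": {("trapezium", "VR"): 0.34,
                            ("trapezium", "VC"): 0.44,
                            ("trapezium", "VU"): 0.43},
    "advanced_oa": {("metacarpal", "VU"): 0.83,
                    ("trapezium", "VR"): 0.86,
                    ("trapezium", "VC"): 1.13,
                    ("trapezium", "VU"): 0.99},
}
_E_OVERALL = {"younger_healthy_early": 0.45,
              "elder_healthy_early": 0.41,
              "advanced_oa": 0.66}

_THICKNESS: dict[str, dict[tuple[str, str], float]] = {
    # stated cells; unlisted cells fall back to the per-group default below
    "younger_healthy_early": {("metacarpal", "DU"): 0.83, ("metacarpal", "VU"): 0.69,
                              ("trapezium", "DR"): 0.72, ("trapezium", "DC"): 0.74,
                              ("trapezium", "DU"): 0.66, ("trapezium", "VC"): 0.72,
                              ("trapezium", "VU"): 0.83},
    "elder_healthy_early": {("metacarpal", "DU"): 0.80, ("metacarpal", "VU"): 0.68,
                            ("trapezium", "DR"): 0.81, ("trapezium", "DC"): 0.63,
                            ("trapezium", "DU"): 0.66, ("trapezium", "VR"): 0.75,
                            ("trapezium", "VC"): 0.71, ("trapezium", "VU"): 0.86},
    "advanced_oa": {("metacarpal", "DU"): 0.54, ("metacarpal", "VU"): 0.25,
                    ("trapezium", "DR"): 0.46, ("trapezium", "DC"): 0.17,
                    ("trapezium", "DU"): 0.41, ("trapezium", "VR"): 0.47,
                    ("trapezium", "VC"): 0.24, ("trapezium", "VU"): 0.44},
}
_THICKNESS_DEFAULT = {"younger_healthy_early": 0.78,
                      "elder_healthy_early": 0.76,
                      "advanced_oa": 0.55}

_PHI_PRINTED: dict[str, dict[tuple[str, str], float]] = {
    "younger_healthy_early": {("trapezium", "DU"): 0.63, ("metacarpal", "DU"): 0.71},
    "elder_healthy_early": {("trapezium", "DU"): 0.83, ("metacarpal", "DU"): 0.87},
    "advanced_oa": {("trapezium", "DU"): 0.81},
}
_PHI_OVERALL = {"younger_healthy_early": 0.76,
                "elder_healthy_early": 0.80,
                "advanced_oa": 0.82}


def _default_cell_means() -> dict[Key, CellMeans]:
    cells: dict[Key, CellMeans] = {}
    for group in GROUPS:
        e_fill = _fill_unprinted(_E_OVERALL[group], _E_PRINTED[group])
        phi_fill = _fill_unprinted(_PHI_OVERALL[group], _PHI_PRINTED[group])
        for bone in BONES:
            for region in REGIONS:
                br = (bone, region)
                cells[(group, bone, region)] = CellMeans(
                    e_mpa=_E_PRINTED[group].get(br, e_fill),
                    thickness_mm=_THICKNESS[group].get(
                        br, _THICKNESS_DEFAULT[group]),
                    porosity=_PHI_PRINTED[group].get(br, phi_fill),
                )
    return cells


def default_spec(**overrides) -> CohortSpec:
    """The study-condition cohort: 6 donors per group, full regional grid."""
    overrides.setdefault("cell_means", _default_cell_means())
    return CohortSpec(**overrides)


# --- generation -------------------------------------------------------------

@dataclass
class CohortData:
    """Everything one synthetic cohort produced.

    records carry thickness and gravimetry (fits are added by the fitting
    stage); curves maps (donor, bone, region) to the noisy creep record;
    truth holds the generating parameters for every sample.
    """

    records: list[RegionalRecord]
    curves: dict[tuple[str, str, str], CreepCurve]
    ligaments: list[LigamentRecord]
    truth: pd.DataFrame
    spec: CohortSpec


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float = np.inf) -> float:
    """Normal draw redrawn into (low, high); clips after 1000 attempts."""
    if sd == 0.0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    log.warning("truncated-normal redraw limit hit (mean=%g sd=%g); clipping", mean, sd)
    return float(np.clip(mean, low, high))


def _donor_rng(seed: int, group_idx: int, donor_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), int(group_idx), int(donor_idx)))
    )


def generate_cohort(spec: CohortSpec | None = None, curves: bool = True) -> CohortData:
    """Draw a full synthetic cohort; reproducible for a fixed spec.seed.

    With curves=False only the scalar truth, gravimetry and ligament tables
    are produced (fast path for statistical studies over many seeds).
    """
    if spec is None:
        spec = default_spec()
    if not spec.cell_means:
        spec = replace(spec, cell_means=_default_cell_means())

    records: list[RegionalRecord] = []
    curve_map: dict[tuple[str, str, str], CreepCurve] = {}
    ligaments: list[LigamentRecord] = []
    truth_rows: list[dict] = []
    prefix = {"younger_healthy_early": "Y", "elder_healthy_early": "E",
              "advanced_oa": "A"}
    times = spec.protocol.creep_times()

    for gi, group in enumerate(GROUPS):
        lig = spec.ligament_params[group]
        for di in range(spec.n_donors_per_group):
            rng = _donor_rng(spec.seed, gi, di)
            donor = f"{prefix[group]}{di + 1:02d}"

            u_e = rng.normal(0.0, spec.donor_sd_e_mpa)
            u_h = rng.normal(0.0, spec.donor_sd_thickness_mm)
            u_phi = rng.normal(0.0, spec.donor_sd_porosity)
            u_logk = rng.normal(0.0, spec.donor_sd_log_k)
            z1 = rng.normal()
            z2 = rng.normal()
            volar_e_offset = lig.volar_e_donor_sd_mpa * z1
            stiffness = lig.mean_n_per_mm + lig.sd_n_per_mm * (
                lig.rho * z1 + np.sqrt(1.0 - lig.rho**2) * z2
            )
            while stiffness <= 0:  # pathological draws only; keeps invariant
                stiffness = rng.normal(lig.mean_n_per_mm, lig.sd_n_per_mm)
            ligaments.append(LigamentRecord(donor, group, float(stiffness)))

            for bone in BONES:
                for region in REGIONS:
                    cell = spec.cell_means[(group, bone, region)]
                    e_mean = cell.e_mpa + u_e
                    if bone == "trapezium" and region in VOLAR_REGIONS:
                        e_mean += volar_e_offset
                    e_mpa = _trunc_normal(rng, e_mean,
                                          spec.residual_sd_e_mpa[group], 0.05)
                    h_mm = _trunc_normal(rng, cell.thickness_mm + u_h,
                                         spec.residual_sd_thickness_mm[group], 0.05)
                    phi = _trunc_normal(rng, cell.porosity + u_phi,
                                        spec.residual_sd_porosity[group],
                                        0.30, 0.97)
                    k = spec.k_median_m4_ns * np.exp(
                        u_logk + rng.normal(0.0, spec.residual_sd_log_k))

                    # water mass fraction tracks porosity (tissue slightly
                    # denser than water); kept below phi/rho_ratio so the
                    # implied PBS weight stays physical
                    wc_hi = 0.985 * phi / spec.rho_ratio
                    wc = _trunc_normal(rng, 0.97 * phi, 0.01, 0.60 * phi, wc_hi)
                    w_wet = spec.wet_weight_median_mg[group] * np.exp(
                        rng.normal(0.0, spec.wet_weight_log_sd))
                    w_wet = max(w_wet, 0.15)
                    w_dry = w_wet * (1.0 - wc)
                    w_pbs = w_wet * (1.0 - wc * spec.rho_ratio / phi)
                    grav = GravimetrySample(w_wet_mg=float(w_wet),
                                            w_pbs_mg=float(w_pbs),
                                            w_dry_mg=float(w_dry),
                                            rho_ratio=spec.rho_ratio)

                    material = MaterialState(eq_modulus_mpa=e_mpa,
                                             permeability_m4_ns=float(k),
                                             thickness_mm=h_mm)
                    if curves:
                        clean = forward_creep(material, spec.protocol, times)
                        noisy = clean.deformation_um + rng.normal(
                            0.0, spec.noise_sd_um, size=times.size)
                        curve_map[(donor, bone, region)] = CreepCurve(
                            time_s=times, deformation_um=noisy,
                            protocol=spec.protocol)

                    records.append(RegionalRecord(
                        donor_id=donor, group=group, bone=bone, region=region,
                        thickness_mm=h_mm, gravimetry=grav))
                    truth_rows.append({
                        "donor_id": donor, "group": group, "bone": bone,
                        "region": region, "e_mpa": e_mpa,
                        "k_m4_ns": float(k), "thickness_mm": h_mm,
                        "porosity": phi, "water_content_pct": 100.0 * wc,
                        "w_wet_mg": float(w_wet), "w_pbs_mg": float(w_pbs),
                        "w_dry_mg": float(w_dry),
                        "vlc_stiffness_n_per_mm": float(stiffness),
                    })

    truth = pd.DataFrame(truth_rows)
    return CohortData(records=records, curves=curve_map, ligaments=ligaments,
                      truth=truth, spec=spec)


def records_with_truth_fits(cohort: CohortData,
                            config: FitConfig = FitConfig()) -> list[RegionalRecord]:
    """Records whose fit slots are filled from the generating truth.

    Stands in for a noiseless, perfectly converged fitting stage (r^2 = 1);
    the geometric thin-layer gate is still evaluated, so gate propagation
    behaves exactly as with real fits.  Useful for statistical studies that
    do not need the curve-fitting stage.
    """
    by_key = {(r["donor_id"], r["bone"], r["region"]): r
              for r in cohort.truth.to_dict("records")}
    out = []
    proto = cohort.spec.protocol
    for rec in cohort.records:
        row = by_key[(rec.donor_id, rec.bone, rec.region)]
        delta_eq = hertz_equilibrium_deflection(
            proto.creep_load_un, proto.probe_radius_mm, row["e_mpa"])
        a_mm = contact_radius(proto.probe_radius_mm, delta_eq)
        a_over_h = a_mm / row["thickness_mm"]
        thin, valid = evaluate_gates(1.0, a_over_h, config)
        fit = BiphasicFit(
            eq_modulus_mpa=row["e_mpa"], permeability_m4_ns=row["k_m4_ns"],
            r_squared=1.0, contact_radius_mm=a_mm, a_over_h=a_over_h,
            thin_layer_flag=thin, permeability_valid=valid,
            n_points=0, converged=True, message="truth")
        out.append(replace(rec, fit=fit))
    return out
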