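"""Regional aggregation and ligament-cartilage correlation statistics.

The unit of aggregation is the (donor, bone, region) record: one cartilage
region of one articular surface of one donor, carrying thickness, the
biphasic fit, and gravimetric composition.  Groups follow the study design
(younger healthy/early-stage, elder healthy/early-stage, advanced OA); each
surface is split into dorsal/volar x radial/central/ulnar sextants.

Summaries are mean +/- SEM per (group, bone, region) cell.  The
ligament-cartilage analysis pairs each donor's volar ligament complex (VLC)
stiffness with that donor's regional cartilage property, pooled over a
region set (by default the volar half: VR, VC, VU), and reports the Pearson
correlation with a two-sided p-value from the exact t transform.
Permeability enters only through records whose fit passed both validity
gates; the equilibrium modulus uses every converged fit.

Group comparison machinery here is cell summaries plus pairwise Welch
t-tests with Bonferroni adjustment — deliberately simpler than a linear
mixed-effects model, and labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .composition import GravimetrySample
from .fitting import BiphasicFit

__all__ = [
    "GROUPS", "BONES", "REGIONS", "VOLAR_REGIONS",
    "RegionalRecord", "LigamentRecord", "CorrelationResult",
    "summarize", "pearson_correlation", "ligament_cartilage_correlation",
    "bonferroni_adjust", "pairwise_group_comparisons", "records_to_frame",
]

GROUPS = ("younger_healthy_early", "elder_healthy_early", "advanced_oa")
BONES = ("metacarpal", "trapezium")
REGIONS = ("DR", "DC", "DU", "VR", "VC", "VU")
VOLAR_REGIONS = ("VR", "VC", "VU")


@dataclass(frozen=True)
class RegionalRecord:
    """All measurements for one (donor, bone, region) cartilage sample."""

    donor_id: str
    group: str
    bone: str
    region: str
    thickness_mm: float
    fit: BiphasicFit | None = None
    gravimetry: GravimetrySample | None = None
    porosity: float | None = None
    water_content: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.bone not in BONES:
            raise ValueError(f"unknown bone {self.bone!r}; expected one of {BONES}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if not self.thickness_mm > 0:
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class LigamentRecord:
    """Per-donor volar ligament complex stiffness (N/mm)."""

    donor_id: str
    group: str
    vlc_stiffness_n_per_mm: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not self.vlc_stiffness_n_per_mm > 0:
            raise ValueError("stiffness must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


def _extract_eq_modulus(rec: RegionalRecord) -> float | None:
    if rec.fit is not None and rec.fit.converged:
        return rec.fit.eq_modulus_mpa
    return None


def _extract_permeability(rec: RegionalRecord) -> float | None:
    # gated: only fits passing both validity rules contribute
    if rec.fit is not None and rec.fit.converged and rec.fit.permeability_valid:
        return rec.fit.permeability_m4_ns
    return None


_MEASURES: dict[str, Callable[[RegionalRecord], float | None]] = {
    "thickness_mm": lambda r: r.thickness_mm,
    "eq_modulus_mpa": _extract_eq_modulus,
    "permeability_m4_ns": _extract_permeability,
    "porosity": lambda r: r.porosity,
    "water_content": lambda r: r.water_content,
}


def measure_names() -> tuple[str, ...]:
    return tuple(_MEASURES)


def records_to_frame(records: Iterable[RegionalRecord], measure: str) -> pd.DataFrame:
    """Tidy frame (donor, group, bone, region, value) for one measure.

    Records without the measure (missing assay, dropped permeability) are
    omitted.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; known: {sorted(_MEASURES)}")
    extract = _MEASURES[measure]
    rows = []
    for rec in records:
        value = extract(rec)
        if value is not None and np.isfinite(value):
            rows.append(
                {"donor_id": rec.donor_id, "group": rec.group, "bone": rec.bone,
                 "region": rec.region, "value": float(value)}
            )
    return pd.DataFrame(rows, columns=["donor_id", "group", "bone", "region", "value"])


def summarize(records: Iterable[RegionalRecord], measure: str) -> pd.DataFrame:
    """Mean, SEM and n of a measure per (group, bone, region) cell.

    SEM = sd / sqrt(n) with the unbiased sd; cells with a single record
    report SEM as NaN (undefined).
    """
    frame = records_to_frame(records, measure)
    if frame.empty:
        raise ValueError(f"no records carry measure {measure!r}")
    out = (
        frame.groupby(["group", "bone", "region"], sort=True)["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    out.loc[out["n"] == 1, "sem"] = np.nan
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    r = cov(x, y) / (sd_x sd_y); p from t = r sqrt((n-2)/(1-r^2)) on n-2
    degrees of freedom.  |r| = 1 returns p = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or xa.shape != ya.shape:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = xa.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(np.dot(dx, dy) / np.sqrt(sxx * syy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, r_squared=r * r, p_value=p, n=n)


def ligament_cartilage_correlation(
    records: Iterable[RegionalRecord],
    ligaments: Iterable[LigamentRecord],
    group: str,
    bone: str,
    measure: str,
    region_set: Sequence[str] = VOLAR_REGIONS,
) -> CorrelationResult:
    """Correlate per-donor VLC stiffness with a pooled cartilage property.

    The per-donor cartilage value is the mean of the measure over
    ``region_set`` on ``bone`` (valid values only: permeability uses gated
    fits).  Donors lacking either the pooled value or a stiffness record are
    dropped; fewer than 3 complete pairs is an error.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    frame = records_to_frame(records, measure)
    frame = frame[
        (frame["group"] == group)
        & (frame["bone"] == bone)
        & frame["region"].isin(region_set)
    ]
    pooled = frame.groupby("donor_id")["value"].mean()
    stiffness = {
        lig.donor_id: lig.vlc_stiffness_n_per_mm
        for lig in ligaments
        if lig.group == group
    }
    donors = sorted(set(pooled.index) & set(stiffness))
    if len(donors) < 3:
        raise ValueError(
            f"only {len(donors)} complete (cartilage, ligament) pairs in group "
            f"{group!r} ({len(pooled)} donors with {measure!r}, "
            f"{len(stiffness)} with stiffness); need >= 3"
        )
    x = [stiffness[d] for d in donors]
    y = [pooled[d] for d in donors]
    return pearson_correlation(x, y)


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni multiplicity adjustment: p -> min(1, m * p).

    m defaults to the number of p-values and must be at least that number.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def pairwise_group_comparisons(
    records: Iterable[RegionalRecord], measure: str
) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups on a measure, Bonferroni-adjusted.

    Operates on all values of the measure pooled within each group (not a
    mixed-effects model: donor correlation is ignored, and the output says
    so in its column naming — p_welch / p_bonferroni).
    """
    frame = records_to_frame(records, measure)
    groups = [g for g in GROUPS if (frame["group"] == g).any()]
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            a = frame.loc[frame["group"] == ga, "value"]
            b = frame.loc[frame["group"] == gb, "value"]
            t, p = sps.ttest_ind(a, b, equal_var=False)
            rows.append({"measure": measure, "group_a": ga, "group_b": gb,
                         "mean_a": a.mean(), "mean_b": b.mean(),
                         "t_welch": float(t), "p_welch": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = bonferroni_adjust(out["p_welch"].to_numpy())
    return out
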