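"""Gravimetric porosity and water content of cartilage samples.

Three weighings per sample: fresh wet weight W_wet, apparent weight W_PBS
while submerged in phosphate-buffered saline (reduced by buoyancy), and dry
weight W_dry after oven desiccation.  Buoyancy gives the tissue volume, the
wet-dry difference gives the fluid mass, and

    porosity      phi_w = (W_wet - W_dry) / (W_wet - W_PBS) * rho_PBS/rho_w
    water content WC    = (W_wet - W_dry) / W_wet * 100     [percent]

Both are homogeneous of degree zero in the weights.  With rho_PBS/rho_w = 1
and W_PBS = 0 the two are algebraically linked: phi_w = WC / 100.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GravimetrySample", "porosity", "water_content",
           "DEFAULT_RHO_RATIO", "MASS_FLOOR_MG"]

#: PBS is marginally denser than water; the ratio is configurable per sample.
DEFAULT_RHO_RATIO = 1.005

#: Below this wet weight (mg) a 0.1 mg-division balance resolves the PBS
#: weighing too coarsely to trust; such samples are flagged, not rejected.
MASS_FLOOR_MG = 0.5


@dataclass(frozen=True)
class GravimetrySample:
    """Wet / PBS-submerged / dry weights of one cartilage sample, in mg."""

    w_wet_mg: float
    w_pbs_mg: float
    w_dry_mg: float
    rho_ratio: float = DEFAULT_RHO_RATIO

    def __post_init__(self) -> None:
        if not self.w_wet_mg > 0:
            raise ValueError("wet weight must be positive")
        if self.w_dry_mg < 0:
            raise ValueError("dry weight must be non-negative")
        if not self.w_wet_mg > self.w_pbs_mg:
            raise ValueError(
                "wet weight must exceed PBS weight (buoyancy reduces apparent weight)"
            )
        if self.w_wet_mg < self.w_dry_mg:
            raise ValueError("dry weight cannot exceed wet weight")
        if not self.rho_ratio > 0:
            raise ValueError("rho_ratio must be positive")

    @property
    def low_mass_flag(self) -> bool:
        """True when the wet weight sits below the balance-reliability floor."""
        return self.w_wet_mg < MASS_FLOOR_MG


def porosity(sample: GravimetrySample) -> float:
    """Water-volume fraction phi_w from buoyancy gravimetry (dimensionless)."""
    return (
        (sample.w_wet_mg - sample.w_dry_mg)
        / (sample.w_wet_mg - sample.w_pbs_mg)
        * sample.rho_ratio
    )


def water_content(sample: GravimetrySample) -> float:
    """Water mass fraction of the wet tissue, in percent (0-100)."""
    return (sample.w_wet_mg - sample.w_dry_mg) / sample.w_wet_mg * 100.0
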