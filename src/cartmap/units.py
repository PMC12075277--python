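"""Unit conversions between bench units and SI.

All physics inside the package is computed in SI (N, m, s, Pa, m^4/(N s)).
Public interfaces speak the units an indentation bench reports: forces in
micronewtons, deflections in micrometres, probe radii and thicknesses in
millimetres, moduli in megapascals.  Permeability is already SI in the
field's convention and passes through unchanged.
"""

from __future__ import annotations

# multiply a bench-unit value by the constant to get SI
UN_TO_N = 1e-6    # micronewton -> newton
UM_TO_M = 1e-6    # micrometre -> metre
MM_TO_M = 1e-3    # millimetre -> metre
MPA_TO_PA = 1e6   # megapascal -> pascal


def force_si(value_un: float) -> float:
    """Force in newtons from micronewtons."""
    return value_un * UN_TO_N


def length_si_from_mm(value_mm: float) -> float:
    return value_mm * MM_TO_M


def length_si_from_um(value_um: float) -> float:
    return value_um * UM_TO_M


def length_mm(value_m: float) -> float:
    return value_m / MM_TO_M


def length_um(value_m: float) -> float:
    return value_m / UM_TO_M


def pressure_si(value_mpa: float) -> float:
    return value_mpa * MPA_TO_PA


def pressure_mpa(value_pa: float) -> float:
    return value_pa / MPA_TO_PA
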