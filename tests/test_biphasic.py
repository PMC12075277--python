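"""Forward biphasic indentation model: closed forms, limits, scaling laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from cartmap import (
    CreepCurve,
    IndentationProtocol,
    MaterialState,
    STUDY_PROTOCOL,
    contact_radius,
    forward_creep,
    hertz_equilibrium_deflection,
    master_curve_g,
    thickness_correction_factor,
)
from cartmap.biphasic import INSTANT_TO_EQ_RATIO, master_curve_tau_at


class TestHertzEquilibrium:
    def test_printed_healthy_parameters_give_midrange_deflection(self):
        # 5000 uN, R = 0.5 mm, E = 0.45 MPa -> 51.79 um, inside the
        # instrument's 50-80 um healthy-cartilage window
        d = hertz_equilibrium_deflection(5000.0, 0.5, 0.45)
        assert d == pytest.approx(51.787, rel=1e-3)
        assert 50.0 <= d <= 80.0

    def test_force_scaling_exponent_two_thirds(self):
        d1 = hertz_equilibrium_deflection(5000.0, 0.5, 0.45)
        d8 = hertz_equilibrium_deflection(8 * 5000.0, 0.5, 0.45)
        assert d8 == pytest.approx(4.0 * d1, rel=1e-12)

    def test_modulus_doubling_scales_by_two_to_minus_two_thirds(self):
        d = hertz_equilibrium_deflection(5000.0, 0.5, 0.45)
        d2 = hertz_equilibrium_deflection(5000.0, 0.5, 0.9)
        assert d2 == pytest.approx(d * 2 ** (-2 / 3), rel=1e-12)
        assert d2 == pytest.approx(32.624, rel=1e-3)

    @pytest.mark.parametrize("f,r,e", [(0, 0.5, 0.45), (5000, -1, 0.45),
                                       (5000, 0.5, 0)])
    def test_nonpositive_inputs_rejected(self, f, r, e):
        with pytest.raises(ValueError):
            hertz_equilibrium_deflection(f, r, e)

    def test_closed_form_matches_numeric_inversion_of_force_relation(self):
        # independent oracle: solve F = (4/3) E sqrt(R) delta^1.5 numerically
        rng = np.random.default_rng(42)
        for _ in range(100):
            f_un = rng.uniform(500, 20000)
            r_mm = rng.uniform(0.2, 2.0)
            e_mpa = rng.uniform(0.1, 3.0)
            F, R, E = f_un * 1e-6, r_mm * 1e-3, e_mpa * 1e6

            def force_balance(delta_m):
                return (4.0 / 3.0) * E * np.sqrt(R) * delta_m**1.5 - F

            delta_oracle = brentq(force_balance, 1e-12, 1e-2, xtol=1e-18)
            d = hertz_equilibrium_deflection(f_un, r_mm, e_mpa)
            assert abs(d - delta_oracle * 1e6) / (delta_oracle * 1e6) < 1e-10


class TestContactRadius:
    @pytest.mark.parametrize("delta_um,expected_mm", [
        (0.0, 0.0),
        (51.8, 0.16094),       # sqrt(0.5 mm * 51.8 um)
        (200.0, 0.31623),      # sqrt(0.1) mm
    ])
    def test_hertz_geometry(self, delta_um, expected_mm):
        assert contact_radius(0.5, delta_um) == pytest.approx(expected_mm, abs=1e-4)

    def test_zero_only_at_zero_deflection(self):
        assert contact_radius(0.5, 0.0) == 0.0
        assert contact_radius(0.5, 1e-9) > 0.0


class TestMasterCurve:
    def test_limits(self):
        assert master_curve_g(0.0) == pytest.approx(1.0, abs=1e-15)
        assert master_curve_g(1e6) == pytest.approx(0.0, abs=1e-12)
        assert master_curve_g(1.0) == pytest.approx(0.2439045, abs=1e-6)

    def test_nonincreasing_on_log_grid(self):
        tau = np.logspace(-4, 3, 4000)
        g = master_curve_g(tau)
        assert np.all(np.diff(g) <= 1e-14)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            master_curve_g(-0.1)

    def test_inverse_lookup_round_trips(self):
        for level in (0.9, 0.5, 0.1):
            tau = master_curve_tau_at(level)
            assert master_curve_g(tau) == pytest.approx(level, abs=1e-10)


class TestThicknessCorrection:
    def test_semi_infinite_limit_and_disabled_hook(self):
        assert thickness_correction_factor(0.0, enabled=True) == 1.0
        assert thickness_correction_factor(0.9, enabled=False) == 1.0

    def test_bonded_layer_polynomial_stiffens_monotonically(self):
        chi_03 = thickness_correction_factor(0.3, enabled=True)
        chi_06 = thickness_correction_factor(0.6, enabled=True)
        assert 1.0 < chi_03 < chi_06
        assert chi_03 == pytest.approx(1.47692, abs=1e-4)

    def test_corrected_equilibrium_deflection_is_smaller(self):
        thin = MaterialState(0.45, 6e-15, 0.3)
        plain = forward_creep(thin, STUDY_PROTOCOL, thickness_correction=False)
        corr = forward_creep(thin, STUDY_PROTOCOL, thickness_correction=True)
        assert corr.deformation_um[-1] < plain.deformation_um[-1]


class TestForwardCreep:
    def test_single_time_returns_instantaneous_deflection(self, healthy_material):
        curve = forward_creep(healthy_material, STUDY_PROTOCOL, times_s=[0.0])
        d_eq = hertz_equilibrium_deflection(5000.0, 0.5, 0.5)
        assert curve.deformation_um[0] == pytest.approx(
            INSTANT_TO_EQ_RATIO * d_eq, rel=1e-12)

    def test_monotone_nondecreasing_toward_equilibrium(self, clean_curve):
        assert np.all(np.diff(clean_curve.deformation_um) >= -1e-12)

    @pytest.mark.parametrize("e_mpa", [0.2, 0.45, 1.0, 2.0])
    @pytest.mark.parametrize("k", [5e-15, 1e-14])
    def test_equilibrium_reached_within_one_percent_on_physiological_grid(
            self, e_mpa, k):
        # physiological band: parameters whose creep time constant fits the
        # 600-s hold (the protocol was designed to reach equilibrium)
        material = MaterialState(e_mpa, k, 0.7)
        curve = forward_creep(material, STUDY_PROTOCOL)
        d_eq = hertz_equilibrium_deflection(5000.0, 0.5, e_mpa)
        ratio = curve.deformation_um[-1] / d_eq
        assert 0.99 <= ratio <= 1.0
        assert curve.deformation_um[0] / d_eq == pytest.approx(
            INSTANT_TO_EQ_RATIO, abs=1e-12)

    def test_doubling_permeability_halves_half_creep_time(self):
        # tau is linear in k, so the time of any fixed transient level halves
        t = np.linspace(0.0, 600.0, 24001)
        c1 = forward_creep(MaterialState(0.5, 2e-15, 0.7), STUDY_PROTOCOL, t)
        c2 = forward_creep(MaterialState(0.5, 4e-15, 0.7), STUDY_PROTOCOL, t)
        d_eq = hertz_equilibrium_deflection(5000.0, 0.5, 0.5)
        level = 0.5 * (1.0 + INSTANT_TO_EQ_RATIO) * d_eq

        def t_half(c):
            return np.interp(level, c.deformation_um, c.time_s)

        assert t_half(c1) == pytest.approx(2 * t_half(c2), rel=1e-3)

    def test_empty_time_vector_rejected(self, healthy_material):
        with pytest.raises(ValueError):
            forward_creep(healthy_material, STUDY_PROTOCOL, times_s=[])


class TestDomainTypes:
    def test_protocol_invariants(self):
        with pytest.raises(ValueError):
            IndentationProtocol(creep_load_un=50.0)  # below preload
        with pytest.raises(ValueError):
            IndentationProtocol(probe_radius_mm=0.0)

    def test_material_contract(self):
        with pytest.raises(ValueError):
            MaterialState(-0.1, 1e-15, 0.5)
        with pytest.raises(ValueError):
            MaterialState(0.5, 1e-15, 0.5, poisson_nu=0.3)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            CreepCurve(time_s=[0.0, 2.0, 1.0], deformation_um=[1, 2, 3])
        with pytest.raises(ValueError):
            CreepCurve(time_s=[1.0, 2.0], deformation_um=[1, 2])  # not from 0
        with pytest.raises(ValueError):
            CreepCurve(time_s=[0.0, 1.0], deformation_um=[1, np.nan])


@settings(max_examples=60, derandomize=True)
@given(
    f=st.floats(100, 50000), r=st.floats(0.1, 5.0), e=st.floats(0.05, 10.0),
    s=st.floats(1.1, 10.0),
)
def test_hertz_deflection_scaling_property(f, r, e, s):
    """delta_eq scales as F^(2/3) and E^(-2/3) for any positive inputs."""
    base = hertz_equilibrium_deflection(f, r, e)
    assert hertz_equilibrium_deflection(s * f, r, e) == pytest.approx(
        s ** (2 / 3) * base, rel=1e-9)
    assert hertz_equilibrium_deflection(f, r, s * e) == pytest.approx(
        s ** (-2 / 3) * base, rel=1e-9)
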