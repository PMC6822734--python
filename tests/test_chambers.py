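"""Chamber mechanics: geometry inversion, activation waveforms, pressure laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heartloop.chambers import (
    AtriumParams,
    VentricleParams,
    atrial_activation,
    atrial_elastance,
    atrium_pressure,
    radius_from_volume,
    ventricle_active_pressure,
    ventricle_passive_pressure,
    ventricle_pressure,
    ventricular_activation,
    volume_from_radius,
)

LV = VentricleParams(l=8, K=1.15, V0=15, E_es=2.5, A=1, B=0.02,
                     T1=0.264, T2=0.36, T=0.8, axis_divisor=2)
RV = VentricleParams(l=8, K=1.75, V0=40, E_es=1.0, A=1, B=0.02,
                     T1=0.264, T2=0.36, T=0.8, axis_divisor=4)
LA = AtriumParams(l=5.5, K=1.20, V0=5, E_max=0.3, E_min=0.2,
                  Ta=0.64, T=0.8, D=0.04)


class TestGeometry:
    @pytest.mark.parametrize("p, r, expected", [
        (LV, 0.0, 0.0),
        # direct evaluation of (4/3)*pi*K*r^2*(l/divisor)
        (LV, 2.5470, (4 / 3) * math.pi * 1.15 * 2.5470**2 * 4),
        (RV, 2.6118, (4 / 3) * math.pi * 1.75 * 2.6118**2 * 2),
    ])
    def test_volume_from_radius(self, p, r, expected):
        assert volume_from_radius(r, p) == pytest.approx(expected, rel=1e-12)

    def test_half_ellipsoid_radii_reproduce_printed_volumes(self):
        # the printed healthy-adult LV EDV of 125 mL corresponds to a
        # 2.547 cm radius, i.e. a 5.09 cm diameter (LVEDD 5.08 to rounding)
        r = radius_from_volume(125.0, LV)
        assert r == pytest.approx(2.547, abs=5e-4)
        assert 2 * r == pytest.approx(5.08, abs=0.02)
        assert volume_from_radius(2.5470, LV) == pytest.approx(125.0, abs=0.01)
        assert volume_from_radius(2.6118, RV) == pytest.approx(100.0, abs=0.01)

    def test_zero_volume_gives_zero_radius(self):
        assert radius_from_volume(0.0, LV) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            volume_from_radius(-1.0, LV)
        with pytest.raises(ValueError):
            radius_from_volume(-1.0, LV)

    @pytest.mark.parametrize("p", [LV, RV, LA])
    @given(r=st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_radius_volume_roundtrip(self, p, r):
        back = radius_from_volume(volume_from_radius(r, p), p)
        assert abs(back - r) < 1e-12 * r

    @given(c=st.floats(min_value=0.25, max_value=4.0),
           V=st.floats(min_value=1.0, max_value=300.0),
           t=st.floats(min_value=0.0, max_value=0.8))
    @settings(max_examples=50, deadline=None)
    def test_K_scaling_changes_diameter_not_pressure(self, c, V, t):
        # scaling K by c at fixed volume shrinks r by c^(-1/2) but leaves
        # the pressure-volume behaviour untouched
        scaled = VentricleParams(l=8, K=1.15 * c, V0=15, E_es=2.5, A=1, B=0.02,
                                 T1=0.264, T2=0.36, T=0.8)
        r1, r2 = radius_from_volume(V, LV), radius_from_volume(V, scaled)
        assert r2 == pytest.approx(r1 * c ** -0.5, rel=1e-12)
        assert ventricle_pressure(r2, t, scaled) == pytest.approx(
            ventricle_pressure(r1, t, LV), rel=1e-12)


class TestVentricularActivation:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 0.0),
        (LV.T1, 1.0),               # peak by construction
        (LV.T1 / 2, 0.5),           # (1 - cos(pi/2)) / 2
        (LV.T2, 0.0),
        (LV.T - 1e-9, 0.0),
    ])
    def test_values(self, t, expected):
        assert ventricular_activation(t, LV) == pytest.approx(expected, abs=1e-8)

    def test_continuity_at_branch_points_and_wrap(self):
        for t_star in (LV.T1, LV.T2, LV.T):
            below = ventricular_activation(t_star - 1e-9, LV)
            above = ventricular_activation(t_star + 1e-9, LV)
            assert below == pytest.approx(above, abs=1e-6)

    def test_bounded_and_zero_late(self):
        t = np.linspace(0, LV.T, 4001, endpoint=False)
        f = ventricular_activation(t, LV)
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(f[t >= LV.T2] == 0)

    def test_time_reduced_modulo_cycle(self):
        assert ventricular_activation(LV.T + 0.1, LV) == pytest.approx(
            ventricular_activation(0.1, LV), rel=1e-12)


class TestAtrialActivationAndElastance:
    def test_activation_values(self):
        assert atrial_activation(LA.Ta, LA) == 0.0
        mid = LA.Ta + (LA.T - LA.Ta) / 2
        assert atrial_activation(mid, LA) == pytest.approx(2.0)
        assert atrial_activation(LA.T - 1e-9, LA) == pytest.approx(0.0, abs=1e-6)
        assert atrial_activation(0.1, LA) == 0.0

    def test_continuity_at_onset_and_wrap(self):
        assert atrial_activation(LA.Ta + 1e-9, LA) == pytest.approx(0.0, abs=1e-6)
        # wrap T -> 0 is continuous at 0
        assert atrial_activation(1e-9, LA) == pytest.approx(
            atrial_activation(LA.T - 1e-9, LA), abs=1e-6)

    def test_cosine_symmetry_integral(self):
        # integral of (activation - 1) over the active window vanishes
        t = np.linspace(LA.Ta, LA.T, 20001)
        f = atrial_activation(t, LA)
        assert np.trapezoid(f - 1.0, t) == pytest.approx(0.0, abs=1e-6)

    def test_elastance_range_and_midpoint(self):
        t = np.linspace(0, LA.T, 8001, endpoint=False)
        E = atrial_elastance(t, LA)
        assert E.min() == pytest.approx(LA.E_min, abs=1e-6)
        assert E.max() == pytest.approx(LA.E_max, abs=1e-6)
        # activation = 1 -> midpoint elastance
        half = AtriumParams(l=5.5, K=1.2, V0=5, E_max=0.3, E_min=0.2,
                            Ta=0.64, T=0.8, D=0.0)
        t_mid = half.Ta + (half.T - half.Ta) / 4  # cos(pi/2): activation 1
        assert atrial_elastance(t_mid, half) == pytest.approx(0.25, rel=1e-9)

    def test_delay_wraps_across_cycle_boundary(self):
        # with D > 0 the activation burst seen at t in [0, D) comes from
        # the tail of the previous cycle
        undelayed = AtriumParams(l=5.5, K=1.2, V0=5, E_max=0.3, E_min=0.2,
                                 Ta=0.64, T=0.8, D=0.0)
        t = np.linspace(0, LA.T, 1601, endpoint=False)
        shifted = atrial_elastance(np.mod(t - LA.D, LA.T), undelayed)
        assert np.allclose(atrial_elastance(t, LA), shifted, atol=1e-12)


class TestPressureLaws:
    def test_active_pressure_zero_cases(self):
        assert ventricle_active_pressure(LV.r0, 0.5, LV) == pytest.approx(0.0, abs=1e-9)
        assert ventricle_active_pressure(3.0, 0.0, LV) == pytest.approx(0.0, abs=1e-9)

    def test_active_pressure_product(self):
        # E_es * (V - V0) * f_act with f_act = 1 at t = T1
        r = radius_from_volume(125.0, LV)  # V - V0 = 110
        assert ventricle_active_pressure(r, LV.T1, LV) == pytest.approx(275.0, rel=1e-9)

    @pytest.mark.parametrize("V, expected", [
        (0.0, 0.0),                      # A*e^0 - 1 with A = 1
        (125.0, math.e**2.5 - 1.0),      # 11.18 mmHg
        (173.0, math.e**3.46 - 1.0),     # 30.79 mmHg
    ])
    def test_passive_pressure(self, V, expected):
        r = radius_from_volume(V, LV)
        assert ventricle_passive_pressure(r, LV) == pytest.approx(expected, rel=1e-9)

    def test_passive_operator_order_switch(self):
        # A*exp(BV) - 1 vs A*(exp(BV) - 1) differ by the constant A - 1
        dcm = VentricleParams(l=8, K=0.95, V0=25, E_es=0.9, A=0.65, B=0.02,
                              T1=0.264, T2=0.36, T=0.8)
        dcm_alt = VentricleParams(l=8, K=0.95, V0=25, E_es=0.9, A=0.65, B=0.02,
                                  T1=0.264, T2=0.36, T=0.8, subtract_A=True)
        r = radius_from_volume(140.0, dcm)
        assert (ventricle_passive_pressure(r, dcm)
                - ventricle_passive_pressure(r, dcm_alt)) == pytest.approx(
            dcm.A - 1.0, rel=1e-9)

    @given(r=st.floats(min_value=0.0, max_value=6.0),
           t=st.floats(min_value=0.0, max_value=0.8))
    @settings(max_examples=100, deadline=None)
    def test_total_pressure_is_sum_of_components(self, r, t):
        assert ventricle_pressure(r, t, LV) == pytest.approx(
            ventricle_active_pressure(r, t, LV) + ventricle_passive_pressure(r, LV),
            rel=1e-12, abs=1e-12)

    def test_active_pressure_increasing_in_radius(self):
        rs = np.linspace(LV.r0 + 1e-3, 6.0, 50)
        ps = ventricle_active_pressure(rs, LV.T1 / 2, LV)
        assert np.all(np.diff(ps) > 0)

    def test_atrium_pressure(self):
        assert atrium_pressure(LA.r0, 0.3, LA) == pytest.approx(0.0, abs=1e-9)
        # constant-elastance atrium: E * (V - V0)
        flat = AtriumParams(l=5.5, K=1.2, V0=5, E_max=0.25, E_min=0.25,
                            Ta=0.64, T=0.8, D=0.04)
        r = radius_from_volume(45.0, flat)
        for t in (0.0, 0.3, 0.7):
            assert atrium_pressure(r, t, flat) == pytest.approx(10.0, rel=1e-9)


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(l=-8), dict(K=0), dict(V0=-1), dict(E_es=0), dict(B=-0.02),
        dict(T1=0.5, T2=0.4), dict(axis_divisor=3),
    ])
    def test_ventricle_invariants_enforced(self, kwargs):
        base = dict(l=8, K=1.15, V0=15, E_es=2.5, A=1, B=0.02,
                    T1=0.264, T2=0.36, T=0.8)
        base.update(kwargs)
        with pytest.raises(ValueError):
            VentricleParams(**base)

    @pytest.mark.parametrize("kwargs", [
        dict(E_max=0.1, E_min=0.2), dict(E_min=0), dict(Ta=0.9),
        dict(D=0.9), dict(axis_divisor=4),
    ])
    def test_atrium_invariants_enforced(self, kwargs):
        base = dict(l=5.5, K=1.2, V0=5, E_max=0.3, E_min=0.2,
                    Ta=0.64, T=0.8, D=0.04)
        base.update(kwargs)
        with pytest.raises(ValueError):
            AtriumParams(**base)
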