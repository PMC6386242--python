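"""Closed-form parametrizations: frozen examples and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coastbloom as cb
from coastbloom.params import Environment


@pytest.mark.parametrize("x, s, expected", [
    (0.0, 4.0, 0.5),
    (50.0, 1.0, 0.0),
    (-1.0, 4.0, 1.0 / (1.0 + math.exp(-4.0))),
    (1e6, 4.0, 0.0),      # exponent clamp must saturate, not overflow
    (-1e6, 4.0, 1.0),
])
def test_sigmoid_step_values(x, s, expected):
    assert cb.sigmoid_step(x, s) == pytest.approx(expected, abs=1e-12)


def test_sigmoid_step_rejects_negative_steepness():
    with pytest.raises(ValueError):
        cb.sigmoid_step(0.0, -1.0)


@settings(deadline=None, derandomize=True)
@given(st.floats(-100, 100), st.floats(0, 50))
def test_sigmoid_point_symmetry(x, s):
    assert cb.sigmoid_step(x, s) + cb.sigmoid_step(-x, s) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("j, l, expected", [
    (20.0, 20.0, 1.0),
    (202.5, 20.0, 0.0),
    (111.25, 20.0, 0.5),
])
def test_seasonal_eta_values(j, l, expected):
    assert cb.seasonal_eta(j, l) == pytest.approx(expected, abs=1e-12)


def test_seasonal_eta_annual_mean():
    """The harmonic integrates to half a year over one annual cycle."""
    from scipy.integrate import quad

    total, _ = quad(lambda j: cb.seasonal_eta(j, 20.0), 0.0, 365.0, limit=200)
    assert total == pytest.approx(182.5, abs=1e-6)


def _env(h=10.0, s=30.0, t=10.0, i0=100.0, eps_b=0.0, j=20.0):
    return Environment(h=h, s=s, t=t, i0=i0, eps_b=eps_b, j=j)


class TestSpmAttenuation:
    def test_background_only_when_alpha_one(self, params):
        p = params.replace(alpha=1.0)
        assert cb.spm_attenuation(_env(), p) == pytest.approx(p.a_spm_prime)

    def test_winter_shallow_limit(self, params):
        # eta = 1, depth sigmoid ~ 1, no event term: a' (1 + alpha) / 2
        env = _env(h=0.01, j=params.l_turb, eps_b=0.0)
        expected = params.a_spm_prime * (1.0 + params.alpha) / 2.0
        assert cb.spm_attenuation(env, params) == pytest.approx(expected, rel=1e-3)

    def test_summer_deep_critical_dissipation(self, params):
        env = _env(h=1e4, j=params.l_turb + 182.5, eps_b=params.eps_star)
        expected = params.a_spm_prime * (1.0 + params.alpha) / 2.0
        assert cb.spm_attenuation(env, params) == pytest.approx(expected, rel=1e-6)

    def test_zero_eps_star_is_an_error(self, params):
        with pytest.raises(ValueError):
            cb.spm_attenuation(_env(), params.replace(eps_star=0.0))

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 60), st.floats(0, 5e-5), st.floats(0, 365))
    def test_background_lower_bound(self, h, eps_b, j):
        p = cb.CoastalParams.default()
        val = cb.spm_attenuation(_env(h=h, eps_b=eps_b, j=j), p)
        assert val >= p.a_spm_prime * p.alpha - 1e-12


class TestVicinityIndex:
    @pytest.mark.parametrize("h, s, expected, tol", [
        (20.0, 31.0, 0.5, 1e-4),           # both primary sigmoids at 1/2
        (1e4, 1e-6, 1.5, 1e-5),            # estuarine limit
        (1e4, 34.0, 0.047426, 1e-5),       # offshore limit
    ])
    def test_values(self, params, h, s, expected, tol):
        assert cb.coastal_vicinity_index(h, s, params) == pytest.approx(expected, abs=tol)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(1, 60), min_size=2, max_size=8),
           st.lists(st.floats(0, 36), min_size=2, max_size=8))
    def test_monotone_non_increasing(self, hs, ss):
        p = cb.CoastalParams.default()
        hs, ss = sorted(hs), sorted(ss)
        vals_h = [cb.coastal_vicinity_index(h, 30.0, p) for h in hs]
        vals_s = [cb.coastal_vicinity_index(10.0, s, p) for s in ss]
        assert all(a >= b - 1e-12 for a, b in zip(vals_h, vals_h[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(vals_s, vals_s[1:]))
        assert all(0.0 <= v <= 1.5 for v in vals_h + vals_s)


@pytest.mark.parametrize("dt, expected", [(0.0, 1.0), (10.0, 2.0), (-10.0, 0.5)])
def test_temperature_factor_q10(params, dt, expected):
    assert cb.temperature_factor(params.t_ref + dt, params) == pytest.approx(expected)


class TestZooplanktonMortality:
    def test_vanishes_offshore(self, params):
        env = _env(h=1e4, s=45.0, j=250.0)
        assert cb.zooplankton_mortality(env, 1.0, params) == pytest.approx(0.0, abs=1e-4)

    def test_vanishes_without_drivers(self, params):
        env = _env(j=params.l_carn + 182.5)
        assert cb.zooplankton_mortality(env, 0.0, params) == pytest.approx(0.0, abs=1e-15)

    def test_printed_amplitude_at_seasonal_peak(self, params):
        """At the carnivory peak with unit vicinity, unit f_T and no
        density dependence the rate equals the mortality amplitude."""
        env = _env(t=params.t_ref, j=250.0)
        val = cb.zooplankton_mortality(env, 0.0, params, vicinity=1.0)
        assert val == pytest.approx(0.025, rel=1e-12)


@pytest.mark.parametrize("k, vic, expected", [
    (1.0, 0.0, 0.5), (1.0, 1.5, 2.0), (2.0, 0.5, 2.0)])
def test_grazing_half_saturation(k, vic, expected):
    assert cb.grazing_half_saturation(k, vic) == pytest.approx(expected)


class TestViralHostMortality:
    def test_half_loss_at_critical_density(self, params):
        assert cb.viral_host_mortality(1.0, params) == pytest.approx(0.5)

    def test_low_density_value(self, params):
        assert cb.viral_host_mortality(0.0, params) == pytest.approx(
            1.0 / (1.0 + math.exp(4.0)), rel=1e-9)

    def test_saturates_at_proportionality_constant(self, params):
        assert cb.viral_host_mortality(100.0, params) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 50), min_size=2, max_size=10))
    def test_monotone_and_bounded(self, vs):
        p = cb.CoastalParams.default()
        vs = sorted(vs)
        vals = [cb.viral_host_mortality(v, p) for v in vs]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= p.m_vir_max for v in vals)
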