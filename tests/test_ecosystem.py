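"""Backbone fluxes, elemental conservation, and integrator accuracy."""

import numpy as np
import pytest

import coastbloom as cb
from coastbloom import experiments as xp
from coastbloom.ecosystem import (EcosystemState, ecosystem_derivative,
                                  integrate, mass_balance, _IDX)
from coastbloom.params import Environment


def _env(**kw):
    base = dict(h=10.0, s=30.0, t=10.0, i0=100.0, eps_b=0.0, j=100.0)
    base.update(kw)
    return Environment(**base)


class TestLimitations:
    def test_light_dark_and_saturation(self, params):
        assert cb.light_limitation(0.0, 0.2, 10.0, params) == 0.0
        assert cb.light_limitation(1e9, 0.2, 10.0, params) == pytest.approx(1.0, abs=1e-6)

    def test_light_optically_thin_limit(self, params):
        i0 = 80.0
        val = cb.light_limitation(i0, 1e-10, 1.0, params)
        assert val == pytest.approx(i0 / (i0 + params.i_k), rel=1e-6)

    def test_nutrient_liebig(self, params):
        assert cb.nutrient_limitation(0.0, 5.0, params) == 0.0
        assert cb.nutrient_limitation(params.k_din, 1e9, params) == pytest.approx(0.5)
        assert cb.nutrient_limitation(1e12, 1e12, params) == pytest.approx(1.0, abs=1e-9)


class TestGrazing:
    def test_zero_prey(self, params):
        assert cb.ecosystem.grazing_flux(0.0, 1.0, 0.5, 10.0, params) == 0.0

    def test_half_saturation_point(self, params):
        k_scaled = cb.grazing_half_saturation(params.k_graz_base, 0.5)
        flux = cb.ecosystem.grazing_flux(k_scaled, 2.0, 0.5, params.t_ref, params)
        assert flux == pytest.approx(params.g_max * 2.0 / 2.0)

    def test_decreases_with_vicinity(self, params):
        fluxes = [cb.ecosystem.grazing_flux(5.0, 1.0, v, 10.0, params)
                  for v in (0.0, 0.5, 1.0, 1.5)]
        assert all(a > b for a, b in zip(fluxes, fluxes[1:]))


class TestDerivative:
    def test_closed_system_conserves_elements(self, params):
        """All internal transfers cancel in the N and P (and C) totals."""
        p = params.replace(f_denit=0.0, f_burial=0.0)
        state = EcosystemState(Phy=20.0, Zoo=3.0, v=0.5, DetC=5.0,
                               DetN=0.7, DetP=0.05, DOC=4.0, DON=0.6, DOP=0.04)
        env = _env()
        dy = ecosystem_derivative(state, env, p)
        h = env.h
        dn = h * (dy[_IDX["DIN"]] + p.q_n * (dy[_IDX["Phy"]] + dy[_IDX["Zoo"]])
                  + dy[_IDX["DetN"]] + dy[_IDX["DON"]]) + dy[_IDX["BenN"]]
        dp = h * (dy[_IDX["DIP"]] + p.q_p * (dy[_IDX["Phy"]] + dy[_IDX["Zoo"]])
                  + dy[_IDX["DetP"]] + dy[_IDX["DOP"]]) + dy[_IDX["BenP"]]
        dc = h * (dy[_IDX["DIC"]] + dy[_IDX["Phy"]] + dy[_IDX["Zoo"]]
                  + dy[_IDX["DetC"]] + dy[_IDX["DOC"]]) + dy[_IDX["BenC"]]
        assert abs(dn) < 1e-12 and abs(dp) < 1e-12 and abs(dc) < 1e-10

    def test_dark_no_grazers_only_aggregation(self, params):
        state = EcosystemState(Phy=10.0, Zoo=0.0, v=0.0, DIN=0.0, DIP=0.0)
        p = params.replace(m_vir_max=0.0)
        dy = ecosystem_derivative(state, _env(i0=0.0), p)
        assert dy[_IDX["Phy"]] == pytest.approx(-p.m_agg * 100.0, rel=1e-9)
        assert dy[_IDX["Phy"]] <= 0.0

    def test_no_virus_scenario_derivative_nonpositive(self, params):
        for phy, v in [(50.0, 0.01), (5.0, 2.0), (0.0, 0.5)]:
            state = EcosystemState(Phy=phy, v=v)
            dy = ecosystem_derivative(state, _env(), params, n_rep_factor=0.0)
            assert dy[_IDX["v"]] <= 0.0


class TestIntegrate:
    def test_zero_rate_configuration_constant(self, params, smooth_forcing):
        p = params.replace(mu_max=0, g_max=0, m_agg=0, w_det=0, r_det=0,
                           r_dom=0, r_ben=0, m_z_prime=0, r_zoo_basal=0,
                           m_vir_max=0, k_ads=0, k_defense=0, k_decay=0,
                           f_denit=0.0, f_burial=0.0)
        s0 = EcosystemState(Phy=5.0, Zoo=1.0)
        traj = integrate(s0, smooth_forcing, 0.05, 10.0, p, output_every=1.5)
        np.testing.assert_allclose(traj.states[-1], traj.states[0], rtol=0, atol=1e-14)

    def test_exponential_decay_oracle(self, params, smooth_forcing):
        """Single linear decay (DOM remineralization at rate k) matches
        exp(-k t) to 1e-6 relative at t = 10/k."""
        k = 0.5
        p = params.replace(mu_max=0, g_max=0, m_agg=0, w_det=0, r_det=0,
                           r_ben=0, m_z_prime=0, r_zoo_basal=0, m_vir_max=0,
                           k_ads=0, k_defense=0, k_decay=0, r_dom=k,
                           f_denit=0.0, f_burial=0.0)
        s0 = EcosystemState(DOC=10.0, Phy=0.0, Zoo=0.0, DetC=0, DetN=0,
                            DetP=0, DON=0, DOP=0, v=0, BenC=0, BenN=0, BenP=0)
        traj = integrate(s0, smooth_forcing, 0.05, 20.0, p, output_every=0.5)
        exact = 10.0 * np.exp(-k * traj.times)
        rel = np.abs(traj.pool("DOC") - exact) / exact
        assert rel.max() < 1e-6

    def test_rk4_order_of_convergence(self, params, smooth_forcing):
        """Halving dt cuts the error vs a dt/16 reference by ~16x."""
        s0 = xp.initial_state_for_station(smooth_forcing, params)
        ref = integrate(s0, smooth_forcing, 0.00625, 30.0, params,
                        output_every=30.0).states[-1][:15]
        err = {}
        for dt in (0.2, 0.1):
            y = integrate(s0, smooth_forcing, dt, 30.0, params,
                          output_every=30.0).states[-1][:15]
            err[dt] = np.linalg.norm(y - ref) / np.linalg.norm(ref)
        assert 8.0 < err[0.2] / err[0.1] < 32.0

    def test_horizon_must_divide(self, params, smooth_forcing):
        s0 = EcosystemState()
        with pytest.raises(ValueError):
            integrate(s0, smooth_forcing, 0.07, 10.0, params)


@pytest.fixture(scope="module")
def closed_run(params):
    p = params.replace(f_denit=0.0, f_burial=0.0)
    station = cb.make_station(12.0, 29.0, seed=5)
    s0 = xp.initial_state_for_station(station, p)
    return mass_balance(integrate(s0, station, 0.05, 365.0, p))


class TestMassBalance:

    def test_closed_box_residuals(self, closed_run):
        assert (closed_run["rel_residual"].abs() < 1e-8).all()

    def test_denitrification_rerouting(self, params):
        """With benthic N loss on, the N budget closes only through the
        cumulated denitrification and burial fluxes."""
        station = cb.make_station(12.0, 29.0, seed=5)
        s0 = xp.initial_state_for_station(station, params)
        traj = integrate(s0, station, 0.05, 365.0, params)
        mb = mass_balance(traj).set_index("element")
        assert mb.loc["N", "sinks"] > 0.0
        assert abs(mb.loc["N", "rel_residual"]) < 1e-8
        # P leaves only by burial
        assert mb.loc["P", "sinks"] == pytest.approx(
            float(traj.states[-1][_IDX["cum_burial_P"]]
                  - traj.states[0][_IDX["cum_burial_P"]]))
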