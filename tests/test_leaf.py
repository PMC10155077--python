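"""Leaf gas-exchange unit and property tests."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from soycanopy.leaf import (LeafEnvironment, aci_curve, assimilation_at_ci,
                            electron_transport, find_transition_ci,
                            percent_gain_an, photoresp_gain_ratio,
                            rubisco_limited, rubp_limited, solve_coupled,
                            temperature_adjust, tpu_limited)
from soycanopy.params import PhotosynthesisParams


class TestTemperatureAdjust:
    def test_identity_at_25(self, params):
        r = temperature_adjust(params, 25.0)
        assert r.vcmax == pytest.approx(params.vcmax25)
        assert r.jmax == pytest.approx(params.jmax25)
        assert r.kc == pytest.approx(params.kc25)
        assert r.gamma_star == pytest.approx(params.gamma_star25)

    def test_kinetics_increase_with_temperature(self, params):
        assert temperature_adjust(params, 35.0).kc > temperature_adjust(params, 25.0).kc

    def test_arrhenius_value_at_15(self, params):
        # 110 * exp(65330/8.314 * (1/298.15 - 1/288.15)) evaluated by hand
        expected = 110.0 * math.exp(65330.0 / 8.314 * (1 / 298.15 - 1 / 288.15))
        assert temperature_adjust(params, 15.0).vcmax == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(44.07, abs=0.01)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            temperature_adjust(params, 60.0)


class TestElectronTransport:
    def test_dark_and_saturation_limits(self, params):
        assert electron_transport(0.0, 195.0, params.theta, params.absorb_effective) == 0.0
        j_big = electron_transport(1e7, 195.0, params.theta, params.absorb_effective)
        assert j_big == pytest.approx(195.0, rel=1e-3)

    def test_smaller_quadratic_root(self, params):
        i2 = 1500.0 * params.absorb_effective
        roots = np.roots([params.theta, -(i2 + 195.0), i2 * 195.0])
        expected = roots.min()
        j = electron_transport(1500.0, 195.0, params.theta, params.absorb_effective)
        assert j == pytest.approx(expected, rel=1e-10)
        assert 0.0 <= j <= 195.0

    def test_bad_theta_rejected(self, params):
        with pytest.raises(ValueError):
            electron_transport(500.0, 195.0, 1.2, params.absorb_effective)

    @given(q1=st.floats(0, 3000), q2=st.floats(0, 3000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_light(self, q1, q2):
        lo, hi = sorted((q1, q2))
        assert (electron_transport(lo, 195.0, 0.7, 0.36125)
                <= electron_transport(hi, 195.0, 0.7, 0.36125) + 1e-9)


class TestCandidateRates:
    def test_rubisco_compensation_and_saturation(self, params):
        assert rubisco_limited(params.gamma_star25, 110.0, params.kc25,
                               params.ko25, params.o2, params.gamma_star25) == 0.0
        assert rubisco_limited(1e8, 110.0, params.kc25, params.ko25,
                               params.o2, params.gamma_star25) == pytest.approx(110.0, rel=1e-4)

    def test_rubisco_hand_value(self, params):
        km = params.kc25 * (1 + params.o2 / params.ko25)
        expected = 110.0 * (280.0 - 42.75) / (280.0 + km)
        got = rubisco_limited(280.0, 110.0, params.kc25, params.ko25,
                              params.o2, params.gamma_star25)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_rubp_limits_and_hand_value(self):
        assert rubp_limited(42.75, 171.0, 42.75) == 0.0
        assert rubp_limited(1e8, 171.0, 42.75) == pytest.approx(171.0 / 4, rel=1e-4)
        assert rubp_limited(400.0, 171.0, 42.75) == pytest.approx(
            171.0 * (400 - 42.75) / (4 * 400 + 8 * 42.75), rel=1e-12)

    def test_tpu_triple_rule(self):
        assert tpu_limited(23.0) == 69.0
        with pytest.raises(ValueError):
            tpu_limited(0.0)

    def test_tpu_never_binds_at_defaults(self, params):
        env = LeafEnvironment(q=2000.0, t_leaf=25.0, rh=0.7, ca=1000.0)
        for ci in np.arange(50.0, 1001.0, 25.0):
            assert assimilation_at_ci(ci, env, params).limiting != "tpu"

    def test_tpu_binds_above_brute_force_threshold(self, params):
        # force a small TPU so the sweep crosses into the TPU regime
        small = replace(params, tpu25=8.0)
        env = LeafEnvironment(q=1500.0, t_leaf=25.0, rh=0.7, ca=1500.0)
        grid = np.arange(50.0, 1501.0, 10.0)
        labels = [assimilation_at_ci(ci, env, small).limiting for ci in grid]
        rates = temperature_adjust(small, 25.0)
        j = electron_transport(1500.0, rates.jmax, small.theta, small.absorb_effective)
        brute = []
        for ci in grid:
            ac = rubisco_limited(ci, rates.vcmax, rates.kc, rates.ko, small.o2, rates.gamma_star)
            aj = rubp_limited(ci, j, rates.gamma_star)
            ap = tpu_limited(rates.tpu)
            brute.append(["rubisco", "rubp", "tpu"][int(np.argmin([ac, aj, ap]))])
        assert labels == brute
        assert "tpu" in labels


class TestAssimilationAtCi:
    def test_dark_respiration_only(self, params):
        env = LeafEnvironment(q=0.0, t_leaf=25.0, rh=0.7, ca=400.0)
        flux = assimilation_at_ci(280.0, env, params)
        assert flux.an == pytest.approx(-flux.rd)
        assert flux.limiting == "rubp"

    def test_argmin_label_matches_brute_force(self, params):
        env = LeafEnvironment(q=1500.0, t_leaf=25.0, rh=0.7, ca=400.0)
        flux = assimilation_at_ci(280.0, env, params)
        assert flux.limiting == ["rubisco", "rubp", "tpu"][
            int(np.argmin([flux.ac, flux.aj, flux.ap]))]

    @given(ci=st.floats(50.0, 1500.0), q=st.floats(0.0, 2500.0),
           t=st.floats(5.0, 40.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_accounting_identity(self, params, ci, q, t):
        """vc - rp - rd = an holds for every solved leaf state."""
        env = LeafEnvironment(q=q, t_leaf=t, rh=0.7, ca=max(ci, 100.0))
        flux = assimilation_at_ci(ci, env, params)
        gstar = temperature_adjust(params, t).gamma_star
        if ci > gstar:
            assert flux.vc - flux.rp - flux.rd == pytest.approx(flux.an, rel=1e-9, abs=1e-9)
            assert flux.rp >= 0.0

    def test_nonpositive_ci_rejected(self, params):
        env = LeafEnvironment(q=500.0, t_leaf=25.0, rh=0.7, ca=400.0)
        with pytest.raises(ValueError):
            assimilation_at_ci(0.0, env, params)


class TestMonotonicity:
    def test_an_nondecreasing_in_ci_q_and_capacity(self, params):
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = rng.uniform(100, 2000)
            t = rng.uniform(10, 35)
            ci = np.sort(rng.uniform(60, 1200, 8))
            env = LeafEnvironment(q=q, t_leaf=t, rh=0.7, ca=1200.0)
            an = [assimilation_at_ci(c, env, params).an for c in ci]
            assert all(b >= a - 1e-9 for a, b in zip(an, an[1:]))
            ci0 = float(rng.uniform(100, 800))
            qs = np.sort(rng.uniform(0, 2500, 6))
            an_q = [assimilation_at_ci(
                ci0, LeafEnvironment(q=float(qq), t_leaf=t, rh=0.7, ca=1000.0),
                params).an for qq in qs]
            assert all(b >= a - 1e-9 for a, b in zip(an_q, an_q[1:]))
        # gross rate non-decreasing in each capacity parameter (rd held fixed)
        base = replace(params, rd25=1.65)
        env = LeafEnvironment(q=1200.0, t_leaf=25.0, rh=0.7, ca=600.0)
        for scale_field in ("vcmax25", "jmax25"):
            vals = [assimilation_at_ci(
                400.0, env,
                replace(base, **{scale_field: getattr(base, scale_field) * s})).an
                for s in (0.8, 1.0, 1.2)]
            assert vals[0] <= vals[1] + 1e-9 <= vals[2] + 2e-9


class TestCoupledSolve:
    def test_dark_closure(self, params):
        env = LeafEnvironment(q=0.0, t_leaf=25.0, rh=0.7, ca=400.0)
        flux = solve_coupled(env, params)
        assert flux.an == pytest.approx(-1.65, rel=1e-6)
        assert flux.gs == pytest.approx(params.bb_intercept)

    def test_balance_residuals_below_tolerance(self, params):
        env = LeafEnvironment(q=1500.0, t_leaf=25.0, rh=0.7, ca=400.0)
        flux = solve_coupled(env, params)
        demand = assimilation_at_ci(flux.ci, env, params)
        assert demand.an == pytest.approx(flux.an, rel=1e-6, abs=1e-6)
        gs = max(params.bb_slope * flux.an * env.rh / env.ca + params.bb_intercept,
                 params.bb_intercept)
        ci_supply = env.ca - 1.6 * flux.an / gs
        assert ci_supply == pytest.approx(flux.ci, rel=1e-5)

    def test_matches_bisection_oracle_on_random_environments(self, params):
        rng = np.random.default_rng(1)
        for _ in range(100):
            q = rng.uniform(0, 2000)
            t = rng.uniform(5, 40)
            rh = rng.uniform(0.2, 0.95)
            ca = rng.uniform(250, 1000)
            env = LeafEnvironment(q=q, t_leaf=t, rh=rh, ca=ca)
            flux = solve_coupled(env, params)

            def resid(ci):
                d = assimilation_at_ci(ci, env, params)
                gs = max(params.bb_slope * d.an * rh / ca + params.bb_intercept,
                         params.bb_intercept)
                return ci - (ca - 1.6 * d.an / gs)

            hi = ca + 1.6 * 5.0 / params.bb_intercept + 100.0
            ci_oracle = brentq(resid, 1e-2, hi)
            assert abs(ci_oracle - flux.ci) / ca < 1e-4


class TestTransitionCi:
    def test_regimes_across_transition(self, params):
        res = find_transition_ci(1500.0, 25.0, params)
        assert res.status == "crossing"
        env = LeafEnvironment(q=1500.0, t_leaf=25.0, rh=0.7, ca=2000.0)
        below = assimilation_at_ci(res.ci_star * 0.9, env, params)
        above = assimilation_at_ci(res.ci_star * 1.1, env, params)
        assert below.limiting == "rubisco"
        assert above.limiting == "rubp"

    def test_no_crossing_reported_not_raised(self, params):
        tiny_j = replace(params, jmax25=20.0)
        res = find_transition_ci(1500.0, 25.0, tiny_j)
        assert res.status == "always_rubp"
        assert res.ci_star is None

    def test_rates_equal_at_root(self, params):
        res = find_transition_ci(800.0, 25.0, params)
        env = LeafEnvironment(q=800.0, t_leaf=25.0, rh=0.7, ca=2000.0)
        flux = assimilation_at_ci(res.ci_star, env, params)
        assert abs(flux.ac - flux.aj) < 1e-6 * params.vcmax25


class TestAciCurve:
    def test_monotone_with_single_regime_switch(self, params):
        grid = list(np.arange(100.0, 1001.0, 50.0))
        fluxes = aci_curve(1500.0, 25.0, params, grid)
        an = [f.an for f in fluxes]
        assert all(b >= a - 1e-9 for a, b in zip(an, an[1:]))
        labels = [f.limiting for f in fluxes]
        switches = sum(a != b for a, b in zip(labels, labels[1:]))
        assert switches == 1
        ci_star = find_transition_ci(1500.0, 25.0, params).ci_star
        for f in fluxes:
            assert (f.limiting == "rubisco") == (f.ci < ci_star)

    def test_jmax_scaling_leaves_rubisco_branch_unchanged(self, params):
        ci_star = find_transition_ci(1500.0, 25.0, params).ci_star
        grid = [c for c in np.arange(100.0, 1001.0, 50.0) if c < ci_star]
        base = replace(params, rd25=1.65)
        ctl = aci_curve(1500.0, 25.0, base, grid)
        up = aci_curve(1500.0, 25.0, replace(base, jmax25=base.jmax25 * 1.2), grid)
        for a, b in zip(ctl, up):
            assert b.an == pytest.approx(a.an, rel=1e-12)

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            aci_curve(1500.0, 25.0, params, [])


class TestScalingResponses:
    def test_identity_scaling_gives_zero_gain(self, params):
        assert percent_gain_an(1500.0, 25.0, params, 400.0, 600.0, 1.0, 1.0) == 0.0

    def test_photoresp_ratio_equals_closed_form(self, params):
        for ci in (300.0, 450.0, 700.0):
            got = photoresp_gain_ratio(ci, 1500.0, 25.0, params, 1.2, 1.2)
            assert got == pytest.approx(100.0 * params.gamma_star25 / ci, abs=1e-6)
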