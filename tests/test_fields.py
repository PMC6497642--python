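"""Analytic field properties: kernels, uptake integral, asymptotics, masses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ebusplan import (
    InjectionPlan,
    asymptotic_intracellular,
    blood_concentration,
    blood_curve,
    blood_peak_time,
    extracellular_field,
    intracellular_field,
    kernel_arguments,
    mass_ledger,
)

POINT = np.array([[0.2, 0.0, 0.0]])


class TestExtracellularField:
    def test_gaussian_peak_value_at_site(self, single_site_plan, params):
        t = 600.0
        expected = (
            8.0
            * math.exp(-params.k_sum * t)
            / (4.0 * math.pi * params.D * t) ** 1.5
        )
        val = extracellular_field(np.zeros((1, 3)), t, single_site_plan, params)
        assert val[0] == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_dose(self, params):
        sites = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        p1 = InjectionPlan(sites, [4.0, 4.0])
        p2 = InjectionPlan(sites, [8.0, 8.0])
        pts = np.random.default_rng(0).uniform(-1, 1, (20, 3))
        np.testing.assert_allclose(
            extracellular_field(pts, 300.0, p2, params),
            2.0 * extracellular_field(pts, 300.0, p1, params),
            rtol=1e-13,
        )

    def test_superposition_over_sites(self, five_site_plan, params):
        pts = np.random.default_rng(1).uniform(-1.5, 1.5, (30, 3))
        total = extracellular_field(pts, 900.0, five_site_plan, params)
        parts = sum(
            extracellular_field(
                pts, 900.0, InjectionPlan(s[None], [m]), params
            )
            for s, m in zip(five_site_plan.sites, five_site_plan.doses)
        )
        np.testing.assert_allclose(total, parts, rtol=1e-13)

    @pytest.mark.parametrize("t", [0.0, -5.0])
    def test_nonpositive_time_rejected(self, t, single_site_plan, params):
        with pytest.raises(ValueError):
            extracellular_field(POINT, t, single_site_plan, params)
        with pytest.raises(ValueError):
            intracellular_field(POINT, t, single_site_plan, params)

    @pytest.mark.parametrize("t", [60.0, 600.0, 3600.0])
    def test_mass_conservation_radial_integral(self, t, single_site_plan, params):
        """Spatial integral of phi_e equals M exp(-k t) within 0.1%."""

        def shell(r):
            pt = np.array([[r, 0.0, 0.0]])
            return 4.0 * math.pi * r**2 * extracellular_field(
                pt, t, single_site_plan, params
            )[0]

        r_max = 10.0 * math.sqrt(4.0 * params.D * t)
        integral, _ = quad(shell, 0.0, r_max, limit=200)
        expected = 8.0 * math.exp(-params.k_sum * t)
        assert integral == pytest.approx(expected, rel=1e-3)

    def test_literature_mode_is_global_4pi(self, single_site_plan, params):
        lit = params.replace(normalization="literature")
        base = extracellular_field(POINT, 600.0, single_site_plan, params)
        assert extracellular_field(POINT, 600.0, single_site_plan, lit)[0] == (
            pytest.approx(4.0 * math.pi * base[0], rel=1e-13)
        )


class TestKernelArguments:
    @given(
        tau=st.floats(1.0, 1e6),
        r=st.floats(1e-3, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_two_alpha_beta_independent_of_tau(self, params, tau, r):
        ka = kernel_arguments(r, tau, params)
        expected = r * math.sqrt(params.k_sum / params.D)
        assert 2.0 * ka.alpha * ka.beta == pytest.approx(expected, rel=1e-12)
        assert ka.two_alpha_beta == pytest.approx(expected, rel=1e-12)


class TestIntracellularField:
    def test_matches_quadrature_of_uptake_integrand(self, single_site_plan, params):
        """Closed form equals k_i * int_0^t phi_e dtau within 0.1%."""
        t = 3600.0

        def integrand(tau):
            return extracellular_field(POINT, tau, single_site_plan, params)[0]

        expected, _ = quad(integrand, 0.0, t, limit=300)
        got = intracellular_field(POINT, t, single_site_plan, params)[0]
        assert got == pytest.approx(params.k_i * expected, rel=1e-3)

    def test_vanishes_at_early_time(self, single_site_plan, params):
        assert intracellular_field(POINT, 1e-6, single_site_plan, params)[0] < 1e-30

    def test_zero_uptake_rate_gives_zero(self, single_site_plan, params):
        p0 = params.replace(k_i=0.0)
        assert intracellular_field(POINT, 3600.0, single_site_plan, p0)[0] == 0.0

    def test_monotone_accumulation_in_time(self, single_site_plan, params):
        radii = np.array([[0.05, 0, 0], [0.2, 0, 0], [0.6, 0, 0], [1.2, 0, 0]])
        times = np.geomspace(10.0, 5e5, 40)
        prev = np.zeros(4)
        for t in times:
            cur = intracellular_field(radii, t, single_site_plan, params)
            assert np.all(cur >= prev * (1.0 - 1e-12))
            prev = cur

    def test_site_coincidence_raises(self, single_site_plan, params):
        with pytest.raises(ValueError, match="grid spacing"):
            intracellular_field(np.zeros((1, 3)), 100.0, single_site_plan, params)


class TestAsymptoticField:
    def test_exact_screened_coulomb_ratio(self, single_site_plan, params):
        r1, r2 = 0.5, 1.0
        vals = asymptotic_intracellular(
            np.array([[r1, 0, 0], [r2, 0, 0]]), single_site_plan, params
        )
        expected_ratio = (r2 / r1) * math.exp(
            (r2 - r1) * math.sqrt(params.k_sum / params.D)
        )
        assert vals[0] / vals[1] == pytest.approx(expected_ratio, rel=1e-12)

    def test_limit_of_time_dependent_field(self, single_site_plan, params):
        """phi_i at t = 20 / k agrees with the asymptote within 0.1% out to
        10 screening lengths."""
        t = 20.0 / params.k_sum
        ell = params.screening_length
        pts = np.column_stack(
            [np.linspace(0.5 * ell, 10.0 * ell, 25), np.zeros(25), np.zeros(25)]
        )
        finite = intracellular_field(pts, t, single_site_plan, params)
        infinite = asymptotic_intracellular(pts, single_site_plan, params)
        np.testing.assert_allclose(finite, infinite, rtol=1e-3)

    def test_matches_long_time_quadrature(self, single_site_plan, params):
        t = 20.0 / params.k_sum
        pt = np.array([[0.5, 0.0, 0.0]])

        def integrand(tau):
            return extracellular_field(pt, tau, single_site_plan, params)[0]

        expected, _ = quad(integrand, 0.0, t, limit=400)
        got = asymptotic_intracellular(pt, single_site_plan, params)[0]
        assert got == pytest.approx(params.k_i * expected, rel=5e-3)

    def test_linear_in_total_dose(self, five_site_plan, params):
        scaled = InjectionPlan(
            five_site_plan.sites, 3.0 * five_site_plan.doses
        )
        pts = np.random.default_rng(2).uniform(-1.5, 1.5, (10, 3))
        np.testing.assert_allclose(
            asymptotic_intracellular(pts, scaled, params),
            3.0 * asymptotic_intracellular(pts, five_site_plan, params),
            rtol=1e-12,
        )

    def test_unscreened_coulomb_limit(self, single_site_plan, params):
        weak = params.replace(k_i=1e-16, k_f=0.0)
        vals = asymptotic_intracellular(
            np.array([[0.25, 0, 0], [0.5, 0, 0]]), single_site_plan, weak
        )
        assert vals[0] / vals[1] == pytest.approx(2.0, rel=1e-5)


class TestMassLedger:
    def test_initial_conditions(self, five_site_plan, params):
        led = mass_ledger(0.0, five_site_plan, params)
        assert led.M_e == pytest.approx(40.0)
        assert led.M_i == 0.0
        assert led.fluid_in_exact == 0.0

    def test_long_time_limits(self, five_site_plan, params):
        led = mass_ledger(1e8, five_site_plan, params)
        expected_mi = (
            (params.alpha_i / params.alpha_e) * (params.k_i / params.k_sum) * 40.0
        )
        assert led.M_e == pytest.approx(0.0, abs=1e-12)
        assert led.M_i == pytest.approx(expected_mi, rel=1e-9)

    @given(t=st.floats(0.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_mass_balance_identity(self, params, t):
        from ebusplan import default_five_site_plan

        led = mass_ledger(t, default_five_site_plan(), params)
        assert led.M_e + led.M_i + led.fluid_in_exact == pytest.approx(40.0, rel=1e-12)

    def test_degenerate_rates_rejected(self, five_site_plan, params):
        with pytest.raises(ValueError, match="degenerate"):
            mass_ledger(10.0, five_site_plan, params.replace(k_i=0.0, k_f=0.0))


class TestBloodConcentration:
    def test_zero_at_injection_time(self, five_site_plan, params):
        assert blood_concentration(0.0, five_site_plan, params) == pytest.approx(0.0)

    def test_peak_time(self, params):
        tp = blood_peak_time(params.k_sum, params.k_r)
        assert tp == pytest.approx(3.19e3, rel=5e-3)
        # stationarity: derivative changes sign around the peak
        plan = __import__("ebusplan").default_five_site_plan()
        t = np.array([tp - 30.0, tp, tp + 30.0])
        v = blood_concentration(t, plan, params)
        assert v[1] >= v[0] and v[1] >= v[2]

    def test_nonnegative_for_either_rate_ordering(self, five_site_plan, params):
        t = np.linspace(0.0, 3e4, 200)
        fast_renal = blood_concentration(t, five_site_plan, params)
        slow_renal = blood_concentration(
            t, five_site_plan, params.replace(k_r=1e-4)
        )
        assert np.all(fast_renal >= 0) and np.all(slow_renal >= 0)

    def test_confluent_limit_continuous(self, params):
        t = np.linspace(1.0, 1e4, 50)
        k = params.k_sum
        exact = blood_curve(t, [40.0], k, k, params.V_f)
        nearby = blood_curve(t, [40.0], k, k * (1.0 + 1e-9), params.V_f)
        np.testing.assert_allclose(exact, nearby, rtol=1e-6)

    def test_renal_clearance_recovers_total_dose(self, five_site_plan, params):
        """int_0^inf k_r phi_f V_f dt equals the injected mass within 0.1%."""

        def integrand(t):
            return params.k_r * params.V_f * blood_concentration(
                t, five_site_plan, params
            )

        total, _ = quad(integrand, 0.0, np.inf, limit=400)
        assert total == pytest.approx(40.0, rel=1e-3)
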