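"""Spectral overlap, Förster radius, rates, efficiencies, distance inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trespfret import (
    EfficiencyDistribution,
    PhotophysicsParams,
    TransitionDipoleVector,
    distance_bias_analysis,
    efficiency_distribution,
    forster_efficiency,
    forster_radius,
    instantaneous_rate,
    invert_distance,
    pda_coupling,
    spectral_overlap,
)
from trespfret.units import ANGSTROM_TO_BOHR, FORSTER_PREFACTOR


def _spectrum(lam, val):
    return pd.DataFrame({"wavelength_nm": lam, "value": val})


class TestSpectralOverlap:
    def test_zero_absorption_gives_zero(self):
        lam = np.linspace(300, 400, 101)
        j = spectral_overlap(_spectrum(lam, np.exp(-((lam - 350) ** 2) / 200)),
                             _spectrum(lam, np.zeros_like(lam)))
        assert j == 0.0

    def test_rectangular_closed_form(self):
        lam = np.linspace(500, 501, 501)
        j = spectral_overlap(_spectrum(lam, np.ones_like(lam)),
                             _spectrum(lam, np.ones_like(lam)))
        exact = (501.0**5 - 500.0**5) / 5.0  # ∫ λ⁴ dλ with unit-area emission
        assert j == pytest.approx(exact, rel=1e-6)

    def test_quadrature_refinement_is_stable(self):
        lam = np.linspace(300, 500, 201)
        em = np.exp(-((lam - 360) ** 2) / 400)
        ab = 1e4 * np.exp(-((lam - 420) ** 2) / 900)
        j1 = spectral_overlap(_spectrum(lam, em), _spectrum(lam, ab), n_grid=2001)
        j2 = spectral_overlap(_spectrum(lam, em), _spectrum(lam, ab), n_grid=4001)
        assert abs(j2 / j1 - 1) < 1e-4

    def test_disjoint_supports_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            spectral_overlap(_spectrum([300, 310], [1, 1]), _spectrum([400, 410], [1, 1]))


class TestForsterRadius:
    def test_doubling_overlap_scales_by_sixth_root(self):
        r1 = forster_radius(2 / 3, 0.2, 1e14, np.sqrt(2))
        r2 = forster_radius(2 / 3, 0.2, 2e14, np.sqrt(2))
        assert r2 / r1 == pytest.approx(2 ** (1 / 6), rel=1e-12)

    def test_zero_kappa2_rejected(self):
        with pytest.raises(ValueError):
            forster_radius(0.0, 0.2, 1e14, np.sqrt(2))

    def test_hand_evaluated_closed_form(self):
        # independent arithmetic: sixth root of 8.79e-5 · (2/3) · 2⁻² · 0.14 · 1e14
        expected = (FORSTER_PREFACTOR * (2 / 3) * 0.25 * 0.14 * 1e14) ** (1 / 6)
        assert forster_radius(2 / 3, 0.14, 1e14, 2 ** 0.5) == pytest.approx(
            expected, rel=1e-12
        )


class TestInstantaneousRate:
    def test_zero_coupling_zero_rate(self, photophysics):
        assert instantaneous_rate(0.0, photophysics) == 0.0

    def test_quadratic_in_coupling(self, photophysics):
        assert instantaneous_rate(2e-5, photophysics) == pytest.approx(
            4 * instantaneous_rate(1e-5, photophysics), rel=1e-12
        )

    def test_reduces_to_forster_rate_at_r0(self, photophysics):
        p = photophysics
        v = (1 / p.n_refr**2) * np.sqrt(2 / 3) * p.mu_d_mag * p.mu_a_mag / (
            p.r0 * ANGSTROM_TO_BOHR
        ) ** 3
        assert instantaneous_rate(v, p) == pytest.approx(1 / p.tau_d, rel=1e-10)

    def test_consistent_with_forster_over_distance_sweep(self, photophysics):
        p = photophysics
        mu_d = TransitionDipoleVector([0, 0, p.mu_d_mag])
        mu_a = TransitionDipoleVector([p.mu_a_mag / np.sqrt(2), 0, p.mu_a_mag / np.sqrt(2)])
        for r in np.linspace(10, 80, 15):
            # screened PDA coupling with the isotropic κ replayed explicitly
            v = (1 / p.n_refr**2) * np.sqrt(2 / 3) * p.mu_d_mag * p.mu_a_mag / (
                r * ANGSTROM_TO_BOHR
            ) ** 3
            k_forster = (p.r0 / r) ** 6 / p.tau_d
            assert instantaneous_rate(v, p) == pytest.approx(k_forster, rel=1e-8)


class TestEfficiencyDistribution:
    def test_constant_rate_closed_form(self, photophysics):
        k = 1.0 / photophysics.tau_d  # kτ = 1 → E = 0.5
        dist = efficiency_distribution(
            [np.full(200, k)], photophysics, fast_window=1.0, stride_ps=50.0
        )
        np.testing.assert_allclose(dist.window_efficiencies, 0.5, rtol=1e-12)

    def test_two_state_arithmetic(self, photophysics):
        tau = photophysics.tau_d
        m = 40  # frames per window
        rates = np.concatenate([np.full(m, 1 / tau), np.full(m, 3 / tau)])
        dist = efficiency_distribution(
            [rates], photophysics, fast_window=m * 0.05, stride_ps=50.0
        )
        np.testing.assert_allclose(np.sort(dist.window_efficiencies), [0.5, 0.75])
        assert dist.mean_e == pytest.approx(0.625)

    def test_series_shorter_than_window_rejected(self, photophysics):
        with pytest.raises(ValueError, match="shorter"):
            efficiency_distribution(
                [np.ones(3)], photophysics, fast_window=1.0, stride_ps=50.0
            )

    def test_static_and_dynamic_limits_bracket_intermediate(self, photophysics):
        tau = photophysics.tau_d
        rng = np.random.default_rng(5)
        rates = rng.uniform(0.1, 3.0, size=400) / tau
        static = efficiency_distribution(  # one frame per window
            [rates], photophysics, fast_window=0.05, stride_ps=50.0
        ).mean_e
        dynamic = efficiency_distribution(  # whole trajectory in one window
            [rates], photophysics, fast_window=400 * 0.05, stride_ps=50.0
        ).mean_e
        kbar = rates.mean()
        assert dynamic == pytest.approx(tau * kbar / (1 + tau * kbar), rel=1e-12)
        intermediate = efficiency_distribution(
            [rates], photophysics, fast_window=1.0, stride_ps=50.0
        ).mean_e
        lo, hi = sorted([static, dynamic])
        assert lo - 1e-12 <= intermediate <= hi + 1e-12

    def test_efficiencies_stay_in_unit_interval(self, photophysics, rng):
        rates = rng.exponential(1.0, size=500)
        dist = efficiency_distribution([rates], photophysics, stride_ps=50.0)
        assert np.all((dist.window_efficiencies >= 0) & (dist.window_efficiencies <= 1))


class TestDistanceInversion:
    def test_half_efficiency_at_r0(self):
        assert invert_distance(0.5, 30.0) == pytest.approx(30.0, rel=1e-12)

    def test_two_r0_closed_form(self):
        assert invert_distance(1 / 65, 30.0) == pytest.approx(60.0, rel=1e-12)

    @given(e=st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_identity(self, e):
        r0 = 27.5
        assert forster_efficiency(invert_distance(e, r0), r0) == pytest.approx(
            e, rel=1e-12
        )

    def test_monotone_decreasing_in_distance(self):
        r = np.linspace(5, 80, 100)
        e = forster_efficiency(r, 30.0)
        assert np.all(np.diff(e) < 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_degenerate_efficiencies_rejected(self, bad):
        with pytest.raises(ValueError):
            invert_distance(bad, 30.0)


class TestDistanceBias:
    def test_self_consistent_efficiencies_give_zero_mue(self, rng):
        r0 = 30.0
        md = rng.uniform(15, 45, size=300)
        dist = EfficiencyDistribution(forster_efficiency(md, r0), window_duration=5.0)
        report = distance_bias_analysis(dist, r0, md)
        assert report["mue"] == pytest.approx(0.0, abs=1e-9)
        assert report["max_deviation"] == pytest.approx(0.0, abs=1e-9)

    def test_orientation_fluctuations_broaden_apparent_distances(self, photophysics, rng):
        # couplings fluctuate through κ at FIXED separation: the inverted
        # distribution must be broader than the (degenerate) true one
        p = photophysics
        r_fixed = 30.0
        k2 = rng.uniform(0.05, 4.0, size=400)
        v = np.sqrt(k2) * p.mu_d_mag * p.mu_a_mag / (r_fixed * ANGSTROM_TO_BOHR) ** 3 / p.n_refr**2
        rates = instantaneous_rate(v, p)
        dist = efficiency_distribution([rates], p, fast_window=0.05, stride_ps=50.0)
        md = np.full(400, r_fixed)
        report = distance_bias_analysis(dist, p.r0, md)
        assert report["inverted_distances"].std() > 1.0
        assert report["md_distances"].std() == 0.0

    def test_degenerate_efficiencies_excluded_with_count(self):
        dist = EfficiencyDistribution([0.0, 0.5, 1.0], window_duration=5.0)
        report = distance_bias_analysis(dist, 30.0, np.array([30.0]))
        assert report["n_excluded"] == 2

    def test_empty_md_series_rejected(self):
        dist = EfficiencyDistribution([0.5], window_duration=5.0)
        with pytest.raises(ValueError):
            distance_bias_analysis(dist, 30.0, np.array([]))
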