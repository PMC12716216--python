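"""Polarizable environment: selection, induction, coupling term, screening."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from trespfret import (
    CouplingRecord,
    PolarizableSite,
    PositionedCharges,
    env_coupling,
    field_at_sites,
    screening_factor,
    screening_profile,
    select_environment,
    solve_induced_dipoles,
)
from trespfret.fixtures import make_polarizable_shell, make_random_sites
from trespfret.mmpol import load_polarizability_table
from trespfret.units import ANG3_TO_BOHR3, BOHR_ANGSTROM

from conftest import random_rotation


def _point(coord, q):
    return PositionedCharges(np.array([coord], dtype=float), np.array([q], dtype=float))


class TestSelectEnvironment:
    def test_empty_environment(self):
        sites = select_environment(np.empty((0, 3)), [], np.zeros((1, 3)), np.ones((1, 3)))
        assert sites == []

    @pytest.mark.parametrize("dist, included", [(14.9, True), (15.0, True), (15.1, False)])
    def test_cutoff_boundary_is_closed(self, dist, included):
        donor = np.zeros((1, 3))
        acceptor = np.array([[40.0, 0, 0]])
        env = np.array([[0.0, dist, 0]])
        sites = select_environment(env, ["O"], donor, acceptor, cutoff=15.0)
        assert (len(sites) == 1) == included

    def test_matches_brute_force_distance_filter(self, rng):
        donor = rng.normal(size=(5, 3))
        acceptor = rng.normal(size=(5, 3)) + [20, 0, 0]
        env = rng.uniform(-30, 50, size=(100, 3))
        types = ["C"] * 100
        sites = select_environment(env, types, donor, acceptor, cutoff=15.0)
        chrom = np.vstack([donor, acceptor])
        expected = {i for i in range(100) if cdist(env[i : i + 1], chrom).min() <= 15.0}
        got = {int(s.source_atom_id.split(":")[1]) for s in sites}
        assert got == expected

    def test_unassigned_atom_type_is_an_error(self):
        with pytest.raises(KeyError, match="Xx"):
            select_environment(
                np.array([[5.0, 0, 0]]), ["Xx"], np.zeros((1, 3)), np.ones((1, 3))
            )

    def test_polarizability_table_units(self, tmp_path):
        p = tmp_path / "pol.txt"
        p.write_text("# units: angstrom^3\nC 1.0\n")
        assert load_polarizability_table(p)["C"] == pytest.approx(ANG3_TO_BOHR3)
        p.write_text("# units: bohr^3\nC 1.0\n")
        assert load_polarizability_table(p)["C"] == pytest.approx(1.0)


class TestFieldAtSites:
    def test_unit_coulomb_field(self):
        charge = _point([0, 0, 0], 1.0)
        site = [PolarizableSite(np.array([BOHR_ANGSTROM, 0, 0]), alpha=1.0)]
        field = field_at_sites(charge, site)
        np.testing.assert_allclose(field, [[1.0, 0, 0]], rtol=1e-12)

    def test_zero_charges_zero_field(self, rng):
        charges = PositionedCharges(rng.normal(size=(4, 3)), np.zeros(4))
        sites = make_random_sites(3, box=30.0, seed=1)
        np.testing.assert_array_equal(field_at_sites(charges, sites), np.zeros((3, 3)))

    def test_matches_direct_summation(self, rng):
        q = rng.uniform(-0.3, 0.3, 4)
        pos = rng.normal(size=(4, 3))
        charges = PositionedCharges(pos, q)
        sites = make_random_sites(3, box=30.0, min_dist=3.0, seed=2)
        field = field_at_sites(charges, sites)
        for l, site in enumerate(sites):
            expected = np.zeros(3)
            for j in range(4):
                d = (site.coordinate - pos[j]) / BOHR_ANGSTROM
                expected += q[j] * d / np.linalg.norm(d) ** 3
            np.testing.assert_allclose(field[l], expected, rtol=1e-12)


class TestInducedDipoles:
    def test_single_site_closed_form(self):
        site = [PolarizableSite(np.zeros(3), alpha=2.0)]
        sol = solve_induced_dipoles(site, np.array([[0.0, 0, 1.0]]))
        np.testing.assert_allclose(sol.dipoles, [[0, 0, 2.0]], rtol=1e-14)

    def test_zero_polarizability_gives_zero_dipoles(self, rng):
        sites = [
            PolarizableSite(c, alpha=0.0)
            for c in rng.uniform(-10, 10, size=(5, 3))
        ]
        for method in ("direct", "iterative"):
            sol = solve_induced_dipoles(sites, rng.normal(size=(5, 3)), method=method)
            np.testing.assert_array_equal(sol.dipoles, np.zeros((5, 3)))

    @pytest.mark.parametrize("n_sites", [10, 50])
    def test_direct_and_iterative_agree(self, n_sites, rng):
        sites = make_random_sites(n_sites, box=22.0, min_dist=2.5, seed=n_sites)
        field = rng.normal(size=(n_sites, 3))
        direct = solve_induced_dipoles(sites, field, method="direct")
        iterative = solve_induced_dipoles(
            sites, field, method="iterative", tolerance=1e-13, max_iter=2000
        )
        scale = np.abs(direct.dipoles).max()
        assert np.abs(direct.dipoles - iterative.dipoles).max() / scale < 1e-10

    def test_nonconvergence_reports_residuals(self):
        # two highly polarizable sites at near-contact: fixed point diverges
        sites = [
            PolarizableSite(np.zeros(3), alpha=30.0),
            PolarizableSite(np.array([1.2, 0, 0]), alpha=30.0),
        ]
        with pytest.raises(RuntimeError, match="not converged"):
            solve_induced_dipoles(
                sites, np.ones((2, 3)), method="iterative", max_iter=20
            )


class TestEnvCoupling:
    def test_no_sites_gives_zero_and_unit_screening(self):
        donor = _point([0, 0, 0], 0.1)
        sol = solve_induced_dipoles([], np.empty((0, 3)))
        v_env = env_coupling(donor, [], sol)
        assert v_env == 0.0
        assert screening_factor(1e-5, v_env) == 1.0

    def test_single_site_matches_closed_form(self):
        donor = _point([0, 0, 0], 1.0)
        acceptor = _point([10.0, 0, 0], 1.0)
        alpha = 2.0
        site = [PolarizableSite(np.array([5.0, 3.0, 0]), alpha=alpha)]
        e_d = field_at_sites(donor, site)[0]
        e_a = field_at_sites(acceptor, site)[0]
        sol = solve_induced_dipoles(site, field_at_sites(acceptor, site))
        v_env = env_coupling(donor, site, sol)
        assert v_env == pytest.approx(-alpha * float(e_d @ e_a), rel=1e-10)

    def test_reciprocity_donor_vs_acceptor_induction(self, rng):
        for seed in range(5):
            donor = PositionedCharges(
                rng.normal(size=(3, 3)), np.array([0.1, -0.05, -0.05])
            )
            acceptor = PositionedCharges(
                rng.normal(size=(3, 3)) + [15, 0, 0], np.array([-0.2, 0.12, 0.08])
            )
            sites = make_random_sites(12, box=10.0, min_dist=2.0, seed=seed)
            sites = [
                PolarizableSite(s.coordinate + np.array([7.5, 6.0, 0]), s.alpha)
                for s in sites
            ]
            sol_a = solve_induced_dipoles(sites, field_at_sites(acceptor, sites))
            sol_d = solve_induced_dipoles(sites, field_at_sites(donor, sites))
            v1 = env_coupling(donor, sites, sol_a)
            v2 = env_coupling(acceptor, sites, sol_d)
            assert v1 == pytest.approx(v2, rel=1e-8)

    def test_invariant_under_global_rigid_motion(self, rng):
        donor = PositionedCharges(rng.normal(size=(2, 3)), np.array([0.1, -0.1]))
        acceptor = PositionedCharges(
            rng.normal(size=(2, 3)) + [12, 0, 0], np.array([0.15, -0.15])
        )
        sites = make_polarizable_shell(8, 5.0, alpha=1.5, center=(6, 0, 0), seed=4)
        sol = solve_induced_dipoles(sites, field_at_sites(acceptor, sites))
        v0 = env_coupling(donor, sites, sol)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 20
        d2 = PositionedCharges(donor.coordinates @ rot.T + shift, donor.charges)
        a2 = PositionedCharges(acceptor.coordinates @ rot.T + shift, acceptor.charges)
        sites2 = [
            PolarizableSite(s.coordinate @ rot.T + shift, s.alpha) for s in sites
        ]
        sol2 = solve_induced_dipoles(sites2, field_at_sites(a2, sites2))
        assert env_coupling(d2, sites2, sol2) == pytest.approx(v0, rel=1e-10)


class TestScreening:
    def test_zero_env_gives_unity(self):
        assert screening_factor(1e-4, 0.0) == 1.0

    def test_forster_value_at_half_cancellation(self):
        v = 1e-4
        assert screening_factor(v, -v / 2) == pytest.approx(0.5)

    def test_below_threshold_is_an_error(self):
        with pytest.raises(ValueError, match="near-zero"):
            screening_factor(1e-12, 1e-10)

    def _record(self, v_coul, v_env, r):
        return CouplingRecord(
            frame_time=0.0, replica_id="r0", v_coul=v_coul, v_env=v_env,
            r=r, kappa2=0.5, v_pda_unscreened=v_coul,
        )

    def test_empty_environment_profile_is_unity(self):
        records = [self._record(1e-4, 0.0, r) for r in (5.0, 8.0, 12.0)]
        prof = screening_profile(records)
        np.testing.assert_array_equal(prof["mean"], 1.0)

    def test_attenuating_environment_lies_between_forster_and_unity(self):
        # shell radius exceeds half the charge separation, so every site
        # sees donor and acceptor fields with a positive overlap and screens
        donor = _point([0, 0, 0], 1.0)
        acceptor = _point([20.0, 0, 0], 1.0)
        records = []
        for seed in range(6):
            sites = make_polarizable_shell(30, 15.0, alpha=6.0, center=(10, 0, 0), seed=seed)
            from trespfret import coulomb_coupling

            v_coul = coulomb_coupling(donor, acceptor)
            sol = solve_induced_dipoles(sites, field_at_sites(acceptor, sites))
            v_env = env_coupling(donor, sites, sol)
            records.append(self._record(v_coul, v_env, 20.0 + 0.01 * seed))
        prof = screening_profile(records)
        assert np.all(prof["mean"] < 1.0)
        assert np.all(prof["mean"] > 0.5)  # stays above the Förster 1/n² = 0.5 floor

    def test_single_record_profile(self):
        prof = screening_profile([self._record(1e-4, -1e-5, 9.7)])
        assert len(prof) == 1
        assert prof["mean"].iloc[0] == pytest.approx(0.9)
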