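"""Sum-over-states response: moments, condensed matrices, fields, oracle."""

import math

import numpy as np
import pytest

import spinlrf as s
from spinlrf.fixtures import two_site_expected
from spinlrf.lrf import NearDegeneracyError, OracleInvalidError
from tests.conftest import make_grid


class TestTransitionMoments:
    def test_antisymmetric_cell_moments(self, closed_shell_toy, toy_grid_ao):
        """Odd bond-antibond product gives opposite moments in symmetric cells."""
        grid, ao = toy_grid_ao
        tm = s.transition_moments(closed_shell_toy.mos, grid, ao)
        m = tm.moments["alpha"]
        assert m[0, 0, 0] == pytest.approx(-m[0, 0, 1], abs=1e-10)

    def test_moment_sums_vanish_by_orthogonality(self, bs_toy):
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        for spin in ("alpha", "beta"):
            total = tm.moments[spin].sum(axis=2)
            assert np.abs(total).max() < 1e-6

    def test_cell_moment_against_direct_quadrature(self, closed_shell_toy,
                                                   toy_grid_ao):
        """Independent weighted sum over cell-1 points reproduces M[0,0,0]."""
        grid, ao = toy_grid_ao
        tm = s.transition_moments(closed_shell_toy.mos, grid, ao)
        occ = ao @ closed_shell_toy.mos.occupied("alpha")[:, 0]
        virt = ao @ closed_shell_toy.mos.virtual("alpha")[:, 0]
        mask = grid.owner_atom == 0
        direct = np.sum(grid.base_weights[mask] * occ[mask] * virt[mask])
        assert tm.moments["alpha"][0, 0, 0] == pytest.approx(direct, abs=1e-14)

    def test_cell_moment_near_closed_form(self, closed_shell_toy, toy_grid_ao):
        """Quadrature cell moment approaches the erf closed form."""
        grid, ao = toy_grid_ao
        tm = s.transition_moments(closed_shell_toy.mos, grid, ao)
        exp = two_site_expected(0.0, 1.4, 1.0, -0.5, -0.1)
        assert abs(tm.moments["alpha"][0, 0, 0]) == pytest.approx(
            exp["cell_moment"], abs=2e-3
        )

    def test_denominators_strictly_negative(self, bs_toy):
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        for spin in ("alpha", "beta"):
            assert np.all(tm.denominators[spin] < 0)

    def test_near_degenerate_gap_aborts(self, toy_grid_ao):
        toy = s.build_two_site_toy(0.1, eps_bond=-0.5, eps_anti=-0.5 + 1e-8)
        grid, ao = make_grid(toy)
        with pytest.raises(NearDegeneracyError, match="near-degenerate"):
            s.transition_moments(toy.mos, grid, ao)


class TestCondensedDensityLRF:
    def test_closed_form_two_level_matrix(self, closed_shell_toy, toy_grid_ao):
        """K = (2 s^2 / -gap) [[1,-1],[-1,1]] with s the computed cell moment."""
        grid, ao = toy_grid_ao
        tm = s.transition_moments(closed_shell_toy.mos, grid, ao)
        k = s.condensed_lrf_density(tm)
        s_mom = tm.moments["alpha"][0, 0, 0]
        gap = -0.1 - (-0.5)
        expected = (2 * s_mom**2 / (-gap)) * np.array([[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(k.matrix, expected, atol=1e-8)

    def test_symmetry(self, bs_toy):
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        k = s.condensed_lrf_density(tm)
        assert k.symmetry_residual() < 1e-6

    def test_column_sums_vanish(self, bs_toy):
        grid, ao = make_grid(bs_toy)
        k = s.compute_lrf(bs_toy.geometry, bs_toy.shells, bs_toy.mos, grid)
        scale = np.abs(k.matrix).max()
        assert np.abs(k.column_sums()).max() <= 1e-3 * scale

    def test_negative_semidefinite(self, chain4):
        grid, ao = make_grid(chain4.system)
        k = s.compute_lrf(chain4.system.geometry, chain4.system.shells,
                          chain4.system.mos, grid)
        assert np.linalg.eigvalsh(k.matrix).max() <= 1e-6

    def test_attractive_perturbation_increases_density(self, closed_shell_toy,
                                                       toy_grid_ao):
        """Diagonal entries are negative: density rises under attraction."""
        grid, ao = toy_grid_ao
        tm = s.transition_moments(closed_shell_toy.mos, grid, ao)
        k = s.condensed_lrf_density(tm)
        assert k.matrix[0, 0] < 0

    def test_csv_json_round_trip(self, tmp_path, bs_toy):
        grid, ao = make_grid(bs_toy)
        k = s.compute_lrf(bs_toy.geometry, bs_toy.shells, bs_toy.mos, grid)
        path = tmp_path / "k.csv"
        k.to_csv(path)
        back = s.CondensedLRF.from_csv(path)
        np.testing.assert_allclose(back.matrix, k.matrix, rtol=1e-10)
        assert back.atom_labels == k.atom_labels
        k.to_json(tmp_path / "k.json")


class TestCondensedSpinLRF:
    def test_closed_shell_spin_response_identically_zero(self, closed_shell_toy,
                                                         toy_grid_ao):
        grid, ao = toy_grid_ao
        tm = s.transition_moments(closed_shell_toy.mos, grid, ao)
        kz = s.condensed_lrf_spin(tm)
        assert np.all(kz.matrix == 0.0)

    def test_channel_difference_identity(self, bs_toy):
        """K_z assembled as channel difference matches the direct definition."""
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        kz = s.condensed_lrf_spin(tm)
        direct = tm.channel_sum("alpha") - tm.channel_sum("beta")
        np.testing.assert_allclose(kz.matrix, direct, atol=1e-12)

    def test_spin_matrix_symmetric(self, bs_toy):
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        kz = s.condensed_lrf_spin(tm)
        assert kz.symmetry_residual() < 1e-6

    def test_symmetric_dimer_spin_response_vanishes_by_symmetry(self, bs_toy):
        """The even orbital product phi_a^2 - phi_b^2 has zero cell moments
        on a mirror-symmetric dimer, so K_z ~ 0 despite broken symmetry."""
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        kz = s.condensed_lrf_spin(tm)
        assert np.abs(kz.matrix).max() < 1e-4

    def test_spin_response_nonzero_for_asymmetric_bs_dimer(self):
        toy = s.build_two_site_toy(math.pi / 8, exponent=(1.0, 1.8))
        grid, ao = make_grid(toy)
        tm = s.transition_moments(toy.mos, grid, ao)
        kz = s.condensed_lrf_spin(tm)
        assert np.abs(kz.matrix).max() > 1e-3
        assert kz.symmetry_residual() < 1e-6


class TestLRFField:
    def test_field_integrates_to_condensed_column(self, bs_toy):
        """Cell integrals of the pointwise field reproduce column J of K."""
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        k = s.condensed_lrf_density(tm)
        fld = s.lrf_field(bs_toy.mos, tm, bs_toy.geometry, bs_toy.shells,
                          0, grid.points)
        col = s.cell_sums(fld.values, grid)
        np.testing.assert_allclose(col, k.matrix[:, 0], atol=1e-4)

    def test_closed_shell_spin_field_zero(self, closed_shell_toy, toy_grid_ao):
        grid, ao = toy_grid_ao
        tm = s.transition_moments(closed_shell_toy.mos, grid, ao)
        fld = s.lrf_field(closed_shell_toy.mos, tm, closed_shell_toy.geometry,
                          closed_shell_toy.shells, 0, grid.points, spin=True)
        assert np.all(fld.values == 0.0)

    def test_field_shape_is_bond_antibond_product(self, closed_shell_toy):
        """Single-term field is proportional to phi_bond * phi_anti."""
        toy = closed_shell_toy
        grid, ao = make_grid(toy)
        tm = s.transition_moments(toy.mos, grid, ao)
        pts = np.array([[0.1, -0.2, z] for z in np.linspace(-1.5, 2.9, 40)])
        fld = s.lrf_field(toy.mos, tm, toy.geometry, toy.shells, 0, pts)
        ao_pts = s.eval_basis(toy.shells, toy.geometry, pts)
        prod = (ao_pts @ toy.mos.occupied("alpha")[:, 0]) * (
            ao_pts @ toy.mos.virtual("alpha")[:, 0]
        )
        coef = 2 * tm.moments["alpha"][0, 0, 0] / tm.denominators["alpha"][0, 0]
        np.testing.assert_allclose(fld.values, coef * prod, atol=1e-12)


class TestFiniteDifferenceOracle:
    def test_matches_condensed_column_two_site(self, bs_toy):
        """First-order perturbation oracle agrees to 3 significant figures."""
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        k = s.condensed_lrf_density(tm)
        for j in range(2):
            col = s.finite_difference_oracle(bs_toy.mos, grid, ao, j, lam=1e-4)
            np.testing.assert_allclose(
                col, k.matrix[:, j], rtol=2e-3,
                atol=2e-3 * np.abs(k.matrix).max(),
            )

    def test_matches_on_chain(self, chain4):
        sys_ = chain4.system
        grid, ao = make_grid(sys_)
        tm = s.transition_moments(sys_.mos, grid, ao)
        k = s.condensed_lrf_density(tm)
        col = s.finite_difference_oracle(sys_.mos, grid, ao, 1, lam=1e-4)
        np.testing.assert_allclose(
            col, k.matrix[:, 1], rtol=2e-3,
            atol=2e-3 * np.abs(k.matrix).max(),
        )

    def test_richardson_improves_agreement(self, bs_toy):
        """Error shrinks roughly linearly in lambda (first-order oracle)."""
        grid, ao = make_grid(bs_toy)
        tm = s.transition_moments(bs_toy.mos, grid, ao)
        k = s.condensed_lrf_density(tm)
        errs = []
        for lam in (1e-3, 1e-4):
            col = s.finite_difference_oracle(bs_toy.mos, grid, ao, 0, lam=lam)
            errs.append(np.abs(col - k.matrix[:, 0]).max())
        assert errs[1] < errs[0]

    def test_zero_perturbation_gives_zero(self, bs_toy):
        grid, ao = make_grid(bs_toy)
        col = s.finite_difference_oracle(bs_toy.mos, grid, ao, 0, lam=0.0)
        np.testing.assert_array_equal(col, 0.0)

    def test_large_lambda_rejected(self, bs_toy):
        grid, ao = make_grid(bs_toy)
        with pytest.raises(OracleInvalidError):
            s.finite_difference_oracle(bs_toy.mos, grid, ao, 0, lam=0.35)


class TestLocality:
    @pytest.mark.parametrize("n_sites,coupling", [
        (4, [-0.35, -0.05, -0.35]),
        (6, [-0.4, -0.05, -0.4, -0.05, -0.4]),
    ])
    def test_dimerized_chain_response_decays_with_distance(self, n_sites,
                                                           coupling):
        """|K[1,J]| is non-increasing in bond distance on insulating chains.

        Dimerized (alternating-coupling) chains have a robust gap and
        near-sighted response; the uniform metallic chain does not, so the
        locality fixtures are built with alternating couplings.
        """
        fix = s.make_chain_toy(n_sites, coupling=coupling)
        grid, ao = make_grid(fix.system)
        k = s.compute_lrf(fix.system.geometry, fix.system.shells,
                          fix.system.mos, grid)
        row = np.abs(k.matrix[0])
        assert all(row[j] >= row[j + 1] for j in range(1, n_sites - 1))

    def test_ring_constant_diagonal(self):
        """Translational symmetry of a ring forces a constant diagonal up to
        hard-cell condensation noise (the cells are congruent but the fixed
        angular grid orientation differs per site)."""
        fix = s.make_chain_toy(6, ring=True)
        grid, ao = make_grid(fix.system)
        k = s.compute_lrf(fix.system.geometry, fix.system.shells,
                          fix.system.mos, grid)
        d = np.diag(k.matrix)
        np.testing.assert_allclose(d, d[0], rtol=3e-3)
        # exact three-fold repetition survives the grid (C3 maps cells onto
        # cells with identical local orientations)
        np.testing.assert_allclose(d[3:], d[:3], rtol=1e-10)
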