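"""Threshold sections, QM-region suggestion and model-error reports."""

import numpy as np
import pytest

import spinlrf as s
from spinlrf.lrf import CondensedLRF
from tests.conftest import make_grid


def _toy_matrices():
    toy = s.build_two_site_toy(0.0)
    grid, ao = make_grid(toy)
    tm = s.transition_moments(toy.mos, grid, ao)
    k_rho = s.condensed_lrf_density(tm, atom_labels=toy.geometry.labels())
    k_spin = s.condensed_lrf_spin(tm, atom_labels=toy.geometry.labels())
    return toy, k_rho, k_spin


class TestThresholdSections:
    def test_empty_above_max(self):
        _, k, _ = _toy_matrices()
        sec = s.threshold_sections(k, 10 * np.abs(k.matrix).max(), "+")
        assert sec.n_pairs == 0

    def test_two_site_membership_by_hand(self):
        """The closed-form K = k [[1,-1],[-1,1]] with k < 0 puts the diagonal
        in the negative section and off-diagonals in the positive one."""
        _, k, _ = _toy_matrices()
        mag = abs(k.matrix[0, 0])
        pos = s.threshold_sections(k, mag / 2, "+")
        neg = s.threshold_sections(k, mag / 2, "-")
        assert pos.mask.tolist() == [[False, True], [True, False]]
        assert neg.mask.tolist() == [[True, False], [False, True]]

    def test_nesting_across_standard_thresholds(self):
        fix = s.make_chain_toy(4, coupling=[-0.35, -0.05, -0.35])
        grid, ao = make_grid(fix.system)
        k = s.compute_lrf(fix.system.geometry, fix.system.shells,
                          fix.system.mos, grid)
        for sign in ("+", "-"):
            s01 = s.threshold_sections(k, 0.1, sign)
            s001 = s.threshold_sections(k, 0.01, sign)
            s0001 = s.threshold_sections(k, 0.001, sign)
            assert s001.contains(s01)
            assert s0001.contains(s001)

    def test_invalid_threshold(self):
        _, k, _ = _toy_matrices()
        with pytest.raises(ValueError):
            s.threshold_sections(k, -0.1)


class TestSuggestQMRegion:
    def test_high_thresholds_select_rc_only(self):
        _, k_rho, k_spin = _toy_matrices()
        big = 10 * np.abs(k_rho.matrix).max()
        sel = s.suggest_qm_region(k_rho, k_spin, [1], tau_rho=big, tau_m=big)
        assert sel.selected == [1]
        assert sel.rule[1] == "reaction-center"

    def test_two_site_coupling_pulls_in_neighbor(self):
        _, k_rho, k_spin = _toy_matrices()
        tau = abs(k_rho.matrix[0, 1]) / 2
        sel = s.suggest_qm_region(k_rho, k_spin, [1], tau_rho=tau, tau_m=tau)
        assert sel.selected == [1, 2]
        assert sel.rule[2] == "density"

    def test_lowering_threshold_never_shrinks_selection(self):
        fix = s.make_chain_toy(6, coupling=[-0.4, -0.05, -0.4, -0.05, -0.4])
        grid, ao = make_grid(fix.system)
        k_rho = s.compute_lrf(fix.system.geometry, fix.system.shells,
                              fix.system.mos, grid)
        k_spin = s.compute_lrf(fix.system.geometry, fix.system.shells,
                               fix.system.mos, grid, spin=True)
        prev: set = set()
        for tau in (0.5, 0.05, 0.005, 0.0005):
            sel = s.suggest_qm_region(k_rho, k_spin, [1],
                                      tau_rho=tau, tau_m=tau)
            assert prev <= set(sel.selected)
            prev = set(sel.selected)

    def test_monotone_in_reaction_center(self):
        fix = s.make_chain_toy(6, coupling=[-0.4, -0.05, -0.4, -0.05, -0.4])
        grid, ao = make_grid(fix.system)
        k_rho = s.compute_lrf(fix.system.geometry, fix.system.shells,
                              fix.system.mos, grid)
        k_spin = s.compute_lrf(fix.system.geometry, fix.system.shells,
                               fix.system.mos, grid, spin=True)
        small = s.suggest_qm_region(k_rho, k_spin, [1], 0.02, 0.02)
        large = s.suggest_qm_region(k_rho, k_spin, [1, 6], 0.02, 0.02)
        assert set(small.selected) <= set(large.selected)

    def test_fragment_completion_and_cut_bonds(self):
        fix = s.make_chain_toy(4, spacing=1.4,
                               coupling=[-0.35, -0.05, -0.35])
        grid, ao = make_grid(fix.system)
        k_rho = s.compute_lrf(fix.system.geometry, fix.system.shells,
                              fix.system.mos, grid)
        k_spin = s.compute_lrf(fix.system.geometry, fix.system.shells,
                               fix.system.mos, grid, spin=True)
        # H sites 1.4 bohr apart are covalently connected: one fragment
        sel = s.suggest_qm_region(k_rho, k_spin, [1], tau_rho=1e6, tau_m=1e6,
                                  complete_fragments=True,
                                  geometry=fix.system.geometry)
        assert sel.selected == [1, 2, 3, 4]
        assert sel.rule[3] == "fragment-completion"
        assert sel.cut_bonds == []

    def test_rc_outside_system(self):
        _, k_rho, k_spin = _toy_matrices()
        with pytest.raises(IndexError):
            s.suggest_qm_region(k_rho, k_spin, [7])

    def test_empty_rc(self):
        _, k_rho, k_spin = _toy_matrices()
        with pytest.raises(ValueError):
            s.suggest_qm_region(k_rho, k_spin, [])


class TestModelErrorReport:
    def test_identity_model_gives_zeros(self):
        rho = np.array([1.2, 0.8, 2.0])
        rhoz = np.array([0.5, -0.5, 0.0])
        rep = s.model_error_report(rho, rhoz, rho, rhoz,
                                   {1: 1, 2: 2, 3: 3})
        assert rep.max_abs_rho == 0.0
        assert rep.max_abs_rhoz == 0.0

    def test_constructed_shift_appears_exactly(self):
        rho = np.array([1.0, 1.0])
        model_rho = np.array([1.05, 1.0])
        rep = s.model_error_report(rho, np.zeros(2), model_rho, np.zeros(2),
                                   {1: 1, 2: 2})
        assert rep.delta_rho[1] == pytest.approx(0.05)
        assert rep.delta_rho[2] == 0.0
        assert rep.max_abs_rho == pytest.approx(0.05)

    def test_dimer_vs_single_site_cluster_model(self):
        """A one-atom cluster model of the H2 toy reproduces the hand-computed
        cell-density difference."""
        toy = s.build_two_site_toy(0.0)
        grid, ao = make_grid(toy)
        rho, rhoz = s.density_on_grid(toy.mos, ao)
        full_rho = s.condensed_density(rho, grid)
        full_rhoz = s.condensed_density(rhoz, grid)

        # "cluster model": isolated one-electron atom
        geom1 = s.Geometry(["H"], np.array([1]), np.zeros((1, 3)))
        sh1 = [s.GaussianShell(0, 0, [1.0], [1.0])]
        mos1 = s.SpinOrbitalSet(
            coefficients={sp: np.eye(1) for sp in ("alpha", "beta")},
            energies={sp: np.array([-0.5]) for sp in ("alpha", "beta")},
            occupations={"alpha": np.array([1]), "beta": np.array([0])},
        )
        grid1 = s.assemble_ws_grid(geom1, 50, 110)
        ao1 = s.eval_basis(sh1, geom1, grid1.points)
        rho1, rhoz1 = s.density_on_grid(mos1, ao1)
        m_rho = s.condensed_density(rho1, grid1)
        m_rhoz = s.condensed_density(rhoz1, grid1)

        rep = s.model_error_report(full_rho, full_rhoz, m_rho, m_rhoz, {1: 1},
                                   model_label="single-site")
        assert rep.delta_rho[1] == pytest.approx(
            float(m_rho[0] - full_rho[0]), abs=1e-14
        )

    def test_non_injective_map_rejected(self):
        with pytest.raises(ValueError):
            s.model_error_report(np.zeros(2), np.zeros(2), np.zeros(2),
                                 np.zeros(2), {1: 1, 2: 1})

    def test_unmapped_atom_rejected(self):
        with pytest.raises(KeyError):
            s.model_error_report(np.zeros(2), np.zeros(2), np.zeros(2),
                                 np.zeros(2), {3: 1})


class TestHeatmapExport:
    def test_round_trip_and_labels(self, tmp_path):
        toy, k_rho, _ = _toy_matrices()
        path = tmp_path / "k.csv"
        s.heatmap_export(k_rho, path)
        back = CondensedLRF.from_csv(path)
        np.testing.assert_allclose(back.matrix, k_rho.matrix, rtol=1e-10)
        assert back.atom_labels == ["H(1)", "H(2)"]
        sidecar = (tmp_path / "k.csv.json").read_text()
        assert "thresholds" in sidecar

    def test_symmetric_matrix_round_trips_symmetric(self, tmp_path):
        _, k_rho, _ = _toy_matrices()
        path = tmp_path / "k.csv"
        s.heatmap_export(k_rho, path)
        back = CondensedLRF.from_csv(path)
        np.testing.assert_allclose(back.matrix, back.matrix.T, atol=1e-12)
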