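import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vibro import ToySpec, compute_normal_modes, make_toy_molecule, units
from vibro.electron_phonon import (couple, coupling_strength,
                                   displacements_from_geometries,
                                   displacements_linear_response, huang_rhys,
                                   mode_shift, DisplacementSet)
from vibro.embedding_field import FieldMap
from vibro.molecular_io import Molecule
from vibro.normal_modes import eckart_vectors


def uniform_field(mol, e_vec, state="donor"):
    return FieldMap(mol.coords, np.tile(e_vec, (mol.n_atoms, 1)), state=state)


class TestLinearResponse:
    def test_zero_field_zero_displacement(self, diatomic):
        mol, hess, _ = diatomic
        disp = displacements_linear_response(hess, uniform_field(mol, [0, 0, 0]))
        np.testing.assert_allclose(disp.vectors, 0.0)

    def test_missing_charges_raise(self, diatomic):
        mol, hess, _ = diatomic
        mol.charges = None
        with pytest.raises(ValueError, match="charges"):
            displacements_linear_response(hess, uniform_field(mol, [0, 0, 1e-3]))

    def test_diatomic_bond_stretch_closed_form(self, diatomic):
        # charges +/-q in an axial field E: the bond coordinate feels a
        # force qE, so the bond length changes by qE/k
        mol, hess, _ = diatomic
        q, k, e = 0.3, 0.25, 2e-3
        disp = displacements_linear_response(hess, uniform_field(mol, [0, 0, e]))
        stretch = disp.vectors[0, 2] - disp.vectors[1, 2]  # along -bond
        assert abs(stretch) == pytest.approx(q * e / k, rel=1e-10)

    def test_triatomic_matches_numerical_minimizer(self, bent_triatomic):
        from scipy.linalg import null_space
        from scipy.optimize import minimize

        mol, hess, _ = bent_triatomic
        fmap = uniform_field(mol, [1e-3, 0.0, -2e-3])
        disp = displacements_linear_response(hess, fmap)

        forces = (mol.charges[:, None] * fmap.vectors).ravel()
        # independent internal basis: null space of the Eckart rows in
        # mass-weighted coordinates, mapped back to Cartesian
        tr = eckart_vectors(mol)
        basis_mw = null_space(tr)  # (3N, 3N-6)
        sqm = np.sqrt(np.repeat(mol.masses, 3))

        def energy(z):
            x = (basis_mw @ z) / sqm
            return 0.5 * x @ hess.matrix @ x - forces @ x

        def grad(z):
            x = (basis_mw @ z) / sqm
            return basis_mw.T @ ((hess.matrix @ x - forces) / sqm)

        res = minimize(energy, np.zeros(basis_mw.shape[1]), jac=grad,
                       method="BFGS", options={"gtol": 1e-14})
        x_opt = ((basis_mw @ res.x) / sqm).reshape(-1, 3)
        np.testing.assert_allclose(disp.vectors, x_opt, atol=1e-8)

    def test_displacements_lie_in_internal_subspace(self, bent_triatomic):
        mol, hess, _ = bent_triatomic
        disp = displacements_linear_response(
            hess, uniform_field(mol, [5e-4, 1e-3, 0.0]))
        tr = eckart_vectors(mol)
        mw = (np.sqrt(np.repeat(mol.masses, 3)) * disp.vectors.ravel())
        np.testing.assert_allclose(tr @ mw, 0.0, atol=1e-12)


class TestGeometryDifference:
    def test_identical_geometries_zero(self, bent_triatomic):
        mol, _, _ = bent_triatomic
        disp = displacements_from_geometries(mol, mol)
        np.testing.assert_allclose(disp.vectors, 0.0, atol=1e-12)

    def test_rigid_rotation_removed_by_alignment(self, bent_triatomic):
        from scipy.spatial.transform import Rotation

        mol, _, _ = bent_triatomic
        rot = Rotation.from_euler("xyz", [10, -20, 30], degrees=True).as_matrix()
        moved = Molecule(mol.symbols, mol.coords @ rot.T + [1.0, -2.0, 0.5],
                         masses=mol.masses)
        disp = displacements_from_geometries(mol, moved)
        np.testing.assert_allclose(disp.vectors, 0.0, atol=1e-8)

    def test_known_bond_stretch_recovered(self, diatomic):
        mol, _, _ = diatomic
        stretched = Molecule(mol.symbols,
                             mol.coords + [[0, 0, 0], [0, 0, 0.05]],
                             masses=mol.masses)
        disp = displacements_from_geometries(mol, stretched)
        dr = (disp.vectors[1] - disp.vectors[0]) * units.ANGSTROM_PER_BOHR
        np.testing.assert_allclose(dr, [0, 0, 0.05], atol=1e-6)

    def test_atom_count_mismatch(self, diatomic, bent_triatomic):
        with pytest.raises(ValueError, match="atom count"):
            displacements_from_geometries(diatomic[0], bent_triatomic[0])


class TestModeShift:
    def test_single_mode_pattern_projects_onto_itself_only(self, bent_modes):
        mol, _, nm = bent_modes
        disp = DisplacementSet(0.01 * nm.vectors[1], "linear_response")
        dpi = mode_shift(nm, disp)
        expected = np.zeros(nm.n_modes)
        expected[1] = 0.01  # sum m y.y = 1 by normalization
        np.testing.assert_allclose(dpi, expected, atol=1e-10)

    def test_pure_translation_projects_to_zero(self, bent_modes):
        mol, _, nm = bent_modes
        disp = DisplacementSet(np.tile([0.02, -0.01, 0.03], (3, 1)),
                               "geometry_difference")
        np.testing.assert_allclose(mode_shift(nm, disp), 0.0, atol=1e-12)

    def test_internal_displacement_reconstructed_from_projections(
            self, bent_modes, rng):
        mol, _, nm = bent_modes
        raw = rng.normal(size=(3, 3))
        sqm = np.sqrt(np.repeat(mol.masses, 3))
        tr = eckart_vectors(mol)
        mw = sqm * raw.ravel()
        mw -= tr.T @ (tr @ mw)  # internal part in mass-weighted coords
        disp = DisplacementSet((mw / sqm).reshape(3, 3), "linear_response")
        dpi = mode_shift(nm, disp)
        recon = dpi @ nm.mass_weighted_vectors()
        np.testing.assert_allclose(recon, mw, atol=1e-8)


class TestCouplingStrength:
    def test_zero_shift_zero_coupling(self):
        assert coupling_strength(1000.0, 0.0) == 0.0

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            coupling_strength(-10.0, 1.0)

    def test_displaced_oscillator_closed_form(self):
        # |u| = delta sqrt(m omega / 2 hbar) for a 1-D oscillator of mass m
        # whose equilibrium shifts by delta (so dPi = sqrt(m) delta)
        m_amu, freq, delta_bohr = 1.5, 800.0, 0.02
        u = coupling_strength(freq, math.sqrt(m_amu) * delta_bohr)
        omega_au = units.angular_frequency_au(freq)
        expected = delta_bohr * math.sqrt(m_amu * units.AMU_PER_ME * omega_au / 2.0)
        assert abs(u) == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_field_strength(self, diatomic):
        mol, hess, _ = diatomic
        nm = compute_normal_modes(hess)
        us = []
        for scale in (1.0, 2.0):
            disp = displacements_linear_response(
                hess, uniform_field(mol, [0, 0, scale * 1e-3]))
            us.append(coupling_strength(nm.frequencies,
                                        mode_shift(nm, disp))[0])
        assert us[1] == pytest.approx(2.0 * us[0], rel=1e-10)


class TestHuangRhys:
    def test_equal_couplings_all_weight_in_sigma0(self):
        s, sigma = huang_rhys(0.7, 0.7)
        assert s == 0.0
        assert sigma[0] == 1.0
        np.testing.assert_allclose(sigma[1:], 0.0)

    def test_s_equal_one_sigma1_is_inverse_e(self):
        s, sigma = huang_rhys(1.0, 0.0)
        assert s == 1.0
        assert sigma[1] == pytest.approx(math.exp(-1.0), rel=1e-12)

    @pytest.mark.parametrize("s_target", [0.5, 2.0, 5.0])
    def test_distribution_peaks_near_poisson_mode(self, s_target):
        _, sigma = huang_rhys(math.sqrt(s_target), 0.0, n_max=30)
        assert abs(int(np.argmax(sigma)) - s_target) <= 1

    @given(st.floats(min_value=0.0, max_value=math.sqrt(10.0)))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_normalization_sums_to_one(self, du):
        _, sigma = huang_rhys(du, 0.0, n_max=50)
        assert sigma.sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-2.0, 2.0), st.floats(-2.0, 2.0))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_swapping_donor_acceptor_invariant(self, ud, ua):
        s1, sig1 = huang_rhys(ud, ua)
        s2, sig2 = huang_rhys(ua, ud)
        assert s1 == s2
        np.testing.assert_array_equal(sig1, sig2)

    def test_literal_printed_variant_available(self):
        s, sigma = huang_rhys(1.0, 0.0, normalized=False)
        assert sigma[1] == pytest.approx(math.exp(1.0), rel=1e-12)


class TestEndToEnd:
    def _pipeline_s(self, diatomic, e_field):
        mol, hess, _ = diatomic
        nm = compute_normal_modes(hess)
        disp_d = displacements_linear_response(
            hess, uniform_field(mol, [0, 0, e_field], "donor"))
        disp_a = displacements_linear_response(
            hess, uniform_field(mol, [0, 0, -e_field], "acceptor"))
        return couple(nm, disp_d, disp_a), nm

    def test_sigma1_matches_hand_derived_closed_form(self, diatomic):
        """Oracle equivalence on the synthetic diatomic: the pipeline's S
        and sigma_1 equal the displaced-harmonic-oscillator closed form
        assembled independently from the same inputs."""
        mol, hess, truth = diatomic
        q, k, e = 0.3, 0.25, 5e-3
        table, nm = self._pipeline_s(diatomic, e)
        # closed form: flipping the axial field shifts the bond coordinate
        # by delta = 2qE/k; reduced mass 1 amu; S = delta^2 mu omega / 2hbar
        delta = 2.0 * q * e / k
        omega_au = units.angular_frequency_au(nm.frequencies[0])
        mu_me = 1.0 * units.AMU_PER_ME
        s_expected = delta**2 * mu_me * omega_au / 2.0
        sigma1_expected = s_expected * math.exp(-s_expected)
        assert table.huang_rhys_s[0] == pytest.approx(s_expected, rel=1e-8)
        assert table.sigma1[0] == pytest.approx(sigma1_expected, rel=1e-8)

    def test_doubling_field_difference_quadruples_s(self, diatomic):
        t1, _ = self._pipeline_s(diatomic, 1e-3)
        t2, _ = self._pipeline_s(diatomic, 2e-3)
        assert t2.huang_rhys_s[0] == pytest.approx(4.0 * t1.huang_rhys_s[0],
                                                   rel=1e-10)

    def test_table_frame_columns(self, diatomic):
        table, _ = self._pipeline_s(diatomic, 1e-3)
        df = table.to_frame()
        assert list(df.columns) == ["mode", "frequency_cm1", "dpi_donor",
                                    "dpi_acceptor", "u_donor", "u_acceptor",
                                    "S", "sigma1"]
        assert (df["S"] >= 0).all()
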