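"""Active-strain kinematics, Guccione law, homogeneous contraction, volumes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from atriomech.continuum import (
    active_strain,
    active_deformation,
    elastic_strains,
    fibre_frame,
    GuccioneParameters,
    guccione_energy,
    second_pk_stress,
    block_energy,
    uniaxial_active_contraction,
    enclosed_volume,
)
from atriomech.fixtures import make_icosphere


def random_unit(seed):
    v = np.random.default_rng(seed).standard_normal(3)
    return v / np.linalg.norm(v)


class TestActiveDeformation:
    def test_zero_strain_is_identity(self):
        assert np.allclose(active_deformation(0.0, [1, 0, 0]), np.eye(3))

    def test_shortening_along_x(self):
        F0 = active_deformation(-0.1, [1.0, 0.0, 0.0])
        assert np.allclose(F0, np.diag([0.9, 1.0, 1.0]))
        assert np.isclose(np.linalg.det(F0), 0.9)

    @given(st.integers(0, 1000), st.floats(-0.5, 0.5))
    def test_eigenvalues_are_one_plus_gamma_and_unity(self, seed, gamma):
        f = random_unit(seed)
        eig = np.sort(np.linalg.eigvalsh(active_deformation(gamma, f)))
        expected = np.sort([1.0 + gamma, 1.0, 1.0])
        assert np.allclose(eig, expected, atol=1e-12)

    def test_non_invertible_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            active_deformation(-1.0, [1, 0, 0])

    def test_non_unit_fibre_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            active_deformation(0.1, [1.0, 1.0, 0.0])


class TestActiveStrain:
    @pytest.mark.parametrize(
        "SL, SL0, expected",
        [(1.9, 1.9, 0.0), (0.9 * 1.9, 1.9, -0.1), (1.1 * 1.9, 1.9, 0.1)],
    )
    def test_definition(self, SL, SL0, expected):
        assert np.isclose(active_strain(SL, SL0), expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            active_strain(1.9, 0.0)


class TestElasticStrains:
    def test_pure_active_deformation_has_no_elastic_strain(self):
        F0 = active_deformation(-0.2, [0, 1, 0])
        Fe, Ce, Ee = elastic_strains(F0, F0)
        assert np.allclose(Fe, np.eye(3), atol=1e-12)
        assert np.allclose(Ee, 0.0, atol=1e-12)

    def test_identity_total_with_active_shortening(self):
        F0 = active_deformation(-0.1, [1, 0, 0])
        Fe, _, _ = elastic_strains(np.eye(3), F0)
        assert np.allclose(Fe, np.diag([1 / 0.9, 1.0, 1.0]))

    @given(st.integers(0, 500))
    def test_objectivity_Ce_invariant_under_rotation(self, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        if abs(np.linalg.det(F)) < 0.2:
            F = np.eye(3)
        F0 = active_deformation(-0.1, random_unit(seed + 1))
        R = Rotation.random(random_state=seed).as_matrix()
        _, Ce1, _ = elastic_strains(F, F0)
        _, Ce2, _ = elastic_strains(R @ F, F0)
        assert np.allclose(Ce1, Ce2, atol=1e-10)

    def test_singular_active_part_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            elastic_strains(np.eye(3), np.zeros((3, 3)))


class TestGuccione:
    def test_energy_at_zero_strain_is_C1(self):
        assert np.isclose(guccione_energy(np.zeros((3, 3))), 0.831)

    def test_fibre_stretch_term(self):
        E = np.zeros((3, 3))
        E[0, 0] = 0.1
        W = guccione_energy(E)
        assert np.isclose(W, 0.831 * np.exp(14.31 * 0.01))

    def test_transverse_isotropy_axes_2_3_swap(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((3, 3)) * 0.1
        E = 0.5 * (A + A.T)
        P = np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
        assert np.isclose(guccione_energy(E), guccione_energy(P @ E @ P.T))

    @given(st.integers(0, 300))
    def test_energy_positive_and_minimal_at_zero(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3)) * 0.2
        E = 0.5 * (A + A.T)
        W = guccione_energy(E)
        assert W > 0
        assert W >= guccione_energy(np.zeros((3, 3))) - 1e-12

    @given(st.integers(0, 300))
    def test_frame_indifference_through_elastic_strain(self, seed):
        rng = np.random.default_rng(seed)
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        F0 = active_deformation(-0.05, [1, 0, 0])
        R = Rotation.random(random_state=seed).as_matrix()
        _, _, Ee1 = elastic_strains(F, F0)
        _, _, Ee2 = elastic_strains(R @ F, F0)
        assert np.isclose(guccione_energy(Ee1), guccione_energy(Ee2), rtol=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GuccioneParameters(C1=-1.0)


class TestStress:
    def test_zero_strain_zero_pressure_is_stress_free(self):
        S = second_pk_stress(np.zeros((3, 3)), p=0.0)
        assert np.allclose(S, 0.0)

    @given(st.integers(0, 200))
    def test_matches_finite_difference_gradient(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((3, 3)) * 0.15
        E = 0.5 * (A + A.T)
        S = second_pk_stress(E)
        h = 1e-6
        for i in range(3):
            for j in range(3):
                Ep, Em = E.copy(), E.copy()
                Ep[i, j] += h
                Em[i, j] -= h
                fd = (guccione_energy(Ep) - guccione_energy(Em)) / (2 * h)
                assert np.isclose(S[i, j], fd, rtol=1e-6, atol=1e-9)

    def test_linear_in_C1(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3)) * 0.1
        E = 0.5 * (A + A.T)
        S1 = second_pk_stress(E, GuccioneParameters())
        S2 = second_pk_stress(E, GuccioneParameters(C1=2 * 0.831))
        assert np.allclose(S2, 2 * S1)

    def test_pressure_term_uses_inverse_Ce(self):
        E = np.zeros((3, 3))
        S = second_pk_stress(E, p=1.0)
        assert np.allclose(S, -np.eye(3))


class TestUniaxialContraction:
    def test_passive_block_stays_undeformed(self):
        lam_f, lam_t = uniaxial_active_contraction(0.0)
        assert np.isclose(lam_f, 1.0, atol=1e-5)
        assert np.isclose(lam_t, 1.0, atol=1e-5)

    def test_fibre_shortens_and_bulges_transversely(self):
        lam_f, lam_t = uniaxial_active_contraction(-0.1)
        assert lam_f < 1.0
        assert lam_t > 1.0
        assert np.isclose(lam_f * lam_t**2, 1.0)

    def test_matches_dense_grid_search(self):
        gamma = -0.15
        lam_f, _ = uniaxial_active_contraction(gamma)
        grid = np.linspace(0.7, 1.3, 6001)
        energies = [block_energy(l, gamma) for l in grid]
        assert abs(lam_f - grid[int(np.argmin(energies))]) < 1e-4

    def test_shortening_monotone_in_activation(self):
        lams = [uniaxial_active_contraction(g)[0] for g in (-0.05, -0.1, -0.2)]
        assert lams[0] > lams[1] > lams[2]

    def test_out_of_range_gamma_rejected(self):
        with pytest.raises(ValueError):
            uniaxial_active_contraction(0.6)


class TestEnclosedVolume:
    def test_unit_icosphere_volume(self):
        v, f = make_icosphere(3, 1.0)
        vol = enclosed_volume(v, f)
        assert abs(vol - 4 * np.pi / 3) / (4 * np.pi / 3) < 0.01

    def test_agrees_with_independent_mesh_library(self):
        import trimesh

        v, f = make_icosphere(2, 1.7)
        mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
        assert np.isclose(enclosed_volume(v, f), mesh.volume, rtol=1e-10)

    def test_uniform_scaling_cubes_the_volume(self):
        v, f = make_icosphere(2, 1.0)
        ref = enclosed_volume(v, f)
        deformed = enclosed_volume(v, f, lambda x: 0.9 * x)
        assert np.isclose(deformed, 0.9**3 * ref, rtol=1e-12)

    def test_rigid_rotation_preserves_volume(self):
        v, f = make_icosphere(2, 1.0)
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        ref = enclosed_volume(v, f)
        rot = enclosed_volume(v, f, lambda x: (x + 1.5) @ R.T)
        assert np.isclose(rot, ref, rtol=1e-12)

    def test_second_order_convergence_under_refinement(self):
        errs = []
        for r in (1, 2, 3):
            v, f = make_icosphere(r, 1.0)
            errs.append(abs(enclosed_volume(v, f) - 4 * np.pi / 3))
        # each refinement level should cut the error by about 4x
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_open_mesh_rejected(self):
        v, f = make_icosphere(0, 1.0)
        with pytest.raises(ValueError, match="closed|twin"):
            enclosed_volume(v, f[:-1])

    def test_inconsistent_orientation_rejected(self):
        v, f = make_icosphere(0, 1.0)
        f = f.copy()
        f[0] = f[0][::-1]
        with pytest.raises(ValueError):
            enclosed_volume(v, f)

    def test_inward_normals_rejected(self):
        v, f = make_icosphere(0, 1.0)
        with pytest.raises(ValueError, match="outward"):
            enclosed_volume(v, f[:, ::-1])


def test_fibre_frame_is_orthonormal_with_fibre_first():
    for seed in range(5):
        f = random_unit(seed)
        R = fibre_frame(f)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.allclose(R[0], f)
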