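"""Promolecular density, RDG, lambda2 classification, grid scanning."""

import numpy as np
import pytest

from flavodesc.nci import (
    classify_voxels,
    density_params,
    promolecular_density,
    reduced_density_gradient,
    scan_grid,
    sign_lambda2_rho,
)
from flavodesc.synthetic import gen_diatomic_nci

RDG_CONST = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)


class TestPromolecularDensity:
    def test_single_shell_atom_closed_form(self):
        (c, a), = density_params("H").shells
        r = 2.3
        rho, grad, hess = promolecular_density([r, 0, 0], [("H", [0, 0, 0])])
        assert rho == pytest.approx(c * np.exp(-a * r), rel=1e-14)
        assert np.linalg.norm(grad) == pytest.approx(a * rho, rel=1e-12)

    def test_midpoint_gradient_vanishes_by_symmetry(self):
        atoms = [("O", [-2.0, 0, 0]), ("O", [2.0, 0, 0])]
        _, grad, _ = promolecular_density([0.0, 0.0, 0.0], atoms)
        assert np.all(grad == 0.0)

    def test_gradient_hessian_vs_finite_differences(self, rng):
        atoms = [
            ("C", rng.uniform(-2, 2, 3)),
            ("O", rng.uniform(-2, 2, 3)),
            ("H", rng.uniform(-2, 2, 3)),
        ]
        point = rng.uniform(-1, 1, 3) + 3.0  # keep away from nuclei
        rho, grad, hess = promolecular_density(point, atoms)
        h = 1e-5
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            rp, gp, _ = promolecular_density(point + e, atoms)
            rm, gm, _ = promolecular_density(point - e, atoms)
            assert grad[k] == pytest.approx((rp - rm) / (2 * h), rel=1e-6)
            assert hess[:, k] == pytest.approx((gp - gm) / (2 * h), rel=1e-6, abs=1e-12)

    def test_unparameterized_element_named(self):
        with pytest.raises(KeyError, match="Xx"):
            promolecular_density([1, 0, 0], [("Xx", [0, 0, 0])])

    def test_empty_atom_list_rejected(self):
        with pytest.raises(ValueError):
            promolecular_density([0, 0, 0], [])

    def test_rigid_motion_equivariance(self, rng):
        from scipy.spatial.transform import Rotation

        atoms = [("O", rng.uniform(-2, 2, 3)), ("H", rng.uniform(-2, 2, 3))]
        point = rng.uniform(1, 2, 3)
        rho0, grad0, _ = promolecular_density(point, atoms)
        Q = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        moved = [(e, Q @ np.asarray(p) + shift) for e, p in atoms]
        rho1, grad1, _ = promolecular_density(Q @ point + shift, moved)
        assert rho1 == pytest.approx(rho0, rel=1e-10)
        assert np.linalg.norm(grad1) == pytest.approx(np.linalg.norm(grad0), rel=1e-10)


class TestReducedDensityGradient:
    def test_zero_gradient_gives_zero(self):
        assert reduced_density_gradient(0.01, [0.0, 0.0, 0.0]) == 0.0

    def test_single_exponential_closed_form(self):
        """For a one-shell atom, s(r) = alpha / (2 (3 pi^2)^(1/3) rho^(1/3))."""
        (c, a), = density_params("H").shells
        for r in (0.5, 1.0, 3.0, 6.0):
            rho, grad, _ = promolecular_density([0, r, 0], [("H", [0, 0, 0])])
            s = reduced_density_gradient(rho, grad)
            expected = a / (RDG_CONST * rho ** (1.0 / 3.0))
            assert s == pytest.approx(expected, rel=1e-10)

    def test_density_scaling_law(self):
        g = [0.0, 0.0, 0.02]
        s1 = reduced_density_gradient(0.01, g)
        s2 = reduced_density_gradient(0.02, g)
        assert s2 == pytest.approx(s1 * 2.0 ** (-4.0 / 3.0), rel=1e-12)

    def test_nonpositive_rho_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            reduced_density_gradient(0.0, [1, 0, 0])


class TestSignLambda2Rho:
    def test_diagonal_hessian_middle_eigenvalue(self):
        assert sign_lambda2_rho(0.01, np.diag([-2.0, -1.0, 3.0])) == pytest.approx(-0.01)

    def test_identity_hessian_positive(self):
        assert sign_lambda2_rho(0.01, np.eye(3)) == pytest.approx(0.01)

    def test_zero_lambda2_maps_to_zero(self):
        assert sign_lambda2_rho(0.5, np.diag([-1.0, 0.0, 2.0])) == 0.0

    def test_single_atom_lambda2_negative_off_nucleus(self, rng):
        """Spherically decaying density has negative tangential curvature:
        lambda2 = -alpha rho / r < 0 everywhere off the nucleus."""
        for _ in range(20):
            point = rng.uniform(-4, 4, 3)
            if np.linalg.norm(point) < 0.2:
                continue
            rho, _, hess = promolecular_density(point, [("C", [0, 0, 0])])
            assert sign_lambda2_rho(rho, hess) < 0.0

    def test_asymmetric_hessian_rejected(self):
        H = np.eye(3)
        H[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            sign_lambda2_rho(0.1, H)


class TestScanGrid:
    def test_diatomic_midpoint_voxel_has_zero_rdg(self):
        atoms, truth = gen_diatomic_nci(separation=5.6)
        grid = scan_grid(atoms, spacing=0.2, box=([-4.0, -2.0, -2.0], [4.0, 2.0, 2.0]))
        # the origin (midpoint) lies exactly on the voxel lattice
        idx = tuple(
            int(round((truth["midpoint"][k] - grid.origin[k]) / grid.spacing[k]))
            for k in range(3)
        )
        assert grid.rdg[idx] == pytest.approx(0.0, abs=1e-10)
        assert grid.rho[idx] > 0

    def test_single_voxel_box(self):
        grid = scan_grid([("H", [0.0, 0.0, 0.0])], spacing=10.0, margin=1.0)
        assert grid.dims == (1, 1, 1)

    def test_halving_spacing_doubles_dims(self):
        atoms = [("O", [0.0, 0.0, 0.0]), ("O", [3.0, 0.0, 0.0])]
        d1 = scan_grid(atoms, spacing=0.5, margin=2.0).dims
        d2 = scan_grid(atoms, spacing=0.25, margin=2.0).dims
        for a, b in zip(d1, d2):
            assert b in (2 * a - 2, 2 * a - 1, 2 * a)

    def test_voxel_budget_enforced(self):
        atoms = [("O", [0.0, 0.0, 0.0])]
        with pytest.raises(ValueError, match="budget"):
            scan_grid(atoms, spacing=0.01, margin=5.0, max_voxels=1000)

    def test_single_atom_grid_all_signed_negative(self):
        grid = scan_grid([("O", [0.0, 0.0, 0.0])], spacing=0.5, margin=3.0)
        # every off-nucleus voxel of a spherical density has lambda2 < 0
        r = np.linalg.norm(
            np.stack(
                np.meshgrid(
                    *[grid.origin[k] + grid.spacing[k] * np.arange(grid.dims[k]) for k in range(3)],
                    indexing="ij",
                ),
                axis=-1,
            ),
            axis=-1,
        )
        off = r > 1e-3
        assert np.all(grid.signed_density[off] < 0)
        assert np.all(grid.rho > 0)
        np.testing.assert_allclose(np.abs(grid.signed_density), grid.rho, rtol=1e-12)


class TestClassifyVoxels:
    def test_single_atom_has_no_interaction_voxels(self):
        grid = scan_grid([("C", [0.0, 0.0, 0.0])], spacing=0.4, margin=4.0)
        counts, _ = classify_voxels(grid, rdg_threshold=0.3)
        # an isolated atom has no partner: nothing that is simultaneously
        # low-RDG and in the low-density window
        assert counts["selected"] == 0

    def test_diatomic_attractive_or_vdw_region_at_midpoint(self):
        atoms, _ = gen_diatomic_nci(separation=5.6)
        grid = scan_grid(atoms, spacing=0.2, box=([-4.0, -2.0, -2.0], [4.0, 2.0, 2.0]))
        counts, masks = classify_voxels(grid)
        assert counts["selected"] > 0
        assert counts["attractive"] + counts["vanderwaals"] > 0
        assert (
            counts["attractive"] + counts["vanderwaals"] + counts["repulsive"]
            == counts["selected"]
        )

    def test_exclusive_thresholds_select_nothing(self):
        grid = scan_grid([("O", [0.0, 0.0, 0.0]), ("O", [3.0, 0.0, 0.0])], spacing=0.5, margin=2.0)
        counts, masks = classify_voxels(grid, density_window=1e-12, rdg_threshold=1e-12)
        assert counts["selected"] == 0
        assert all(not m.any() for m in masks.values())
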