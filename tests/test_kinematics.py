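"""Registration, deformation gradients, Green-Lagrange strain, CRL frame."""

import numpy as np
import pytest
from scipy import ndimage

from strain2scar.kinematics import (RegistrationParams, build_crl_basis,
                                    green_lagrange, incremental_gradient,
                                    propagate, register, registration_cost,
                                    to_crl)


class TestRegistration:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            register(np.zeros((8, 8)), np.zeros((8, 9)))
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            register(np.zeros((8, 8)), bad)
        with pytest.raises(ValueError):
            RegistrationParams(sigma_i=-1.0)

    def test_identical_frames_zero_motion(self, smooth_test_image):
        res = register(smooth_test_image, smooth_test_image)
        assert np.abs(res.displacement).mean() < 0.05

    def test_translation_recovery(self, smooth_test_image):
        """A known 3-pixel shift is recovered within 0.5 px mean error."""
        moving = ndimage.shift(smooth_test_image, (3, 0), order=3)
        res = register(smooth_test_image, moving)
        interior = (slice(5, -5), slice(5, -5))
        err = np.hypot(res.displacement[..., 0][interior] - 3.0,
                       res.displacement[..., 1][interior]).mean()
        assert err < 0.5

    def test_cost_monotone_and_below_start(self, smooth_test_image):
        moving = ndimage.shift(smooth_test_image, (2, 1), order=3)
        res = register(smooth_test_image, moving)
        assert all(np.diff(res.costs) <= 1e-12)
        params = RegistrationParams()
        start = registration_cost(smooth_test_image, moving,
                                  np.zeros(res.displacement.shape),
                                  np.zeros(res.displacement.shape), params)
        final = registration_cost(smooth_test_image, moving,
                                  res.correspondence, res.displacement, params)
        assert final <= start


class TestDeformationGradient:
    def test_zero_displacement_gives_identity(self):
        F = incremental_gradient(np.zeros((8, 8, 2)))
        assert np.allclose(F, np.eye(3))

    def test_uniform_stretch(self):
        gy, gx = np.mgrid[0:16, 0:16].astype(float)
        u = np.stack([0.1 * gy, np.zeros_like(gx)], axis=-1)
        F = incremental_gradient(u)
        assert np.allclose(F[4:-4, 4:-4], np.diag([1.1, 1.0, 1.0]))

    def test_matches_independent_gradient_oracle(self):
        rng = np.random.default_rng(0)
        u = ndimage.gaussian_filter(rng.standard_normal((20, 20, 2)), (2, 2, 0))
        F = incremental_gradient(u)
        # independent oracle: loop-based central/one-sided differences
        for comp in range(2):
            for ax in range(2):
                g = np.gradient(u[..., comp], axis=ax)
                assert np.allclose(F[..., comp, ax] - (comp == ax), g,
                                   atol=1e-8)

    def test_propagate_orders_increments(self):
        grid = (4, 4)
        def const_F(mat):
            F = np.zeros(grid + (3, 3))
            F[...] = mat
            return F
        eye = const_F(np.eye(3))
        assert np.allclose(propagate([eye]), np.eye(3))
        stretch = const_F(np.diag([1.1, 1.0, 1.0]))
        assert np.allclose(propagate([stretch, stretch]),
                           np.diag([1.21, 1.0, 1.0]))
        with pytest.raises(ValueError):
            propagate([])

    def test_propagate_matches_composed_affine(self):
        """Product of two affine increments equals the one-step composition."""
        rng = np.random.default_rng(1)
        A1 = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        A2 = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        grid = (3, 3)
        F1 = np.broadcast_to(A1, grid + (3, 3))
        F2 = np.broadcast_to(A2, grid + (3, 3))
        total = propagate([F1, F2])  # F2 applied after F1
        assert np.allclose(total, A2 @ A1)


class TestGreenLagrange:
    def test_identity_gives_zero(self):
        assert np.allclose(green_lagrange(np.eye(3)), 0.0)

    def test_uniaxial_stretch(self):
        E = green_lagrange(np.diag([1.1, 1.0, 1.0]))
        assert np.isclose(E[0, 0], 0.105)
        assert np.allclose(E - np.diag([0.105, 0, 0]), 0.0)

    def test_simple_shear(self):
        F = np.eye(3)
        F[0, 1] = 0.2
        E = green_lagrange(F)
        assert np.isclose(E[0, 1], 0.1)
        assert np.isclose(E[1, 0], 0.1)
        assert np.isclose(E[1, 1], 0.02)
        assert np.isclose(E[0, 0], 0.0)

    def test_symmetry_for_random_f(self):
        rng = np.random.default_rng(2)
        F = np.eye(3) + 0.1 * rng.standard_normal((10, 3, 3))
        E = green_lagrange(F)
        assert np.allclose(E, np.swapaxes(E, -1, -2))


class TestCRLBasis:
    def test_east_point_convention(self):
        Q = build_crl_basis((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
        radial, longitudinal = Q[1], Q[2]
        assert np.allclose(radial, [1, 0, 0])
        assert np.allclose(longitudinal, [0, 0, 1])
        # circumferential along +/- y, completing a right-handed triad
        assert np.allclose(np.abs(Q[0]), [0, 1, 0])
        assert np.allclose(Q[0], np.cross(radial, longitudinal))

    def test_orthonormality_random_points(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            point = rng.uniform(-1, 1, 3)
            if np.hypot(point[0], point[1]) < 1e-3:
                continue
            Q = build_crl_basis((0, 0, 0), point)
            assert np.allclose(Q @ Q.T, np.eye(3), atol=1e-10)
            assert np.isclose(np.linalg.det(Q), 1.0, atol=1e-10)

    def test_basis_rotates_with_point(self):
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        p = np.array([1.0, 0.2, 0.0])
        Q1 = build_crl_basis((0, 0, 0), p)
        Q2 = build_crl_basis((0, 0, 0), R @ p)
        assert np.allclose(Q2[0], R @ Q1[0], atol=1e-12)  # circumferential
        assert np.allclose(Q2[1], R @ Q1[1], atol=1e-12)  # radial

    def test_center_point_rejected(self):
        with pytest.raises(ValueError):
            build_crl_basis((0, 0, 0), (0, 0, 0))


class TestToCRL:
    def test_identity_basis_passthrough(self):
        E = np.diag([0.1, 0.2, 0.3])
        E_crl, comps = to_crl(E, np.eye(3))
        assert np.allclose(E_crl, E)
        assert comps["CC"] == 0.1 and comps["RR"] == 0.2 and comps["LL"] == 0.3

    def test_quarter_turn_swaps_cc_rr(self):
        E = np.diag([0.1, 0.3, 0.0])
        Q = np.array([[0, 1, 0], [-1, 0, 0], [0, 0, 1.0]])
        _, comps = to_crl(E, Q)
        assert np.isclose(comps["CC"], 0.3)
        assert np.isclose(comps["RR"], 0.1)

    def test_trace_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            A = rng.standard_normal((3, 3))
            E = 0.5 * (A + A.T)
            point = rng.uniform(0.2, 1.0, 3)
            Q = build_crl_basis((0, 0, 0), point)
            E_crl, _ = to_crl(E, Q)
            assert np.isclose(np.trace(E_crl), np.trace(E), atol=1e-10)

    def test_asymmetric_input_rejected(self):
        E = np.zeros((3, 3))
        E[0, 1] = 0.5
        with pytest.raises(ValueError):
            to_crl(E, np.eye(3))


class TestFullChain:
    def _affine_pair(self, img, A):
        h = img.shape[0]
        gy, gx = np.mgrid[0:h, 0:h]
        c0 = np.array([(h - 1) / 2, (h - 1) / 2])
        src = (np.stack([gy, gx], -1) - c0) @ np.linalg.inv(A).T + c0
        return ndimage.map_coordinates(img, [src[..., 0], src[..., 1]], order=3)

    def test_affine_strain_recovery(self, smooth_test_image):
        """Register a known affine warp and recover its analytic strain
        within 10% relative error (mean over interior pixels)."""
        A = np.array([[1.08, 0.03], [0.02, 0.94]])
        moving = self._affine_pair(smooth_test_image, A)
        params = RegistrationParams(sigma_i=1.0, sigma_x=5.0, sigma_t=5.0,
                                    max_iterations=500, tol=1e-8)
        res = register(smooth_test_image, moving, params)
        E = green_lagrange(incremental_gradient(res.displacement))
        E_true = 0.5 * (A.T @ A - np.eye(2))
        E_in = E[16:-16, 16:-16][..., :2, :2].mean(axis=(0, 1))
        rel = np.abs(E_in - E_true).max() / np.abs(E_true).max()
        assert rel < 0.10

    def test_objectivity_under_rigid_rotation(self):
        """Rigidly rotating the configuration leaves CRL components (with a
        co-rotated basis) unchanged."""
        rng = np.random.default_rng(5)
        A2 = np.eye(2) + 0.08 * rng.standard_normal((2, 2))
        F = np.eye(3)
        F[:2, :2] = A2
        E = green_lagrange(F)
        point = np.array([0.8, 0.3, 0.0])
        Q = build_crl_basis((0, 0, 0), point)
        _, comps = to_crl(E, Q)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        F_rot = R @ F
        E_rot = green_lagrange(F_rot)  # E is rotation-invariant pre-rotation
        _, comps_rot = to_crl(E_rot, Q)
        for key in ("CC", "RR", "LL"):
            assert np.isclose(comps_rot[key], comps[key], atol=1e-12)
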