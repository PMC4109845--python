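"""Collective-mode subtraction, order parameters and the uncorrelated band."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from conftest import random_rotation
from midgeswarm.fixtures import FixtureSpec, planted_mode_swarm
from midgeswarm.io import SwarmFrame
from midgeswarm.modes import (
    DegenerateFrameError,
    decompose,
    dilatational_order,
    fit_dilatation,
    fit_rotation,
    null_band,
    order_parameters,
    polarization,
    rotational_order,
    subtract_translation,
)


def _pair_from_velocity(pos, vel, fps=1.0):
    n = len(pos)
    a = SwarmFrame(0, pos, np.arange(n), vel)
    b = SwarmFrame(1, pos + vel / fps, np.arange(n))
    return a, b


class TestSubtractTranslation:
    def test_pure_translation_gives_zero(self, rng):
        pos = rng.normal(size=(10, 3))
        vel = np.tile([0.3, -0.1, 0.2], (10, 1))
        _, dv = subtract_translation(pos, vel)
        np.testing.assert_allclose(dv, 0.0, atol=1e-15)

    def test_symmetric_pair(self):
        u = np.array([0.5, 0.0, 0.0])
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        _, dv = subtract_translation(pos, np.vstack([u, -u]))
        np.testing.assert_allclose(dv, np.vstack([u, -u]))
        np.testing.assert_allclose(dv.sum(axis=0), 0.0, atol=1e-15)

    def test_matches_mean_subtraction_loop(self, rng):
        pos = rng.normal(size=(20, 3))
        vel = rng.normal(size=(20, 3))
        y, dv = subtract_translation(pos, vel)
        mean_v = sum(vel[i] for i in range(20)) / 20
        mean_x = sum(pos[i] for i in range(20)) / 20
        for i in range(20):
            np.testing.assert_allclose(dv[i], vel[i] - mean_v, rtol=1e-12)
            np.testing.assert_allclose(y[i], pos[i] - mean_x, rtol=1e-12)


class TestFitRotation:
    def test_identity(self, rng):
        y = rng.normal(size=(6, 3))
        rot, _, angle = fit_rotation(y, y)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_planted_rotation_recovered_exactly(self, rng):
        y = rng.normal(size=(6, 3))
        planted = Rotation.from_rotvec([0, 0, np.deg2rad(10)]).as_matrix()
        rot, axis, angle = fit_rotation(y, y @ planted.T)
        np.testing.assert_allclose(rot, planted, atol=1e-9)
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-9)
        assert angle == pytest.approx(np.deg2rad(10), abs=1e-9)

    def test_angle_is_nonnegative(self, rng):
        y = rng.normal(size=(8, 3))
        planted = Rotation.from_rotvec([0, 0, -np.deg2rad(25)]).as_matrix()
        _, axis, angle = fit_rotation(y, y @ planted.T)
        assert angle >= 0
        np.testing.assert_allclose(axis, [0, 0, -1], atol=1e-9)

    def test_noisy_rotation_matches_grid_search_oracle(self, rng):
        y = rng.normal(size=(12, 3))
        planted = Rotation.from_rotvec([0, 0, np.deg2rad(10)]).as_matrix()
        y_next = y @ planted.T + rng.normal(scale=0.01, size=y.shape)
        rot, _, _ = fit_rotation(y, y_next)

        def cost(mat):
            return np.sum((y_next - y @ mat.T) ** 2)

        # coarse grid over axis-angle space around z
        best = (np.inf, None)
        for ax in np.deg2rad(np.arange(-10, 11, 2)):
            for az in np.deg2rad(np.arange(-10, 11, 2)):
                for ang in np.deg2rad(np.arange(0, 20.5, 0.5)):
                    axis = np.array(
                        [np.sin(ax), np.sin(az) * np.cos(ax), 0.0]
                    )
                    axis[2] = np.sqrt(max(0.0, 1 - axis[0] ** 2 - axis[1] ** 2))
                    mat = Rotation.from_rotvec(ang * axis).as_matrix()
                    c = cost(mat)
                    if c < best[0]:
                        best = (c, mat)
        assert cost(rot) <= best[0] + 1e-12
        grid_angle = Rotation.from_matrix(best[1]).magnitude()
        fit_angle = Rotation.from_matrix(rot).magnitude()
        assert abs(fit_angle - grid_angle) < np.deg2rad(1.0)

    def test_collinear_rejected(self):
        y = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(DegenerateFrameError, match="collinear"):
            fit_rotation(y, y)

    def test_reflection_optimal_corrected_to_proper(self, rng):
        # near-planar cloud with a flip: best orthogonal map is a reflection,
        # the fit must still return det = +1
        y = rng.normal(size=(10, 3)) * np.array([1.0, 1.0, 1e-3])
        y_next = y * np.array([1.0, 1.0, -1.0])
        rot, _, _ = fit_rotation(y, y_next)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestFitDilatation:
    def test_pure_expansion(self, rng):
        y = rng.normal(size=(5, 3))
        assert fit_dilatation(y, 1.5 * y) == pytest.approx(1.5, rel=1e-12)

    def test_identity(self, rng):
        y = rng.normal(size=(5, 3))
        assert fit_dilatation(y, y) == pytest.approx(1.0, rel=1e-12)

    def test_matches_golden_section_oracle(self, rng):
        y = rng.normal(size=(20, 3))
        y_next = 0.8 * y + rng.normal(scale=0.05, size=y.shape)
        alpha = fit_dilatation(y, y_next)
        oracle = minimize_scalar(
            lambda a: np.sum((y_next - a * y) ** 2),
            bracket=(0.0, 2.0),
            method="golden",
        ).x
        assert alpha == pytest.approx(oracle, abs=1e-6)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateFrameError):
            fit_dilatation(np.zeros((4, 3)), np.ones((4, 3)))


class TestDecompose:
    def test_pure_rigid_motion_leaves_no_residual(self):
        fa, fb, _ = planted_mode_swarm(
            FixtureSpec(n=25, rotation_angle=0.2, dilatation=1.1, noise_sd=0.0, seed=1)
        )
        dec = decompose(fa, fb, 1.0)
        signal = np.linalg.norm(fa.velocities)
        assert np.linalg.norm(dec.residuals) < 1e-9 * signal

    def test_no_collective_modes_keeps_velocity(self, rng):
        # two antiparallel groups, zero net motion, symmetric positions
        pos = rng.normal(size=(10, 3))
        pos = np.vstack([pos, -pos])  # point-symmetric so rotation/dilatation fit ~0
        u = np.array([0.0, 0.0, 0.3])
        vel = np.vstack([np.tile(u, (10, 1)), np.tile(-u, (10, 1))])
        dec = decompose(*_pair_from_velocity(pos, vel), fps=1.0)
        # translation is zero; fitted rotation/dilatation absorb some signal but
        # the fluctuation stays essentially the velocity itself
        assert np.mean(np.sum(dec.phi**2, axis=1)) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.norm(dec.v_cm) < 1e-12

    def test_normalization_invariants(self, rng):
        fa, fb, _ = planted_mode_swarm(
            FixtureSpec(n=40, rotation_angle=0.05, dilatation=0.97, noise_sd=0.05, seed=2)
        )
        dec = decompose(fa, fb, 1.0)
        assert np.abs(dec.residuals.sum(axis=0)).max() < 1e-9 * np.abs(
            dec.residuals
        ).max()
        assert np.mean(np.sum(dec.phi**2, axis=1)) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.det(dec.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            dec.rotation @ dec.rotation.T, np.eye(3), atol=1e-9
        )

    def test_monte_carlo_recovery_unbiased(self):
        """Planted (V, angle, alpha) recovered without bias over 100 seeds."""
        spec = dict(
            n=50,
            v_cm=np.array([0.2, 0.0, 0.0]),
            rotation_angle=0.1,
            dilatation=1.05,
            noise_sd=0.02,  # 10% of the mode speed scale
        )
        est = {"v": [], "angle": [], "alpha": []}
        for seed in range(100):
            fa, fb, truth = planted_mode_swarm(FixtureSpec(seed=seed, **spec))
            dec = decompose(fa, fb, 1.0)
            est["v"].append(dec.v_cm[0])
            est["angle"].append(dec.rotation_angle)
            est["alpha"].append(dec.dilatation)
        for key, planted in (("v", 0.2), ("angle", 0.1), ("alpha", 1.05)):
            vals = np.array(est[key])
            se = vals.std(ddof=1) / 10.0
            assert abs(vals.mean() - planted) < 3 * max(se, 1e-12), key

    def test_residual_objective_nonincreasing_along_subtraction(self, rng):
        fa, fb, _ = planted_mode_swarm(
            FixtureSpec(n=30, rotation_angle=0.15, dilatation=1.08, noise_sd=0.1, seed=7)
        )
        dec = decompose(fa, fb, 1.0)
        sq = lambda a: float(np.sum(a**2))
        assert sq(dec.dv_translation) >= sq(dec.dv_rotation) - 1e-12
        assert sq(dec.dv_rotation) >= sq(dec.residuals) - 1e-12

    def test_equivariance_under_global_rotation(self, rng):
        fa, fb, _ = planted_mode_swarm(
            FixtureSpec(n=25, rotation_angle=0.1, dilatation=1.02, noise_sd=0.05, seed=3)
        )
        g = random_rotation(rng)
        fa_r = SwarmFrame(0, fa.positions @ g.T, fa.ids, fa.velocities @ g.T)
        fb_r = SwarmFrame(1, fb.positions @ g.T, fb.ids)
        d0 = decompose(fa, fb, 1.0)
        d1 = decompose(fa_r, fb_r, 1.0)
        np.testing.assert_allclose(
            np.linalg.norm(d1.residuals, axis=1),
            np.linalg.norm(d0.residuals, axis=1),
            atol=1e-9,
        )
        o0 = order_parameters(fa, fb, 1.0)
        o1 = order_parameters(fa_r, fb_r, 1.0)
        assert o1.polarization == pytest.approx(o0.polarization, abs=1e-9)
        assert o1.rotational == pytest.approx(o0.rotational, abs=1e-9)
        assert o1.dilatational == pytest.approx(o0.dilatational, abs=1e-9)


class TestOrderParameters:
    def test_perfect_alignment(self, rng):
        vel = np.tile([0.1, 0.2, 0.0], (12, 1))
        assert polarization(vel)[0] == pytest.approx(1.0)

    def test_rigid_rotation_gives_full_rotational_order(self):
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(8)])
        rot = Rotation.from_rotvec([0, 0, 0.12]).as_matrix()
        vel = ring @ rot.T - ring
        _, dv = subtract_translation(ring, vel)
        assert rotational_order(ring, dv, np.array([0.0, 0, 1])) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_coherent_expansion_and_contraction(self, rng):
        y = rng.normal(size=(15, 3))
        y -= y.mean(axis=0)
        assert dilatational_order(y, 0.3 * y) == pytest.approx(1.0, abs=1e-12)
        assert dilatational_order(y, -0.3 * y) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_speed_individuals_excluded_with_warning(self):
        vel = np.vstack([np.tile([1.0, 0, 0], (5, 1)), np.zeros((2, 3))])
        with pytest.warns(UserWarning, match="zero-speed"):
            phi, n_exc = polarization(vel)
        assert n_exc == 2
        assert phi == pytest.approx(1.0)

    def test_small_frames_skip_rotational_statistics(self, rng):
        pos = rng.normal(size=(3, 3))
        vel = rng.normal(size=(3, 3))
        op = order_parameters(*_pair_from_velocity(pos, vel), fps=1.0)
        assert np.isfinite(op.polarization)
        assert np.isnan(op.rotational) and np.isnan(op.dilatational)


class TestNullBand:
    def test_polarization_matches_asymptotic_form(self):
        n = 1000
        band = null_band(n, n_samples=400, seed=0)
        mean, sd = band["polarization"]
        expected = np.sqrt(8 / (3 * np.pi * n))
        mc_se = sd / np.sqrt(400)
        assert abs(mean - expected) < 3 * mc_se + 0.02 * expected

    def test_band_positive(self):
        band = null_band(2, n_samples=100, seed=1)
        assert band["polarization"][0] > 0

    def test_doubling_n_halves_squared_polarization(self):
        b1 = null_band(200, n_samples=600, seed=2)
        b2 = null_band(400, n_samples=600, seed=3)
        ratio = b1["polarization"][0] ** 2 / b2["polarization"][0] ** 2
        assert ratio == pytest.approx(2.0, rel=0.2)
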