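"""Connected correlation, first zero, cumulative correlation, susceptibility."""

import numpy as np
import pytest

from conftest import random_rotation
from midgeswarm.correlation import (
    CorrelationCurve,
    connected_correlation,
    correlation_from_pairwise,
    correlation_length,
    susceptibility,
    susceptibility_timeseries,
)
from midgeswarm.fixtures import correlated_swarm, correlated_trajectory
from midgeswarm.io import PairwiseSample, SwarmFrame, SwarmTrajectory, compute_velocities


def brute_force_curve(phi, pos, bin_width):
    """O(N^2) double-loop estimator used as the oracle."""
    n = len(pos)
    sums, counts = {}, {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = np.linalg.norm(pos[i] - pos[j])
            b = int(r / bin_width)
            sums[b] = sums.get(b, 0.0) + phi[i] @ phi[j]
            counts[b] = counts.get(b, 0) + 1
    return sums, counts


def normalized_field(rng, n):
    phi = rng.normal(size=(n, 3))
    phi -= phi.mean(axis=0)
    return phi / np.sqrt(np.mean(np.sum(phi**2, axis=1)))


class TestConnectedCorrelation:
    def test_antiparallel_pair_is_minus_one(self):
        pos = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        phi = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        curve = connected_correlation(phi, pos, bin_width=0.1)
        b = int(0.4 / 0.1)
        assert curve.values[b] == pytest.approx(-1.0)
        assert curve.pair_counts.sum() == 1  # unordered pairs are counted once

    def test_matches_double_loop_oracle(self, rng):
        pos = rng.uniform(size=(200, 3))
        phi = normalized_field(rng, 200)
        bw = 0.07
        curve = connected_correlation(phi, pos, bin_width=bw)
        sums, counts = brute_force_curve(phi, pos, bw)
        for b in range(len(curve.values)):
            if counts.get(b, 0) == 0:
                assert np.isnan(curve.values[b])
                assert curve.pair_counts[b] == 0
            else:
                # unordered pairs: same ratio, half the count
                assert curve.pair_counts[b] * 2 == counts[b]
                assert curve.values[b] == pytest.approx(
                    sums[b] / counts[b], rel=1e-10, abs=1e-12
                )

    def test_two_antiparallel_clusters_sign_structure(self, rng):
        sep = np.array([5.0, 0, 0])
        a = rng.normal(scale=0.2, size=(20, 3))
        b = rng.normal(scale=0.2, size=(20, 3)) + sep
        pos = np.vstack([a, b])
        phi = np.vstack([np.tile([1.0, 0, 0], (20, 1)), np.tile([-1.0, 0, 0], (20, 1))])
        phi = phi - phi.mean(axis=0)
        phi /= np.sqrt(np.mean(np.sum(phi**2, axis=1)))
        curve = connected_correlation(phi, pos, bin_width=0.5)
        ok = curve.pair_counts > 0
        assert curve.values[ok][0] > 0           # intra-cluster
        assert curve.values[ok][-1] < 0          # inter-cluster separation

    def test_empty_bins_marked_absent_not_zero(self):
        pos = np.array([[0.0, 0, 0], [0.0, 0, 1.0], [0.0, 0, 1.1]])
        phi = normalized_field(np.random.default_rng(0), 3)
        curve = connected_correlation(phi, pos, bin_width=0.2)
        assert np.isnan(curve.values[2])  # nothing between 0.4 and 0.6
        assert curve.pair_counts[2] == 0


class TestCorrelationLength:
    def test_hand_interpolated_zero(self):
        curve = CorrelationCurve(
            bin_centers=np.array([1.0, 2.0, 3.0]),
            values=np.array([0.5, 0.1, -0.2]),
            pair_counts=np.array([5, 5, 5]),
            bin_width=1.0,
        )
        assert correlation_length(curve) == pytest.approx(2 + 0.1 / 0.3)

    def test_all_positive_returns_none(self):
        curve = CorrelationCurve(
            np.array([1.0, 2.0]), np.array([0.5, 0.2]), np.array([3, 3]), 1.0
        )
        assert correlation_length(curve) is None

    def test_starting_negative_returns_first_boundary(self):
        curve = CorrelationCurve(
            np.array([0.5, 1.5]), np.array([-0.1, -0.2]), np.array([3, 3]), 1.0
        )
        assert correlation_length(curve) == pytest.approx(0.0)

    def test_empty_bin_between_crossing_is_skipped(self):
        curve = CorrelationCurve(
            np.array([0.5, 1.5, 2.5]),
            np.array([0.3, np.nan, -0.3]),
            np.array([4, 0, 4]),
            1.0,
        )
        # interpolates between the populated straddling bins
        assert correlation_length(curve) == pytest.approx(1.5)


class TestSusceptibility:
    def test_q_beyond_max_distance_is_minus_one(self, rng):
        pos = rng.uniform(size=(30, 3))
        phi = normalized_field(rng, 30)
        res = susceptibility(phi, pos)
        assert res.q_curve[-1] == pytest.approx(-1.0, abs=1e-9)

    def test_antiparallel_pair(self):
        pos = np.array([[0.0, 0, 0], [0.4, 0, 0]])
        phi = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        res = susceptibility(phi, pos, grid=np.array([0.0, 0.2, 0.4, 0.6]))
        np.testing.assert_allclose(res.q_curve, [0.0, 0.0, -1.0, -1.0])
        assert res.chi == pytest.approx(0.0)

    def test_correlated_exceeds_uncorrelated(self):
        wins = 0
        n_rep = 30
        for seed in range(n_rep):
            pos, phi_c, _ = correlated_swarm(n=120, corr_length=0.2, seed=seed)
            res_c = susceptibility(phi_c, pos)
            rng = np.random.default_rng(10_000 + seed)
            phi_u = normalized_field(rng, 120)
            res_u = susceptibility(phi_u, pos)
            wins += res_c.chi > res_u.chi
        assert wins >= int(0.95 * n_rep)

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_argmax_within_one_bin_of_first_zero(self, seed):
        # a smooth long-wavelength fluctuation field gives C(r) a single
        # clean zero crossing, where the cumulative correlation must peak
        from midgeswarm.fixtures import _uniform_ball

        rng = np.random.default_rng(seed)
        pos = _uniform_ball(250, 0.5, rng)
        z = pos[:, 2] - pos[:, 2].mean()
        phi = np.outer(z, [1.0, 0, 0]) + rng.normal(scale=0.05, size=(250, 3))
        phi -= phi.mean(axis=0)
        phi /= np.sqrt(np.mean(np.sum(phi**2, axis=1)))
        bw = 0.02
        curve = connected_correlation(phi, pos, bin_width=bw)
        r0 = correlation_length(curve)
        res = susceptibility(phi, pos, bin_width=bw)
        assert r0 is not None
        assert abs(res.argmax_r - r0) <= bw + 1e-12

    def test_invariance_under_rigid_motion_and_scaling(self, rng):
        pos, phi, _ = correlated_swarm(n=100, corr_length=0.15, seed=5)
        bw = 0.02
        chi0 = susceptibility(phi, pos, bin_width=bw).chi
        r0_0 = correlation_length(connected_correlation(phi, pos, bin_width=bw))
        g = random_rotation(rng)
        moved = pos @ g.T + np.array([3.0, -1.0, 2.0])
        chi1 = susceptibility(phi, moved, bin_width=bw).chi
        r0_1 = correlation_length(connected_correlation(phi, moved, bin_width=bw))
        assert chi1 == pytest.approx(chi0, abs=1e-9)
        assert r0_1 == pytest.approx(r0_0, abs=1e-9)
        r0_2 = correlation_length(
            connected_correlation(phi, 2.0 * pos, bin_width=2 * bw)
        )
        assert r0_2 == pytest.approx(2 * r0_0, rel=1e-9)


class TestSusceptibilityTimeseries:
    def test_congruent_frames_give_constant_series(self, rng):
        # pure rigid translation: every frame pair is congruent, the mode
        # subtraction removes all motion, and chi is identical (zero) per frame
        pos = rng.normal(size=(20, 3))
        drift = np.array([0.05, -0.02, 0.01])
        frames = [SwarmFrame(t, pos + t * drift, np.arange(20)) for t in range(4)]
        traj = compute_velocities(
            SwarmTrajectory(frames, fps=1.0, body_length=0.002)
        )
        res = susceptibility_timeseries(traj)
        assert res.sd == pytest.approx(0.0, abs=1e-12)
        assert len(res.per_frame) == 3
        assert len(set(res.per_frame)) == 1

    def test_correlated_series_beats_uncorrelated_control(self):
        corr = correlated_trajectory(n=90, corr_length=0.2, n_frames=8, seed=11)
        ctrl = correlated_trajectory(n=90, corr_length=0.0, n_frames=8, seed=11)
        chi_corr = susceptibility_timeseries(corr).mean
        chi_ctrl = susceptibility_timeseries(ctrl).mean
        assert chi_corr > 2 * chi_ctrl


class TestCorrelationFromPairwise:
    def test_consistent_with_frame_estimator(self, rng):
        pos, phi, _ = correlated_swarm(n=60, corr_length=0.1, seed=6)
        bw = 0.05
        direct = connected_correlation(phi, pos, bin_width=bw)
        samples = [
            PairwiseSample(
                float(np.linalg.norm(pos[i] - pos[j])), float(phi[i] @ phi[j])
            )
            for i in range(60)
            for j in range(i + 1, 60)
        ]
        from_pairs = correlation_from_pairwise(samples, bin_width=bw)
        np.testing.assert_allclose(
            from_pairs.values, direct.values, rtol=1e-10, equal_nan=True
        )
        np.testing.assert_array_equal(from_pairs.pair_counts, direct.pair_counts)

    def test_single_sample(self):
        curve = correlation_from_pairwise([PairwiseSample(0.35, 0.6)], bin_width=0.1)
        assert curve.values[3] == pytest.approx(0.6)
        assert curve.pair_counts.sum() == 1

    def test_empty_list(self):
        curve = correlation_from_pairwise([], bin_width=0.1)
        assert len(curve.values) == 0
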