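"""RTS smoother, process covariance, and head/tail disambiguation."""

import itertools

import numpy as np
import pytest

from flightmaneuvers.kinematics import spline_derivatives
from flightmaneuvers.smoothing import (
    SmootherConfig,
    build_process_covariance,
    canonicalize_signs,
    chain_score,
    resolve_head_tail,
    rts_smooth,
    tip_velocity_up,
)
from flightmaneuvers.synthetic import gen_free_fall


class TestProcessCovariance:
    def test_published_constants(self):
        q = build_process_covariance(0.01, 0.005)
        assert q[0, 0] == pytest.approx(0.01 * 0.005**3 / 3.0)  # ~4.1667e-10
        assert q[0, 3] == pytest.approx(0.01 * 0.005**2 / 2.0)
        assert q[3, 3] == pytest.approx(0.01 * 0.005)
        assert np.allclose(q, q.T)

    def test_zero_intensity_gives_zero_matrix(self):
        assert np.all(build_process_covariance(0.0, 0.1) == 0.0)

    def test_velocity_block_scales_linearly_with_time(self):
        q = build_process_covariance(3.0, 1.0)
        assert q[3, 3] == pytest.approx(3.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_process_covariance(0.01, 0.0)
        with pytest.raises(ValueError):
            build_process_covariance(-1.0, 0.005)


class TestRtsSmoother:
    def test_matches_batch_map_solution(self):
        """The forward/backward recursion must equal the direct MAP
        (banded least-squares) solution of the same state-space model."""
        rng = np.random.default_rng(0)
        n, T = 50, 0.005
        t = np.arange(n) * T
        pos = np.column_stack([0.2 * t, -0.1 * t, 1.0 - 4.905 * t**2])
        obs = pos + rng.normal(0, 0.012, pos.shape)
        cfg = SmootherConfig()
        sm = rts_smooth(obs, cfg)

        F = np.eye(6)
        F[0, 3] = F[1, 4] = F[2, 5] = T
        Qi = np.linalg.inv(build_process_covariance(cfg.sigma2, T))
        Ri = np.eye(3) / cfg.r_pos
        H = np.zeros((3, 6))
        H[:, :3] = np.eye(3)
        P0i = np.eye(6) / cfg.initial_variance
        A = np.zeros((6 * n, 6 * n))
        b = np.zeros(6 * n)
        x0 = np.zeros(6)
        x0[:3] = obs[0]
        A[:6, :6] += P0i
        b[:6] += P0i @ x0
        for k in range(n):
            sl = slice(6 * k, 6 * k + 6)
            A[sl, sl] += H.T @ Ri @ H
            b[sl] += H.T @ Ri @ obs[k]
        for k in range(n - 1):
            i = slice(6 * k, 6 * k + 6)
            j = slice(6 * k + 6, 6 * k + 12)
            A[i, i] += F.T @ Qi @ F
            A[i, j] += -F.T @ Qi
            A[j, i] += -Qi @ F
            A[j, j] += Qi
        x = np.linalg.solve(A, b).reshape(n, 6)
        assert np.allclose(x[:, :3], sm.position, atol=1e-8)
        assert np.allclose(x[:, 3:], sm.velocity, atol=1e-8)

    def test_noise_free_constant_velocity_is_preserved(self):
        # seeding the filter with zero velocity leaves a ~1e-4 transient
        # at the start of the track that decays within about a second;
        # past it the track is reproduced to sub-micron accuracy
        t = np.arange(0, 2.0, 0.005)
        pos = np.column_stack([1.5 * t, -0.5 * t, 0.2 * t + 1.0])
        sm = rts_smooth(pos, SmootherConfig())
        dev = np.abs(sm.position - pos)
        assert np.max(dev) < 2e-4
        assert np.max(dev[250:]) < 1e-6

    def test_smoothing_smoothed_data_is_near_identity(self):
        """Data already consistent with the constant-velocity model pass
        through the smoother essentially unchanged on a second pass;
        only the decaying zero-velocity seeding transient differs."""
        t = np.arange(0, 2.0, 0.005)
        pos = np.column_stack([1.5 * t, -0.2 * t, 0.1 * t + 1.0])
        once = rts_smooth(pos, SmootherConfig()).position
        twice = rts_smooth(once, SmootherConfig()).position
        change = np.abs(twice - once)
        assert np.max(change) < 1e-4
        assert np.max(change[300:]) < 1e-8

    def test_spike_attenuated(self):
        pos = np.zeros((200, 3))
        pos[:, 2] = 1.0
        pos[100, 0] = 0.05
        sm = rts_smooth(pos, SmootherConfig())
        assert np.max(np.abs(sm.position[:, 0])) < 0.05

    def test_heavier_smoothing_lowers_peak_acceleration(self):
        """Scaling R_pos up by 10 must attenuate peak accelerations on
        the falling-object fixture (the published sensitivity sweep)."""
        traces = gen_free_fall(n_traces=3, seed=3)
        peaks = {}
        for scale in (1.0, 10.0):
            cfg = SmootherConfig(r_pos=0.000144 * scale)
            vals = []
            for tr in traces:
                sm = rts_smooth(tr.position, cfg)
                _, acc = spline_derivatives(sm.position, tr.time)
                vals.append(np.max(np.abs(acc[:, 2])))
            peaks[scale] = np.mean(vals)
        assert peaks[10.0] < peaks[1.0]

    def test_orientation_output_unit_norm(self):
        rng = np.random.default_rng(2)
        t = np.arange(0, 0.5, 0.005)
        ang = np.linspace(0, np.pi / 3, len(t))
        ori = np.column_stack([np.cos(ang), np.zeros_like(ang), np.sin(ang)])
        obs = ori + rng.normal(0, 0.0012, ori.shape)
        sm = rts_smooth(obs, SmootherConfig(), which="orientation")
        assert np.allclose(np.linalg.norm(sm.orientation, axis=1), 1.0, atol=1e-9)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            rts_smooth(np.zeros((1, 3)), SmootherConfig())


class TestTipVelocityUp:
    def test_horizontal_vector_tips_up(self):
        out = tip_velocity_up(np.array([1.0, 0.0, 0.0]), 15.0)
        assert out == pytest.approx([np.cos(np.radians(15)), 0.0, np.sin(np.radians(15))])

    def test_vertical_vector_unchanged(self):
        assert tip_velocity_up(np.array([0.0, 0.0, 1.0]), 15.0) == pytest.approx([0, 0, 1])

    def test_magnitude_preserved_with_large_angle(self):
        out = tip_velocity_up(np.array([0.0, 2.0, 0.0]), 89.0)
        assert np.linalg.norm(out) == pytest.approx(2.0)
        assert out[2] == pytest.approx(2.0 * np.sin(np.radians(89.0)))

    def test_zero_vector_unchanged(self):
        assert np.all(tip_velocity_up(np.zeros(3), 15.0) == 0.0)


def _random_instance(rng, n):
    ori = rng.normal(size=(n, 3))
    ori /= np.linalg.norm(ori, axis=1)[:, None]
    speeds = rng.uniform(0, 3, size=n)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    return ori, dirs * speeds[:, None]


def _brute_force_signs(ori, vel, **kw):
    best, best_score = None, -np.inf
    for signs in itertools.product((1.0, -1.0), repeat=len(ori)):
        s = chain_score(np.array(signs), ori, vel, **kw)
        if s > best_score:
            best, best_score = np.array(signs), s
    return best, best_score


class TestHeadTailResolution:
    def test_dp_equals_brute_force_on_random_chains(self):
        """Exact agreement of the two-state DP with exhaustive
        enumeration of all sign assignments (chains of up to 15)."""
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(1, 16))
            cap = bool(trial % 2)
            ori, vel = _random_instance(rng, n)
            resolved = resolve_head_tail(ori, vel, cap_speed_weight=cap)
            signs = np.sign(np.einsum("ij,ij->i", resolved, ori))
            _, best_score = _brute_force_signs(ori, vel, cap_speed_weight=cap)
            assert chain_score(signs, ori, vel, cap_speed_weight=cap) == pytest.approx(
                best_score, abs=1e-10
            )

    def test_forward_flight_resolves_to_travel_direction(self):
        """Cruising forward with randomly sign-flipped axis estimates,
        every frame resolves to the travel direction."""
        rng = np.random.default_rng(7)
        n = 60
        flips = rng.choice([-1.0, 1.0], size=n)
        ori = np.column_stack([flips, np.zeros(n), np.zeros(n)])
        for speed in (1.5, 2.5):
            vel = np.tile([speed, 0.0, 0.0], (n, 1))
            assert np.all(resolve_head_tail(ori, vel)[:, 0] > 0)

    def test_literal_weighting_degenerates_at_high_speed(self):
        """With the unclamped weighting the continuity weight goes
        negative above 1 m/s and the optimal chain alternates signs —
        the reason the clamp is the default."""
        n = 40
        ori = np.tile([np.cos(np.radians(45)), 0.0, np.sin(np.radians(45))], (n, 1))
        vel = np.tile([2.2, 0.0, 0.0], (n, 1))
        resolved = resolve_head_tail(ori, vel, cap_speed_weight=False)
        dots = np.einsum("ij,ij->i", resolved[1:], resolved[:-1])
        assert np.all(dots < 0)  # alternates every frame
        resolved = resolve_head_tail(ori, vel)  # clamped default
        assert np.all(resolved[:, 2] > 0)

    def test_hover_resolves_upward(self):
        """At low speed the up-vector term dominates: alternating-sign
        near-vertical axes all resolve to point up."""
        n = 40
        vel = np.tile([0.3, 0.0, 0.0], (n, 1))
        signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        ori = np.column_stack([0.1 * np.ones(n), np.zeros(n), 0.995 * signs])
        ori /= np.linalg.norm(ori, axis=1)[:, None]
        resolved = resolve_head_tail(ori, vel)
        assert np.all(resolved[:, 2] > 0)

    def test_single_frame_follows_velocity(self):
        resolved = resolve_head_tail(
            np.array([[1.0, 0.0, 0.0]]), np.array([[-2.0, 0.0, 0.0]])
        )
        assert resolved[0, 0] == pytest.approx(-1.0)

    def test_greedy_not_better_than_dp(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ori, vel = _random_instance(rng, 12)
            s_dp = np.sign(np.einsum("ij,ij->i", resolve_head_tail(ori, vel), ori))
            s_gr = np.sign(
                np.einsum("ij,ij->i", resolve_head_tail(ori, vel, method="greedy"), ori)
            )
            assert chain_score(s_dp, ori, vel) >= chain_score(s_gr, ori, vel) - 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            resolve_head_tail(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_canonicalize_makes_consecutive_hemispheres_agree(self):
        rng = np.random.default_rng(5)
        ang = np.linspace(0, np.pi, 50)
        ori = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
        ori *= rng.choice([-1.0, 1.0], size=50)[:, None]
        fixed = canonicalize_signs(ori)
        dots = np.einsum("ij,ij->i", fixed[1:], fixed[:-1])
        assert np.all(dots >= 0)
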