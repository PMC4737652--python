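"""Trajectory smoothing and body-axis disambiguation.

Tracked body positions and orientation vectors are smoothed with a
forward/backward (Rauch-Tung-Striebel) Kalman smoother under a discrete
constant-velocity motion model.  The process covariance is the standard
continuous-white-noise-acceleration matrix with intensity ``sigma2``;
the default observation covariances correspond to ~12 mm position noise
per axis and a much tighter orientation noise.

Because the tracker estimates the body axis from an image eigensystem,
the raw orientation vector is sign-ambiguous: it points either at the
head or at the tail.  :func:`resolve_head_tail` selects a sign per frame
by maximizing, over the whole chain, an alignment score that rewards
pointing along the (slightly tipped-up) travel direction, pointing
upward, and temporal continuity.  The chain optimum is found exactly by
a two-state dynamic program (Viterbi recursion over the sign coupling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SmootherConfig",
    "SmoothedState",
    "build_process_covariance",
    "rts_smooth",
    "tip_velocity_up",
    "resolve_head_tail",
    "chain_score",
]

UP = np.array([0.0, 0.0, 1.0])


@dataclass
class SmootherConfig:
    """Parameters of the position/orientation RTS smoother.

    sigma2
        Process-noise intensity of the constant-velocity model
        (m^2 s^-3 for position).  Default 0.01.
    frame_interval
        Time step T between frames in seconds (0.005 s at 200 Hz).
    r_pos
        Per-axis observation variance for position, m^2.  The default
        0.000144 corresponds to 12 mm RMS tracking noise.
    r_ori
        Per-axis observation variance for the orientation unit vector.
    initial_variance
        Diagonal of the initial state covariance.  The filter is seeded
        with the first observation and zero velocity, so this is kept
        large (1.0) to let the data dominate immediately.
    """

    sigma2: float = 0.01
    frame_interval: float = 0.005
    r_pos: float = 0.000144
    r_ori: float = 1.44e-6
    initial_variance: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.r_pos <= 0 or self.r_ori <= 0:
            raise ValueError("observation variances must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


@dataclass
class SmoothedState:
    """Smoothed per-frame state estimates.

    ``estimate`` holds smoothed positions (m) or renormalized
    orientation unit vectors; ``derivative`` holds the corresponding
    smoothed rates (m/s, or 1/s for the raw orientation components).
    """

    estimate: np.ndarray
    derivative: np.ndarray
    kind: str = "position"

    @property
    def position(self) -> np.ndarray:
        return self.estimate

    @property
    def velocity(self) -> np.ndarray:
        return self.derivative

    @property
    def orientation(self) -> np.ndarray:
        return self.estimate


def build_process_covariance(sigma2: float, frame_interval: float) -> np.ndarray:
    """6x6 process covariance for the state [x, y, z, vx, vy, vz].

    Each axis contributes the 2x2 block
    ``sigma2 * [[T^3/3, T^2/2], [T^2/2, T]]`` coupling that coordinate
    with its own velocity.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    T = frame_interval
    q = np.zeros((6, 6))
    for i in range(3):
        q[i, i] = sigma2 * T**3 / 3.0
        q[i, i + 3] = q[i + 3, i] = sigma2 * T**2 / 2.0
        q[i + 3, i + 3] = sigma2 * T
    return q


def _transition_matrix(frame_interval: float) -> np.ndarray:
    f = np.eye(6)
    f[0, 3] = f[1, 4] = f[2, 5] = frame_interval
    return f


def rts_smooth(
    observations: np.ndarray,
    config: SmootherConfig | None = None,
    which: str = "position",
) -> SmoothedState:
    """Smooth a 3-vector observation sequence with the RTS smoother.

    Runs a forward Kalman filter under the constant-velocity model and
    then the backward Rauch-Tung-Striebel recursion, yielding non-causal
    state estimates.  ``which`` selects the observation variance
    (``"position"`` -> ``r_pos``, ``"orientation"`` -> ``r_ori``); for
    orientation the smoothed vectors are renormalized to unit length.
    The smoother is sign-agnostic and is applied before head/tail
    resolution.
    """
    if config is None:
        config = SmootherConfig()
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observations must have shape (n, 3)")
    n = obs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames to smooth")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations contain non-finite values")
    if which == "position":
        r = config.r_pos
    elif which == "orientation":
        r = config.r_ori
    else:
        raise ValueError(f"unknown observation kind {which!r}")

    F = _transition_matrix(config.frame_interval)
    Q = build_process_covariance(config.sigma2, config.frame_interval)
    R = r * np.eye(3)
    H = np.zeros((3, 6))
    H[:, :3] = np.eye(3)
    I6 = np.eye(6)

    x_filt = np.empty((n, 6))
    p_filt = np.empty((n, 6, 6))
    x_pred = np.empty((n, 6))
    p_pred = np.empty((n, 6, 6))

    x = np.zeros(6)
    x[:3] = obs[0]
    p = config.initial_variance * I6
    x_pred[0], p_pred[0] = x, p
    for k in range(n):
        if k > 0:
            x = F @ x
            p = F @ p @ F.T + Q
            x_pred[k], p_pred[k] = x, p
        s = H @ p @ H.T + R
        gain = p @ H.T @ np.linalg.inv(s)
        x = x + gain @ (obs[k] - H @ x)
        p = (I6 - gain @ H) @ p
        x_filt[k], p_filt[k] = x, p

    x_smooth = np.empty_like(x_filt)
    x_smooth[-1] = x_filt[-1]
    p_smooth = p_filt[-1]
    for k in range(n - 2, -1, -1):
        c = p_filt[k] @ F.T @ np.linalg.inv(p_pred[k + 1])
        x_smooth[k] = x_filt[k] + c @ (x_smooth[k + 1] - x_pred[k + 1])
        p_smooth = p_filt[k] + c @ (p_smooth - p_pred[k + 1]) @ c.T

    estimate = x_smooth[:, :3]
    derivative = x_smooth[:, 3:]
    if which == "orientation":
        norms = np.linalg.norm(estimate, axis=1)
        if np.any(norms <= 0):
            raise ValueError("smoothed orientation collapsed to zero norm")
        estimate = estimate / norms[:, None]
    return SmoothedState(estimate=estimate, derivative=derivative, kind=which)


def tip_velocity_up(velocity: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a velocity vector up toward +z within its vertical plane.

    The magnitude is preserved and the rotation happens in the vertical
    plane containing the input vector.  The elevation is clamped at 90
    degrees so the horizontal direction is never reversed.  Zero and
    exactly vertical vectors are returned unchanged (the rotation plane
    is undefined).
    """
    if not 0.0 <= angle_deg < 90.0:
        raise ValueError("angle_deg must lie in [0, 90)")
    v = np.asarray(velocity, dtype=float)
    mag = float(np.linalg.norm(v))
    horiz = float(np.hypot(v[0], v[1]))
    if mag == 0.0 or horiz == 0.0:
        return v.copy()
    elev = np.arctan2(v[2], horiz)
    elev = min(elev + np.radians(angle_deg), np.pi / 2)
    h_unit = np.array([v[0] / horiz, v[1] / horiz, 0.0])
    return mag * (np.cos(elev) * h_unit + np.sin(elev) * UP)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _speed_weight(speed: float, floor: float, cap: bool) -> float:
    w = speed if speed > floor else 0.5
    if cap:
        w = min(w, 1.0)
    return w


def _frame_terms(
    orientations: np.ndarray,
    velocities: np.ndarray,
    tip_angle_deg: float,
    speed_floor: float,
    cap_speed_weight: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame score pieces.

    Returns ``unary[n]`` (score of sign +1 from the travel and up terms;
    sign -1 scores ``-unary``) and ``coupling[n]`` (score of keeping the
    same sign as frame n-1; flipping scores ``-coupling``).
    """
    n = len(orientations)
    unary = np.zeros(n)
    coupling = np.zeros(n)
    for k in range(n):
        speed = float(np.linalg.norm(velocities[k]))
        w = _speed_weight(speed, speed_floor, cap_speed_weight)
        vel_mod = tip_velocity_up(velocities[k], tip_angle_deg)
        unary[k] = w * _cosine(orientations[k], vel_mod) + (1.0 - w) * _cosine(
            orientations[k], UP
        )
        if k > 0:
            coupling[k] = (1.0 - w) * _cosine(orientations[k], orientations[k - 1])
    return unary, coupling


def chain_score(
    signs: np.ndarray,
    orientations: np.ndarray,
    velocities: np.ndarray,
    tip_angle_deg: float = 15.0,
    speed_floor: float = 0.5,
    cap_speed_weight: bool = True,
) -> float:
    """Total alignment score of a head/tail sign assignment.

    Each frame contributes the speed-weighted cosine with the tipped-up
    velocity, the cosine with vertical, and (from frame 1 on) the cosine
    with the previous signed orientation.  The first frame has no
    predecessor, so its continuity term is dropped.  Weight conventions
    (including the default clamp of the speed weight) match
    :func:`resolve_head_tail`.
    """
    signs = np.asarray(signs, dtype=float)
    unary, coupling = _frame_terms(
        np.asarray(orientations, dtype=float),
        np.asarray(velocities, dtype=float),
        tip_angle_deg,
        speed_floor,
        cap_speed_weight,
    )
    total = float(np.sum(signs * unary))
    total += float(np.sum(signs[1:] * signs[:-1] * coupling[1:]))
    return total


def resolve_head_tail(
    orientations: np.ndarray,
    velocities: np.ndarray,
    tip_angle_deg: float = 15.0,
    speed_floor: float = 0.5,
    cap_speed_weight: bool = True,
    method: str = "dp",
) -> np.ndarray:
    """Resolve which end of each body-axis vector is the head.

    Chooses a sign s_n in {+1, -1} per frame so that the cumulative
    score of :func:`chain_score` is maximized.  The frame weight is the
    speed in m/s when above ``speed_floor`` (0.5 m/s) and 0.5 otherwise;
    faster flight therefore trusts the travel direction more, while
    hovering leans on posture and continuity.  ``method="dp"`` solves
    the sign chain exactly by a two-state Viterbi recursion;
    ``method="greedy"`` is a cheaper left-to-right pass.

    By default the speed weight is clamped into [0, 1]
    (``cap_speed_weight=True``).  Taken literally, the weighting lets
    Speed exceed 1 above 1 m/s, which makes the (1 - Speed) posture and
    continuity weights negative — and a negative continuity weight
    *rewards* flipping the axis on every frame of fast upright flight,
    for any resolver honoring the score.  The clamp removes that
    degeneracy while leaving behavior below 1 m/s untouched; pass
    ``cap_speed_weight=False`` for the literal weighting.

    Returns the signed orientation sequence (same shape as input).
    """
    ori = np.asarray(orientations, dtype=float)
    vel = np.asarray(velocities, dtype=float)
    if ori.shape != vel.shape or ori.ndim != 2 or ori.shape[1] != 3:
        raise ValueError("orientations and velocities must both have shape (n, 3)")
    n = ori.shape[0]
    if n == 0:
        return ori.copy()
    unary, coupling = _frame_terms(ori, vel, tip_angle_deg, speed_floor, cap_speed_weight)

    signs = np.ones(n)
    if method == "dp":
        # score[j]: best cumulative score ending at the current frame
        # with sign (+1, -1)[j]; ties prefer +1.
        score = np.array([unary[0], -unary[0]])
        back = np.zeros((n, 2), dtype=int)
        for k in range(1, n):
            for j, s in enumerate((1.0, -1.0)):
                cand = score + np.array([s * 1.0, s * -1.0]) * coupling[k]
                best = 0 if cand[0] >= cand[1] else 1
                back[k, j] = best
                new = cand[best] + s * unary[k]
                if j == 0:
                    plus = new
                else:
                    minus = new
            score = np.array([plus, minus])
        j = 0 if score[0] >= score[1] else 1
        for k in range(n - 1, -1, -1):
            signs[k] = 1.0 if j == 0 else -1.0
            j = back[k, j]
    elif method == "greedy":
        signs[0] = 1.0 if unary[0] >= 0 else -1.0
        for k in range(1, n):
            gain = unary[k] + signs[k - 1] * coupling[k]
            signs[k] = 1.0 if gain >= 0 else -1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return ori * signs[:, None]


def canonicalize_signs(orientations: np.ndarray) -> np.ndarray:
    """Flip raw axis vectors so consecutive frames share a hemisphere.

    The image-based axis estimate carries an arbitrary sign per frame.
    Before smoothing, each vector is flipped (if needed) to have a
    non-negative dot product with its predecessor.  This is pure
    continuity bookkeeping: the global head-versus-tail choice is still
    open and is made later by :func:`resolve_head_tail`.
    """
    ori = np.asarray(orientations, dtype=float).copy()
    for k in range(1, len(ori)):
        if np.dot(ori[k], ori[k - 1]) < 0:
            ori[k] = -ori[k]
    return ori
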