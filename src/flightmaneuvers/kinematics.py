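"""Per-frame translational and angular kinematics.

Velocities and accelerations come from the first and second derivatives
of an interpolating cubic spline fit to the (already smoothed) body
positions.  The body-axis vector is expressed as azimuth and pitch in a
global frame (pitch is measured from the horizontal plane; body roll is
not observable from an axis vector).  Heading is the direction of the
horizontal translation velocity and is undefined when the horizontal
speed drops below a small floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splrep

__all__ = [
    "KinematicSeries",
    "spline_derivatives",
    "orientation_angles",
    "heading_series",
    "segment_lengths",
    "find_extrema",
    "zero_crossings",
    "compute_kinematics",
]

#: horizontal speed (m/s) below which heading is treated as undefined
HEADING_SPEED_FLOOR = 0.01


def spline_derivatives(
    values: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives of a cubic interpolating spline.

    ``values`` may be a scalar series (n,) or a vector series (n, d);
    each component is fit with an interpolating spline (zero smoothing)
    and differentiated analytically at the sample times.  Requires at
    least 4 frames.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.shape[0] != t.shape[0]:
        raise ValueError("values and times must have equal length")
    if v.shape[0] < 4:
        raise ValueError("need at least 4 frames for cubic spline derivatives")
    scalar = v.ndim == 1
    cols = v[:, None] if scalar else v
    d1 = np.empty_like(cols, dtype=float)
    d2 = np.empty_like(cols, dtype=float)
    for j in range(cols.shape[1]):
        tck = splrep(t, cols[:, j], k=3, s=0)
        d1[:, j] = splev(t, tck, der=1)
        d2[:, j] = splev(t, tck, der=2)
    if scalar:
        return d1[:, 0], d2[:, 0]
    return d1, d2


def orientation_angles(
    orientations: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Azimuth/pitch (deg) of the body axis plus angular velocities (deg/s).

    Azimuth is atan2(o_y, o_x), unwrapped before differentiation so
    continued rotation accumulates instead of jumping at +-180 deg.
    Pitch is asin(o_z) in [-90, 90].  Velocities are spline derivatives
    of the angle series.  Expects sign-resolved orientation vectors.
    """
    ori = np.asarray(orientations, dtype=float)
    norms = np.linalg.norm(ori, axis=1)
    if np.any(norms <= 1e-12):
        raise ValueError("orientation contains a zero-norm vector")
    unit = ori / norms[:, None]
    azimuth = np.degrees(np.unwrap(np.arctan2(unit[:, 1], unit[:, 0])))
    pitch = np.degrees(np.arcsin(np.clip(unit[:, 2], -1.0, 1.0)))
    azimuth_vel, _ = spline_derivatives(azimuth, times)
    pitch_vel, _ = spline_derivatives(pitch, times)
    return azimuth, pitch, azimuth_vel, pitch_vel


def heading_series(
    velocities: np.ndarray,
    times: np.ndarray,
    speed_floor: float = HEADING_SPEED_FLOOR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heading (deg, unwrapped), heading velocity (deg/s), defined mask.

    Heading is atan2(v_y, v_x).  Frames whose horizontal speed is below
    ``speed_floor`` are flagged undefined (NaN) and excluded from the
    unwrapping chain and from the derivative spline; the unwrap offset
    is carried across such gaps.
    """
    vel = np.asarray(velocities, dtype=float)
    t = np.asarray(times, dtype=float)
    speed_xy = np.hypot(vel[:, 0], vel[:, 1])
    defined = speed_xy >= speed_floor
    n = len(t)
    heading = np.full(n, np.nan)
    heading_vel = np.full(n, np.nan)
    idx = np.flatnonzero(defined)
    if idx.size:
        raw = np.arctan2(vel[idx, 1], vel[idx, 0])
        heading[idx] = np.degrees(np.unwrap(raw))
    if idx.size >= 4:
        dv, _ = spline_derivatives(heading[idx], t[idx])
        heading_vel[idx] = dv
    return heading, heading_vel, defined


def _cumulative_paths(position: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.diff(position, axis=0)
    step_xyz = np.linalg.norm(d, axis=1)
    step_xy = np.hypot(d[:, 0], d[:, 1])
    step_z = np.abs(d[:, 2])
    zero = np.zeros(1)
    return (
        np.concatenate([zero, np.cumsum(step_xyz)]),
        np.concatenate([zero, np.cumsum(step_xy)]),
        np.concatenate([zero, np.cumsum(step_z)]),
    )


@dataclass
class KinematicSeries:
    """Frame-aligned kinematic quantities derived from one trajectory."""

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    speed_xyz: np.ndarray
    speed_xy: np.ndarray
    v_z: np.ndarray
    #: spline derivative of horizontal speed: tangential acceleration, m/s^2
    accel_xy_tangential: np.ndarray
    #: spline derivative of vertical velocity, m/s^2
    accel_z: np.ndarray
    azimuth: np.ndarray
    pitch: np.ndarray
    azimuth_velocity: np.ndarray
    pitch_velocity: np.ndarray
    heading: np.ndarray
    heading_velocity: np.ndarray
    heading_defined: np.ndarray
    cum_path_xyz: np.ndarray
    cum_path_xy: np.ndarray
    cum_path_z: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0])


def compute_kinematics(
    position: np.ndarray,
    orientation: np.ndarray,
    times: np.ndarray,
    heading_floor: float = HEADING_SPEED_FLOOR,
) -> KinematicSeries:
    """Derive the full :class:`KinematicSeries` from smoothed states.

    ``orientation`` must already be sign-resolved.  Angular series are in
    degrees; path lengths in metres.
    """
    pos = np.asarray(position, dtype=float)
    t = np.asarray(times, dtype=float)
    velocity, acceleration = spline_derivatives(pos, t)
    speed_xyz = np.linalg.norm(velocity, axis=1)
    speed_xy = np.hypot(velocity[:, 0], velocity[:, 1])
    v_z = velocity[:, 2]
    accel_xy_t, _ = spline_derivatives(speed_xy, t)
    accel_z, _ = spline_derivatives(v_z, t)
    azimuth, pitch, azimuth_vel, pitch_vel = orientation_angles(orientation, t)
    heading, heading_vel, defined = heading_series(velocity, t, heading_floor)
    cxyz, cxy, cz = _cumulative_paths(pos)
    return KinematicSeries(
        time=t,
        position=pos,
        velocity=velocity,
        acceleration=acceleration,
        speed_xyz=speed_xyz,
        speed_xy=speed_xy,
        v_z=v_z,
        accel_xy_tangential=accel_xy_t,
        accel_z=accel_z,
        azimuth=azimuth,
        pitch=pitch,
        azimuth_velocity=azimuth_vel,
        pitch_velocity=pitch_vel,
        heading=heading,
        heading_velocity=heading_vel,
        heading_defined=defined,
        cum_path_xyz=cxyz,
        cum_path_xy=cxy,
        cum_path_z=cz,
    )


def segment_lengths(
    kin: KinematicSeries, start: int, end: int
) -> tuple[float, float, float]:
    """Path lengths (xyz, xy, |z|) accumulated over frames [start, end].

    Distances are cumulative path lengths, not net displacements: the
    vertical component is the sum of |dz| over the segment.
    """
    n = kin.n_frames
    if not (0 <= start < end <= n - 1):
        raise IndexError(f"segment [{start}, {end}] outside series of {n} frames")
    return (
        float(kin.cum_path_xyz[end] - kin.cum_path_xyz[start]),
        float(kin.cum_path_xy[end] - kin.cum_path_xy[start]),
        float(kin.cum_path_z[end] - kin.cum_path_z[start]),
    )


def _plateau_midpoint(series: np.ndarray, idx: int, tol: float) -> int:
    """Midpoint of the run of near-equal values containing ``idx``."""
    lo = idx
    while lo > 0 and abs(series[lo - 1] - series[idx]) <= tol:
        lo -= 1
    hi = idx
    n = len(series)
    while hi < n - 1 and abs(series[hi + 1] - series[idx]) <= tol:
        hi += 1
    return (lo + hi) // 2


def alternating_extrema(
    series: np.ndarray, min_swing: float = 0.0, plateau_tol: float = 1e-9
) -> list[tuple[int, str]]:
    """Alternating significant local extrema of a scalar series.

    Walks the series with hysteresis ``min_swing``: an extremum is
    confirmed once the series has moved away from it by more than
    ``min_swing``, which suppresses noise-induced micro-extrema.
    Plateaus report their midpoint.  The segment endpoints are included
    as boundary extrema so maneuvers truncated by the trajectory ends
    remain bounded.  Returns ordered ``(frame, "min"|"max")`` pairs.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if n == 1 or np.all(np.abs(x - x[0]) <= plateau_tol):
        return []
    out: list[tuple[int, str]] = []
    i_min = i_max = 0
    direction = 0  # +1 rising since last extremum, -1 falling, 0 unknown
    for k in range(1, n):
        if x[k] > x[i_max]:
            i_max = k
        if x[k] < x[i_min]:
            i_min = k
        if direction >= 0 and x[i_max] - x[k] > min_swing:
            out.append((_plateau_midpoint(x, i_max, plateau_tol), "max"))
            direction = -1
            i_min = k
        elif direction <= 0 and x[k] - x[i_min] > min_swing:
            out.append((_plateau_midpoint(x, i_min, plateau_tol), "min"))
            direction = 1
            i_max = k
    # trailing boundary extremum
    if direction == 1:
        out.append((_plateau_midpoint(x, i_max, plateau_tol), "max"))
    elif direction == -1:
        out.append((_plateau_midpoint(x, i_min, plateau_tol), "min"))
    else:
        # no confirmed swing: a monotone drift beyond min_swing still
        # yields its endpoints as boundary extrema; anything flatter is
        # treated as constant
        if np.max(x) - np.min(x) > min_swing:
            kind0, kind1 = ("min", "max") if x[-1] >= x[0] else ("max", "min")
            out = [(0, kind0), (n - 1, kind1)]
    return out


def zero_crossings(series: np.ndarray, dead_band: float = 0.0) -> np.ndarray:
    """Frames just after each sign change of ``series``.

    Values within ``dead_band`` of zero count as zero; a crossing is
    recorded at the first frame whose (banded) sign differs from the
    last non-zero sign seen.
    """
    x = np.asarray(series, dtype=float)
    sign = np.where(np.abs(x) <= dead_band, 0, np.sign(x))
    out = []
    last = 0
    for k, s in enumerate(sign):
        if s != 0:
            if last != 0 and s != last:
                out.append(k)
            last = s
    return np.asarray(out, dtype=int)


def find_extrema(
    series: np.ndarray,
    kind: str,
    min_swing: float = 0.0,
    dead_band: float = 0.0,
) -> np.ndarray:
    """Ordered frame indices of local minima, maxima or zero crossings.

    ``kind`` is one of ``"min"``, ``"max"``, ``"zero-crossing"``.
    Extrema come from :func:`alternating_extrema` (plateau midpoints,
    boundary endpoints included); zero crossings return the first frame
    after each sign change, with an optional dead band.
    """
    if kind == "zero-crossing":
        return zero_crossings(series, dead_band)
    if kind not in ("min", "max"):
        raise ValueError(f"unknown extremum kind {kind!r}")
    ext = alternating_extrema(series, min_swing=min_swing)
    return np.asarray([i for i, k in ext if k == kind], dtype=int)
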