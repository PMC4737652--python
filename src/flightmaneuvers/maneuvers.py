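"""Detection of the ten stereotyped maneuvers and their metrics.

Five translational maneuvers are bounded by minima/maxima of a speed
series (total, horizontal, or vertical), three rotational maneuvers by
zero crossings of an angular velocity, and the two complex turns
(arcing and pitch-roll) additionally clip a 25 cm window around the
sharpest point for scale-free comparison.  All thresholds live in
:class:`DetectionParams` and default to the assay's printed values
(25 cm of travel, 10 cm cross-axis limit, 45/90 deg rotation minima,
75 deg pitch boundary, 90 deg/s heading-velocity entry, 0.5 m/s arc
speed floor).

Notes on conventions
--------------------
* "Distance" thresholds are cumulative path lengths, not net
  displacements; the vertical distance is the path length of the z
  component.
* Horizontal acceleration metrics use the derivative of horizontal
  speed (tangential acceleration), which excludes the centripetal
  component; set ``tangential_horizontal_accel=False`` for the
  magnitude-of-acceleration alternative.
* All translational acceleration metrics are reported positive.
* Speed extrema are found with a small hysteresis (``speed_swing``) and
  angular-velocity zero crossings with a dead band, so that residual
  noise after smoothing does not spawn micro-maneuvers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import CLASS_METRICS, MANEUVER_CLASSES, Maneuver
from .kinematics import KinematicSeries, alternating_extrema, _plateau_midpoint

__all__ = [
    "DetectionParams",
    "METRIC_NAMES",
    "detect_maneuvers",
    "clip_by_arclength",
    "prt_percent",
    "recheck_maneuver",
]

#: the fourteen performance metrics (incl. the trial-level PRT_pct)
METRIC_NAMES = (
    "Vel_max",
    "AccHor_max",
    "DecHor_max",
    "AccVU_max",
    "AccVD_max",
    "PitchU_vel_avg",
    "PitchD_vel_avg",
    "Yaw_vel_avg",
    "Arc_vel_avg",
    "Arc_rad",
    "Arc_cent_max",
    "PRT_time",
    "PRT_deg",
    "PRT_pct",
)


@dataclass
class DetectionParams:
    """Search thresholds for the ten maneuver classes.

    Units: metres, seconds, degrees.  The defaults are the printed
    search parameters of the assay; the ``*_swing``/``dead_band``
    entries are numerical hysteresis settings for extremum and
    zero-crossing detection on residually noisy series.
    """

    min_translation_path: float = 0.25
    max_cross_path: float = 0.10
    min_pitch_rotation_deg: float = 45.0
    min_yaw_rotation_deg: float = 90.0
    pitch_boundary_deg: float = 75.0
    heading_velocity_threshold_deg_s: float = 90.0
    min_arc_speed: float = 0.5
    clip_length: float = 0.25
    prt_half_path: float = 0.125
    speed_swing: float = 0.05
    angular_velocity_dead_band_deg_s: float = 5.0
    #: the effective dead band rises to this multiple of the robust
    #: (MAD-based) angular-velocity noise scale, so run bounds land where
    #: signal emerges from the noise floor rather than inside it
    dead_band_noise_mult: float = 4.0
    tangential_horizontal_accel: bool = True
    net_displacement_distances: bool = False

    @classmethod
    def for_smoothed(cls, **overrides) -> "DetectionParams":
        """Defaults matched to Kalman-smoothed input.

        Smoothing spreads low angular-velocity tails beyond a rotation's
        true bounds; a dead band of 50 deg/s places the run bounds at
        the smoothed series' effective rise, which recovers scripted
        rotation durations on synthetic fixtures (hummingbird rotations
        peak well above 300 deg/s, so no real maneuver is lost).
        """
        overrides.setdefault("angular_velocity_dead_band_deg_s", 50.0)
        return cls(**overrides)


def _segment_path(kin: KinematicSeries, which: str, i: int, j: int) -> float:
    cum = {
        "xyz": kin.cum_path_xyz,
        "xy": kin.cum_path_xy,
        "z": kin.cum_path_z,
    }[which]
    return float(cum[j] - cum[i])


def _distance(kin: KinematicSeries, which: str, i: int, j: int, params: DetectionParams) -> float:
    if not params.net_displacement_distances:
        return _segment_path(kin, which, i, j)
    d = kin.position[j] - kin.position[i]
    if which == "xyz":
        return float(np.linalg.norm(d))
    if which == "xy":
        return float(np.hypot(d[0], d[1]))
    return float(abs(d[2]))


def clip_by_arclength(
    kin: KinematicSeries, center: int, length: float, plane: str = "xyz"
) -> tuple[int, int] | None:
    """Smallest frame window around ``center`` with >= ``length`` of path.

    The window is split as evenly as the sampling allows: each side must
    accumulate ``length / 2`` of cumulative path (``plane`` selects xy
    or xyz path length).  Returns None when either side of the
    trajectory cannot supply half the path, which rejects the maneuver.
    """
    cum = kin.cum_path_xy if plane == "xy" else kin.cum_path_xyz
    half = length / 2.0
    left = cum[center] - cum[: center + 1]
    lo_candidates = np.flatnonzero(left >= half)
    if lo_candidates.size == 0:
        return None
    lo = int(lo_candidates[-1])
    right = cum[center:] - cum[center]
    hi_candidates = np.flatnonzero(right >= half)
    if hi_candidates.size == 0:
        return None
    hi = int(center + hi_candidates[0])
    return lo, hi


def _extrema_pairs(
    series: np.ndarray, swing: float, first: str
) -> list[tuple[int, int]]:
    """Consecutive (start, end) extremum pairs, ``first`` -> opposite."""
    ext = alternating_extrema(series, min_swing=swing)
    pairs = []
    for (i, ki), (j, kj) in zip(ext[:-1], ext[1:]):
        if ki == first and i < j:
            pairs.append((i, j))
    return pairs


def _detect_translational(kin: KinematicSeries, params: DetectionParams) -> list[Maneuver]:
    out: list[Maneuver] = []
    dt = kin.frame_interval

    def max_over(series, i, j, sign):
        seg = sign * series[i : j + 1]
        return float(np.max(seg))

    # 3D acceleration: total-speed minimum -> maximum, >= 25 cm of travel
    for i, j in _extrema_pairs(kin.speed_xyz, params.speed_swing, "min"):
        if _distance(kin, "xyz", i, j, params) > params.min_translation_path:
            out.append(
                Maneuver(
                    "accel3D", i, j, {"Vel_max": float(np.max(kin.speed_xyz[i : j + 1]))}
                )
            )
    # horizontal acceleration / deceleration
    if params.tangential_horizontal_accel:
        accel_h = kin.accel_xy_tangential
    else:
        accel_h = np.sign(kin.accel_xy_tangential) * np.hypot(
            kin.acceleration[:, 0], kin.acceleration[:, 1]
        )
    for first, cls, metric, sign in (
        ("min", "accelHor", "AccHor_max", 1.0),
        ("max", "decelHor", "DecHor_max", -1.0),
    ):
        for i, j in _extrema_pairs(kin.speed_xy, params.speed_swing, first):
            if (
                _distance(kin, "xy", i, j, params) > params.min_translation_path
                and _distance(kin, "z", i, j, params) < params.max_cross_path
            ):
                out.append(Maneuver(cls, i, j, {metric: max_over(accel_h, i, j, sign)}))
    # vertical up / down acceleration on signed vertical velocity
    for first, cls, metric, sign in (
        ("min", "accelVU", "AccVU_max", 1.0),
        ("max", "accelVD", "AccVD_max", -1.0),
    ):
        for i, j in _extrema_pairs(kin.v_z, params.speed_swing, first):
            if _distance(kin, "z", i, j, params) > params.min_translation_path:
                out.append(Maneuver(cls, i, j, {metric: max_over(kin.accel_z, i, j, sign)}))
    return out


def _signed_runs(series: np.ndarray, dead_band: float, sign: float) -> list[tuple[int, int]]:
    """Maximal frame runs where ``sign * series > dead_band``."""
    mask = sign * series > dead_band
    runs = []
    start = None
    for k, m in enumerate(mask):
        if m and start is None:
            start = k
        elif not m and start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, len(series) - 1))
    return [(i, j) for i, j in runs if j > i]


def _adaptive_band(series: np.ndarray, params: DetectionParams) -> float:
    """Dead band raised to sit above the series' own noise floor."""
    med = np.median(series)
    mad = np.median(np.abs(series - med))
    return max(
        params.angular_velocity_dead_band_deg_s,
        params.dead_band_noise_mult * 1.4826 * float(mad),
    )


def _detect_rotational(kin: KinematicSeries, params: DetectionParams) -> list[Maneuver]:
    out: list[Maneuver] = []
    n = kin.n_frames

    def widen(i: int, j: int, angle: np.ndarray, sign: float) -> tuple[int, int]:
        # the bounding angle extrema sit on the adjacent frames, but only
        # when those frames still continue the sweep (the dead-band
        # crossing may already coincide with the extremum)
        eps = 1e-3
        if i > 0 and sign * (angle[i] - angle[i - 1]) > eps:
            i -= 1
        if j < n - 1 and sign * (angle[j + 1] - angle[j]) > eps:
            j += 1
        return i, j

    # pitch-up / pitch-down: continuous pitch velocity of one sign
    band = _adaptive_band(kin.pitch_velocity, params)
    for sign, cls, metric in ((1.0, "pitchUp", "PitchU_vel_avg"), (-1.0, "pitchDown", "PitchD_vel_avg")):
        for i, j in _signed_runs(kin.pitch_velocity, band, sign):
            i, j = widen(i, j, kin.pitch, sign)
            rotated = abs(kin.pitch[j] - kin.pitch[i])
            if (
                rotated > params.min_pitch_rotation_deg
                and _distance(kin, "xyz", i, j, params) < params.max_cross_path
            ):
                duration = kin.time[j] - kin.time[i]
                out.append(Maneuver(cls, i, j, {metric: rotated / duration / 360.0}))
    # yaw turns: azimuth sweeps of either sign while pitched below 75 deg
    band = _adaptive_band(kin.azimuth_velocity, params)
    for sign in (1.0, -1.0):
        for i, j in _signed_runs(kin.azimuth_velocity, band, sign):
            i, j = widen(i, j, kin.azimuth, sign)
            rotated = abs(kin.azimuth[j] - kin.azimuth[i])
            if (
                rotated > params.min_yaw_rotation_deg
                and np.max(kin.pitch[i : j + 1]) < params.pitch_boundary_deg
                and _distance(kin, "xyz", i, j, params) < params.max_cross_path
            ):
                duration = kin.time[j] - kin.time[i]
                out.append(
                    Maneuver("yawTurn", i, j, {"Yaw_vel_avg": rotated / duration / 360.0})
                )
    return out


def _detect_arcing(kin: KinematicSeries, params: DetectionParams) -> list[Maneuver]:
    out: list[Maneuver] = []
    hv = np.where(kin.heading_defined, kin.heading_velocity, 0.0)
    hv = np.nan_to_num(hv)
    for i, j in _signed_runs(np.abs(hv), params.heading_velocity_threshold_deg_s, 1.0):
        if np.min(kin.speed_xy[i : j + 1]) <= params.min_arc_speed:
            continue
        if _distance(kin, "xy", i, j, params) <= params.min_translation_path:
            continue
        if _distance(kin, "z", i, j, params) >= params.max_cross_path:
            continue
        # sharpest point: frame of maximum heading-velocity magnitude
        seg = np.abs(hv[i : j + 1])
        center = i + _plateau_midpoint(seg, int(np.argmax(seg)), 0.5)
        clip = clip_by_arclength(kin, center, params.clip_length, plane="xy")
        if clip is None:
            continue
        cs, ce = clip
        if not (kin.heading_defined[cs] and kin.heading_defined[ce]):
            continue
        arc_vel = float(np.mean(kin.speed_xy[cs : ce + 1]))
        d_heading = abs(np.radians(kin.heading[ce] - kin.heading[cs]))
        if d_heading <= 0:
            continue
        arc_dist = _segment_path(kin, "xy", cs, ce)
        arc_rad = arc_dist / d_heading
        out.append(
            Maneuver(
                "arcingTurn",
                i,
                j,
                {
                    "Arc_vel_avg": arc_vel,
                    "Arc_rad": arc_rad,
                    "Arc_cent_max": arc_vel**2 / arc_rad,
                },
                clip_start=cs,
                clip_end=ce,
            )
        )
    return out


def _detect_pitch_roll(kin: KinematicSeries, params: DetectionParams) -> list[Maneuver]:
    out: list[Maneuver] = []
    ext = alternating_extrema(kin.speed_xyz, min_swing=params.speed_swing)
    maxima = [(k, idx) for k, (idx, kind) in enumerate(ext) if kind == "max"]
    for (k1, i), (k2, j) in zip(maxima[:-1], maxima[1:]):
        if k2 != k1 + 2:  # must be consecutive maxima with one minimum between
            continue
        m = ext[k1 + 1][0]
        if np.max(kin.pitch[i : j + 1]) <= params.pitch_boundary_deg:
            continue
        if (
            _distance(kin, "xy", i, m, params) < params.prt_half_path
            or _distance(kin, "xy", m, j, params) < params.prt_half_path
        ):
            continue
        clip = clip_by_arclength(kin, m, params.clip_length, plane="xyz")
        if clip is None:
            continue
        cs, ce = clip
        if _distance(kin, "z", cs, ce, params) >= params.max_cross_path:
            continue
        prt_time = float(kin.time[ce] - kin.time[cs])
        hs = kin.heading[cs] if kin.heading_defined[cs] else np.nan
        he = kin.heading[ce] if kin.heading_defined[ce] else np.nan
        prt_deg = float(abs(he - hs)) if np.isfinite(hs) and np.isfinite(he) else np.nan
        out.append(
            Maneuver(
                "pitchRollTurn",
                i,
                j,
                {"PRT_time": prt_time, "PRT_deg": prt_deg},
                clip_start=cs,
                clip_end=ce,
            )
        )
    return out


def detect_maneuvers(
    kin: KinematicSeries,
    params: DetectionParams | None = None,
    classes: tuple[str, ...] | None = None,
) -> list[Maneuver]:
    """Run all maneuver detectors over one kinematic series.

    Classes are detected independently and may overlap in frames, with
    one exception checked downstream: arcing and pitch-roll turns are
    mutually exclusive by construction (an arcing turn requires > 0.5
    m/s everywhere while a pitch-roll turn brakes to near zero).
    Returns maneuvers ordered by start frame.
    """
    if params is None:
        params = DetectionParams()
    found = (
        _detect_translational(kin, params)
        + _detect_rotational(kin, params)
        + _detect_arcing(kin, params)
        + _detect_pitch_roll(kin, params)
    )
    if classes is not None:
        found = [m for m in found if m.maneuver_class in classes]
    return sorted(found, key=lambda m: (m.start_frame, m.maneuver_class))


def prt_percent(maneuvers: list[Maneuver]) -> float:
    """Share of complex turns executed as pitch-roll turns.

    n_PRT / (n_PRT + n_arcing) over one trial's maneuvers; NaN when the
    trial contains no complex turn.
    """
    n_prt = sum(1 for m in maneuvers if m.maneuver_class == "pitchRollTurn")
    n_arc = sum(1 for m in maneuvers if m.maneuver_class == "arcingTurn")
    if n_prt + n_arc == 0:
        return float("nan")
    return n_prt / (n_prt + n_arc)


def recheck_maneuver(kin: KinematicSeries, m: Maneuver, params: DetectionParams | None = None) -> bool:
    """Re-evaluate the class predicate on a stored maneuver segment.

    Used as a self-check invariant: every emitted maneuver must still
    satisfy its search constraints when they are re-applied to the
    stored bounds.
    """
    if params is None:
        params = DetectionParams()
    i, j = m.start_frame, m.end_frame
    cls = m.maneuver_class
    if cls == "accel3D":
        return _distance(kin, "xyz", i, j, params) > params.min_translation_path
    if cls in ("accelHor", "decelHor"):
        return (
            _distance(kin, "xy", i, j, params) > params.min_translation_path
            and _distance(kin, "z", i, j, params) < params.max_cross_path
        )
    if cls in ("accelVU", "accelVD"):
        return _distance(kin, "z", i, j, params) > params.min_translation_path
    if cls in ("pitchUp", "pitchDown"):
        return (
            abs(kin.pitch[j] - kin.pitch[i]) > params.min_pitch_rotation_deg
            and _distance(kin, "xyz", i, j, params) < params.max_cross_path
        )
    if cls == "yawTurn":
        return (
            abs(kin.azimuth[j] - kin.azimuth[i]) > params.min_yaw_rotation_deg
            and float(np.max(kin.pitch[i : j + 1])) < params.pitch_boundary_deg
            and _distance(kin, "xyz", i, j, params) < params.max_cross_path
        )
    if cls == "arcingTurn":
        hv = np.nan_to_num(kin.heading_velocity)
        return (
            float(np.min(np.abs(hv[i : j + 1])))
            > params.heading_velocity_threshold_deg_s - 1e-9
            and float(np.min(kin.speed_xy[i : j + 1])) > params.min_arc_speed
            and _distance(kin, "xy", i, j, params) > params.min_translation_path
            and _distance(kin, "z", i, j, params) < params.max_cross_path
        )
    if cls == "pitchRollTurn":
        return (
            float(np.max(kin.pitch[i : j + 1])) > params.pitch_boundary_deg
            and m.clip_start is not None
            and m.clip_end is not None
            and _distance(kin, "z", m.clip_start, m.clip_end, params) < params.max_cross_path
        )
    raise ValueError(f"unknown maneuver class {cls!r}")
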