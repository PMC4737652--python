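"""Synthetic flight data with known ground truth.

Three generators cover the pipeline's test surface:

* :func:`gen_free_fall` — dropped-object traces for calibrating and
  validating the position smoother against gravity.
* :func:`gen_bout` / :func:`standard_bouts` — single-trajectory flight
  bouts composed of kinematic primitives (cruises, speed ramps, arcs,
  pitch ramps, azimuth sweeps, pitch-roll turns).  Every planted
  maneuver is returned with its true metric values, so detector recall,
  precision, and metric accuracy can be scored exactly.
* :func:`gen_population` — bird-trial performance records drawn from a
  linear mixed model with known variance components and fixed effects,
  for validating the repeatability and model-selection machinery.

Bout primitives are built from piecewise-linear profiles of horizontal
speed, heading, vertical velocity, and body-axis angles.  Corners are
blended with a smoothstep window (default 0.05 s) so positions are C2
and interpolation splines do not ring; the blend preserves knot values
and never exceeds the adjoining slopes, so closed-form peak
accelerations remain exact.  Tracking noise is modeled as isotropic
Gaussian position error, small-angle orientation error, and Bernoulli
sign flips of the (head/tail ambiguous) body axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core_io import Trajectory
from .kinematics import alternating_extrema

__all__ = [
    "GRAVITY",
    "TruthManeuver",
    "BoutPlan",
    "PopulationPlan",
    "gen_free_fall",
    "gen_bout",
    "standard_bouts",
    "trial_structure",
    "gen_population",
    "gen_trial_set",
    "TABLE_GRAND_MEANS",
]

GRAVITY = 9.81

#: published grand means (and bird-mean ranges) used as generator defaults
TABLE_GRAND_MEANS = {
    "Vel_max": (2.22, 1.20, 2.94),
    "AccHor_max": (6.30, 2.96, 8.83),
    "DecHor_max": (6.67, 3.45, 9.03),
    "AccVU_max": (3.78, 2.98, 4.67),
    "AccVD_max": (3.58, 2.68, 4.69),
    "PitchU_vel_avg": (1.13, 0.91, 1.34),
    "PitchD_vel_avg": (1.00, 0.78, 1.19),
    "Yaw_vel_avg": (1.52, 1.32, 1.75),
    "PRT_deg": (133.3, 34.9, 162.7),
    "PRT_time": (0.47, 0.38, 0.60),
    "Arc_rad": (0.48, 0.14, 0.70),
    "Arc_vel_avg": (1.57, 0.80, 2.26),
    "Arc_cent_max": (6.59, 3.42, 10.80),
    "PRT_pct": (0.69, 0.39, 0.87),
}

#: default repeatability targets per metric (high for translational and
#: complex-turn metrics, moderate for rotations, low for vertical)
DEFAULT_ICC = {
    "Vel_max": 0.85,
    "AccHor_max": 0.85,
    "DecHor_max": 0.85,
    "AccVU_max": 0.05,
    "AccVD_max": 0.05,
    "PitchU_vel_avg": 0.55,
    "PitchD_vel_avg": 0.55,
    "Yaw_vel_avg": 0.55,
    "PRT_deg": 0.85,
    "PRT_time": 0.85,
    "Arc_rad": 0.85,
    "Arc_vel_avg": 0.85,
    "Arc_cent_max": 0.85,
    "PRT_pct": 0.55,
}


@dataclass
class TruthManeuver:
    """A planted maneuver: class, time bounds, and true metric values."""

    maneuver_class: str
    t_start: float
    t_end: float
    metrics: dict[str, float]


def gen_free_fall(
    n_traces: int = 7,
    durations: np.ndarray | None = None,
    noise_sd: float = 0.012,
    fps: float = 200.0,
    seed: int | np.random.Generator | None = None,
) -> list[Trajectory]:
    """Dropped-object traces: z(t) = z0 - g t^2 / 2 plus tracking noise.

    Durations default to ``n_traces`` values evenly spanning 0.5-1.0 s
    (drops of varying lengths).  Noise is isotropic Gaussian with SD
    ``noise_sd`` (default 12 mm, the position observation noise).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if durations is None:
        durations = np.linspace(0.5, 1.0, n_traces)
    durations = np.asarray(durations, dtype=float)
    if np.any(durations < 0.3):
        raise ValueError("free-fall traces must last at least 0.3 s")
    out = []
    for k, dur in enumerate(durations):
        t = np.arange(0.0, dur, 1.0 / fps)
        z0 = 0.5 * GRAVITY * dur**2 + 0.05
        pos = np.column_stack([np.zeros_like(t), np.zeros_like(t), z0 - 0.5 * GRAVITY * t**2])
        if noise_sd > 0:
            pos = pos + rng.normal(0.0, noise_sd, pos.shape)
        ori = np.tile([1.0, 0.0, 0.0], (len(t), 1))
        out.append(
            Trajectory(
                object_id=f"fall{k}",
                bird_id="drop",
                trial_id="calibration",
                competitor_present=False,
                time=t,
                position=pos,
                orientation=ori,
            )
        )
    return out


class _Profile:
    """Piecewise scalar profile built from hold/ramp segments.

    ``linear`` ramps have constant slope (constant acceleration) and get
    their corners C1-blended with a smoothstep window so position
    splines do not ring; the blend preserves knot values and never
    exceeds the adjoining slopes.  ``smooth`` ramps follow a smoothstep
    shape whose derivative is zero exactly at the scripted endpoints —
    used for angle sweeps, where the maneuver's average angular velocity
    must equal delta / duration exactly.
    """

    def __init__(self, initial: float):
        self.v0 = float(initial)
        self.segments: list[tuple[float, float, float, float, str, float | None]] = []

    @property
    def current(self) -> float:
        return self.segments[-1][3] if self.segments else self.v0

    @property
    def t_last(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    def ramp(
        self,
        t0: float,
        t1: float,
        v1: float,
        kind: str = "linear",
        blend: float | None = None,
    ) -> None:
        """Append a ramp; ``blend`` widens the corner windows of a linear
        ramp (a wider window gives a trapezoidal, step-free acceleration
        profile while preserving the same peak slope)."""
        if t1 <= t0:
            raise ValueError("profile segment must have positive duration")
        if t0 < self.t_last - 1e-12:
            raise ValueError("profile segments must not overlap")
        self.segments.append((t0, t1, self.current, float(v1), kind, blend))

    def _slope(self, time: float) -> float:
        for t0, t1, v0, v1, kind, _ in self.segments:
            if t0 <= time < t1:
                if kind == "linear":
                    return (v1 - v0) / (t1 - t0)
                u = (time - t0) / (t1 - t0)
                return (v1 - v0) / (t1 - t0) * 6.0 * u * (1.0 - u)
        return 0.0

    def sample(self, t: np.ndarray, default_blend: float) -> np.ndarray:
        if not self.segments:
            return np.full(t.shape, self.v0)
        d = np.zeros_like(t, dtype=float)
        corners: dict[float, float] = {}
        for t0, t1, v0, v1, kind, blend in self.segments:
            m = (t >= t0) & (t < t1)
            if kind == "linear":
                d[m] = (v1 - v0) / (t1 - t0)
                w = default_blend if blend is None else blend
                for tc in (t0, t1):
                    corners[tc] = max(corners.get(tc, 0.0), w)
            else:
                u = (t[m] - t0) / (t1 - t0)
                d[m] = (v1 - v0) / (t1 - t0) * 6.0 * u * (1.0 - u)
        corner_times = sorted(corners)
        for k, tc in enumerate(corner_times):
            sl = self._slope(tc - 1e-9)
            sr = self._slope(tc + 1e-9)
            if sl == sr:
                continue
            w = corners[tc]
            if k > 0:
                w = min(w, (tc - corner_times[k - 1]) / 2)
            if k < len(corner_times) - 1:
                w = min(w, (corner_times[k + 1] - tc) / 2)
            m = (t > tc - w) & (t < tc + w)
            if np.any(m):
                u = (t[m] - tc + w) / (2 * w)
                d[m] = sl + (sr - sl) * (3 * u**2 - 2 * u**3)
        return self.v0 + cumulative_trapezoid(d, t, initial=0.0)


class BoutBuilder:
    """Compose a flight bout from kinematic primitives.

    The builder keeps profiles of horizontal speed, heading, vertical
    velocity, and the body-axis azimuth/pitch.  During translation the
    body azimuth follows the heading with an upright pitch bias;
    in-place rotation primitives script the angles directly.  Each
    primitive records the maneuvers it plants (with closed-form metric
    values); a finalization scan adds the total-speed accelerations
    that emerge from the composed speed profile.
    """

    def __init__(
        self,
        fps: float = 200.0,
        start: tuple[float, float, float] = (0.0, 0.0, 0.75),
        heading_deg: float = 0.0,
        pitch_deg: float = 45.0,
        speed: float = 0.0,
        vz: float = 0.0,
        blend: float = 0.05,
        oversample: int = 10,
        min_translation_path: float = 0.25,
    ):
        self.fps = fps
        self.blend = blend
        self.oversample = oversample
        self.start = np.asarray(start, dtype=float)
        self.min_translation_path = min_translation_path
        self.t = 0.0
        self.speed = _Profile(speed)
        self.heading = _Profile(heading_deg)
        self.vz = _Profile(vz)
        self.opitch = _Profile(pitch_deg)
        self.oaz = _Profile(heading_deg)
        self.truth: list[TruthManeuver] = []
        self._pending_prt: list[tuple[float, float, float]] = []

    # ------------------------------------------------------------------
    # primitives
    def cruise(self, duration: float) -> "BoutBuilder":
        self.t += duration
        return self

    def ramp_speed(
        self, v1: float, duration: float, kind: str = "linear", blend: float | None = None
    ) -> "BoutBuilder":
        """Change horizontal speed: constant acceleration (``linear``)
        or a smoothstep ramp (``smooth``, peak acceleration 1.5 dv/dt)."""
        v0 = self.speed.current
        t0 = self.t
        self.speed.ramp(t0, t0 + duration, v1, kind=kind, blend=blend)
        self.t = t0 + duration
        path = 0.5 * (v0 + v1) * duration
        accel = abs(v1 - v0) / duration * (1.5 if kind == "smooth" else 1.0)
        if path > self.min_translation_path and self.vz.current == 0.0:
            cls, metric = ("accelHor", "AccHor_max") if v1 > v0 else ("decelHor", "DecHor_max")
            self.truth.append(TruthManeuver(cls, t0, self.t, {metric: accel}))
        return self

    def ramp_vz(
        self, vz1: float, duration: float, kind: str = "linear", blend: float | None = None
    ) -> "BoutBuilder":
        """Change vertical velocity (constant-acceleration or smoothstep)."""
        v0 = self.vz.current
        t0 = self.t
        self.vz.ramp(t0, t0 + duration, vz1, kind=kind, blend=blend)
        self.t = t0 + duration
        z_path = 0.5 * abs(v0 + vz1) * duration  # assumes no sign change
        accel = abs(vz1 - v0) / duration * (1.5 if kind == "smooth" else 1.0)
        if z_path > self.min_translation_path:
            cls, metric = ("accelVU", "AccVU_max") if vz1 > v0 else ("accelVD", "AccVD_max")
            self.truth.append(TruthManeuver(cls, t0, self.t, {metric: accel}))
        return self

    def arc(self, angle_deg: float, radius: float) -> "BoutBuilder":
        """Horizontal circular arc at the current (constant) speed."""
        v = self.speed.current
        if v <= 0:
            raise ValueError("arc requires positive horizontal speed")
        duration = abs(np.radians(angle_deg)) * radius / v
        t0 = self.t
        self.heading.ramp(t0, t0 + duration, self.heading.current + angle_deg)
        self.oaz.ramp(t0, t0 + duration, self.oaz.current + angle_deg)
        self.t = t0 + duration
        heading_rate = v / radius  # rad/s
        arc_len = abs(np.radians(angle_deg)) * radius
        if (
            np.degrees(heading_rate) > 90.0
            and v > 0.5
            and arc_len > self.min_translation_path
        ):
            self.truth.append(
                TruthManeuver(
                    "arcingTurn",
                    t0,
                    self.t,
                    {"Arc_vel_avg": v, "Arc_rad": radius, "Arc_cent_max": v**2 / radius},
                )
            )
        return self

    def pitch_to(self, pitch_deg: float, duration: float) -> "BoutBuilder":
        """In-place body pitch ramp (hover primitives only)."""
        p0 = self.opitch.current
        t0 = self.t
        self.opitch.ramp(t0, t0 + duration, pitch_deg, kind="smooth")
        self.t = t0 + duration
        rotated = abs(pitch_deg - p0)
        travel = np.hypot(self.speed.current, self.vz.current) * duration
        if rotated > 45.0 and travel < 0.10:
            cls, metric = ("pitchUp", "PitchU_vel_avg") if pitch_deg > p0 else ("pitchDown", "PitchD_vel_avg")
            self.truth.append(TruthManeuver(cls, t0, self.t, {metric: rotated / duration / 360.0}))
        return self

    def sweep_az(self, delta_deg: float, duration: float) -> "BoutBuilder":
        """In-place body azimuth sweep (hover primitives only)."""
        t0 = self.t
        self.oaz.ramp(t0, t0 + duration, self.oaz.current + delta_deg, kind="smooth")
        self.t = t0 + duration
        travel = np.hypot(self.speed.current, self.vz.current) * duration
        if (
            abs(delta_deg) > 90.0
            and max(self.opitch.current, 0.0) < 75.0
            and travel < 0.10
        ):
            self.truth.append(
                TruthManeuver(
                    "yawTurn", t0, self.t, {"Yaw_vel_avg": abs(delta_deg) / duration / 360.0}
                )
            )
        return self

    def pitch_roll_turn(
        self,
        v_min: float = 0.05,
        decel: float = 3.0,
        peak_pitch_deg: float = 85.0,
        turn_deg: float = 180.0,
        kind: str = "linear",
        blend: float | None = None,
        dwell: float = 0.25,
    ) -> "BoutBuilder":
        """Brake, pitch near vertical, flip heading, accelerate away.

        The speed drops from the current speed to ``v_min`` at constant
        ``decel``, pauses for ``dwell`` seconds at the turn point (birds
        momentarily hang in the air mid-turn), and accelerates back; the
        body pitches to ``peak_pitch_deg`` around the turn while heading
        and body azimuth rotate by ``turn_deg``.  Plants a pitchRollTurn
        plus the deceleration/acceleration legs it contains.
        """
        v0 = self.speed.current
        if v0 <= 0.5:
            raise ValueError("pitch-roll turn must start from forward flight")
        dd = (v0 - v_min) / decel
        if dd < 0.2 or dwell < 0.2:
            raise ValueError("legs and dwell too short to script the turn")
        t0 = self.t
        t_lo = t0 + dd
        t_hi = t_lo + dwell
        t_c = 0.5 * (t_lo + t_hi)
        self.speed.ramp(t0, t_lo, v_min, kind=kind, blend=blend)
        self.speed.ramp(t_hi, t_hi + dd, v0, kind=kind, blend=blend)
        p0 = self.opitch.current
        ramp = min(0.25, dd)
        self.opitch.ramp(t_c - 0.1 - ramp, t_c - 0.1, peak_pitch_deg, kind="smooth")
        self.opitch.ramp(t_c + 0.1, t_c + 0.1 + ramp, p0, kind="smooth")
        h0 = self.heading.current
        self.heading.ramp(t_c - 0.1, t_c + 0.1, h0 + turn_deg, kind="smooth")
        self.oaz.ramp(t_c - 0.1, t_c + 0.1, self.oaz.current + turn_deg, kind="smooth")
        self.t = t_hi + dd
        path = 0.5 * (v0 + v_min) * dd
        peak = decel * (1.5 if kind == "smooth" else 1.0)
        if path > self.min_translation_path:
            self.truth.append(TruthManeuver("decelHor", t0, t_lo, {"DecHor_max": peak}))
            self.truth.append(TruthManeuver("accelHor", t_hi, self.t, {"AccHor_max": peak}))
        if peak_pitch_deg > 75.0:  # otherwise the segment is not a pitch-roll turn
            self._pending_prt.append((t_c, abs(turn_deg), t0))
        return self

    # ------------------------------------------------------------------
    def _frame_grid(self) -> tuple[np.ndarray, np.ndarray]:
        n_frames = int(round(self.t * self.fps)) + 1
        n_fine = (n_frames - 1) * self.oversample + 1
        dt_fine = 1.0 / (self.fps * self.oversample)
        return np.arange(n_fine) * dt_fine, np.arange(n_frames) / self.fps

    def build(
        self,
        noise_sd: float = 0.0,
        ori_noise_sd: float = 0.0,
        sign_flip_p: float = 0.0,
        rng: np.random.Generator | None = None,
        object_id: str = "bout",
        bird_id: str = "bird0",
        trial_id: str = "trial0",
        competitor_present: bool = False,
    ) -> tuple[Trajectory, list[TruthManeuver]]:
        """Sample the composed bout at the frame rate and emit truth."""
        if rng is None:
            rng = np.random.default_rng(0)
        t_fine, t_frames = self._frame_grid()
        speed = self.speed.sample(t_fine, self.blend)
        heading = np.radians(self.heading.sample(t_fine, self.blend))
        vz = self.vz.sample(t_fine, self.blend)
        vx = speed * np.cos(heading)
        vy = speed * np.sin(heading)
        x = self.start[0] + cumulative_trapezoid(vx, t_fine, initial=0.0)
        y = self.start[1] + cumulative_trapezoid(vy, t_fine, initial=0.0)
        z = self.start[2] + cumulative_trapezoid(vz, t_fine, initial=0.0)
        step = self.oversample
        pos = np.column_stack([x[::step], y[::step], z[::step]])
        oaz = np.radians(self.oaz.sample(t_fine, self.blend)[::step])
        opitch = np.radians(self.opitch.sample(t_fine, self.blend)[::step])
        ori = np.column_stack(
            [np.cos(opitch) * np.cos(oaz), np.cos(opitch) * np.sin(oaz), np.sin(opitch)]
        )

        speed_xyz_frames = np.hypot(speed[::step], vz[::step])
        truth = list(self.truth)
        truth += self._accel3d_truths(t_frames, speed_xyz_frames)
        truth += self._resolve_prt_truths(t_frames, speed_xyz_frames)
        truth.sort(key=lambda m: m.t_start)

        if noise_sd > 0:
            pos = pos + rng.normal(0.0, noise_sd, pos.shape)
        if ori_noise_sd > 0:
            ori = ori + rng.normal(0.0, ori_noise_sd, ori.shape)
            ori = ori / np.linalg.norm(ori, axis=1)[:, None]
        if sign_flip_p > 0:
            flips = np.where(rng.random(len(ori)) < sign_flip_p, -1.0, 1.0)
            ori = ori * flips[:, None]
        traj = Trajectory(
            object_id=object_id,
            bird_id=bird_id,
            trial_id=trial_id,
            competitor_present=competitor_present,
            time=t_frames,
            position=pos,
            orientation=ori,
        )
        return traj, truth

    def _accel3d_truths(self, t_frames, speed_xyz) -> list[TruthManeuver]:
        """Total-speed minimum-to-maximum runs implied by the profiles."""
        out = []
        ext = alternating_extrema(speed_xyz, min_swing=1e-6, plateau_tol=1e-9)
        dt = t_frames[1] - t_frames[0] if len(t_frames) > 1 else 0.0
        path = cumulative_trapezoid(speed_xyz, t_frames, initial=0.0)
        for (i, ki), (j, kj) in zip(ext[:-1], ext[1:]):
            if ki == "min" and kj == "max" and path[j] - path[i] > self.min_translation_path:
                out.append(
                    TruthManeuver(
                        "accel3D",
                        t_frames[i],
                        t_frames[j],
                        {"Vel_max": float(np.max(speed_xyz[i : j + 1]))},
                    )
                )
        return out

    def _resolve_prt_truths(self, t_frames, speed_xyz) -> list[TruthManeuver]:
        """Clip-based pitch-roll metrics from the analytic speed profile.

        The 25 cm clip is evaluated on the frame grid with the same
        at-least-half-path-per-side rule the extraction stage uses, so
        the true PRT duration carries the same frame quantization.
        """
        out = []
        path = cumulative_trapezoid(speed_xyz, t_frames, initial=0.0)
        for t_min, turn_deg, t0 in self._pending_prt:
            c = int(np.argmin(np.abs(t_frames - t_min)))
            left = path[c] - path[: c + 1]
            right = path[c:] - path[c]
            lo = np.flatnonzero(left >= 0.125)
            hi = np.flatnonzero(right >= 0.125)
            if lo.size == 0 or hi.size == 0:
                continue
            cs, ce = int(lo[-1]), int(c + hi[0])
            out.append(
                TruthManeuver(
                    "pitchRollTurn",
                    t0,
                    2 * t_min - t0,
                    {"PRT_time": float(t_frames[ce] - t_frames[cs]), "PRT_deg": turn_deg},
                )
            )
        return out


@dataclass
class BoutPlan:
    """A scripted bout: ordered primitives plus sampling and noise settings.

    ``segments`` is a list of ``(primitive, kwargs)`` pairs naming
    :class:`BoutBuilder` methods (``cruise``, ``ramp_speed``, ``arc``,
    ``ramp_vz``, ``pitch_to``, ``sweep_az``, ``pitch_roll_turn``).
    """

    segments: list[tuple[str, dict]]
    fps: float = 200.0
    start: tuple[float, float, float] = (0.0, 0.0, 0.75)
    heading_deg: float = 0.0
    pitch_deg: float = 45.0
    speed: float = 0.0
    vz: float = 0.0
    noise_sd: float = 0.0
    ori_noise_sd: float = 0.0
    sign_flip_p: float = 0.0
    seed: int | None = None

_PRIMITIVES = ("cruise", "ramp_speed", "arc", "ramp_vz", "pitch_to", "sweep_az", "pitch_roll_turn")


def gen_bout(
    plan: BoutPlan,
    rng: np.random.Generator | None = None,
    **ids,
) -> tuple[Trajectory, list[TruthManeuver]]:
    """Generate one bout from a plan; returns trajectory and ground truth."""
    builder = BoutBuilder(
        fps=plan.fps,
        start=plan.start,
        heading_deg=plan.heading_deg,
        pitch_deg=plan.pitch_deg,
        speed=plan.speed,
        vz=plan.vz,
    )
    for name, kwargs in plan.segments:
        if name not in _PRIMITIVES:
            raise ValueError(f"unknown bout primitive {name!r}")
        getattr(builder, name)(**kwargs)
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    return builder.build(
        noise_sd=plan.noise_sd,
        ori_noise_sd=plan.ori_noise_sd,
        sign_flip_p=plan.sign_flip_p,
        rng=rng,
        **ids,
    )


def standard_bouts(scale: float = 1.0, fps: float = 200.0, **noise) -> list[BoutPlan]:
    """Five canned bouts that together plant all ten maneuver classes.

    ``scale`` multiplies the characteristic speeds/accelerations (and
    divides rotation durations), emulating a faster or slower
    individual; geometry (arc radius, travel distances) is preserved.
    """
    s = float(scale)
    translational = BoutPlan(
        segments=[
            ("cruise", {"duration": 0.8}),
            ("ramp_speed", {"v1": 2.6 * s, "duration": 0.4, "blend": 0.10}),
            ("cruise", {"duration": 0.8}),
            ("ramp_speed", {"v1": 0.4 * s, "duration": 0.4, "blend": 0.10}),
            ("cruise", {"duration": 0.8}),
        ],
        speed=0.4 * s,
        fps=fps,
        **noise,
    )
    vertical = BoutPlan(
        segments=[
            ("cruise", {"duration": 0.6}),
            ("ramp_vz", {"vz1": 1.9 * s, "duration": 0.45, "blend": 0.10}),
            ("cruise", {"duration": 0.5}),
            ("ramp_vz", {"vz1": 0.2 * s, "duration": 0.45, "blend": 0.10}),
            ("cruise", {"duration": 0.6}),
        ],
        vz=0.2 * s,
        start=(0.0, 0.0, 0.1),
        fps=fps,
        **noise,
    )
    # rotations happen on a slow drift: real hovering birds are never
    # perfectly stationary, and a nonzero travel direction anchors the
    # head/tail resolution without breaking the < 10 cm in-place limit
    rotations = BoutPlan(
        segments=[
            ("cruise", {"duration": 0.4}),
            ("pitch_to", {"pitch_deg": 65.0, "duration": 0.3 / s}),
            ("cruise", {"duration": 0.4}),
            ("pitch_to", {"pitch_deg": 5.0, "duration": 0.3 / s}),
            ("cruise", {"duration": 0.4}),
            ("pitch_to", {"pitch_deg": 40.0, "duration": 0.3}),
            ("cruise", {"duration": 0.3}),
            ("sweep_az", {"delta_deg": 150.0, "duration": 0.5 / s}),
            ("cruise", {"duration": 0.4}),
        ],
        pitch_deg=5.0,
        speed=0.08,
        fps=fps,
        **noise,
    )
    arc = BoutPlan(
        segments=[
            ("cruise", {"duration": 0.5}),
            ("arc", {"angle_deg": 120.0, "radius": 0.6}),
            ("cruise", {"duration": 0.5}),
        ],
        speed=1.5 * s,
        fps=fps,
        **noise,
    )
    prt = BoutPlan(
        segments=[
            ("cruise", {"duration": 0.7}),
            ("pitch_roll_turn", {"v_min": 0.05, "decel": 3.0 * s, "peak_pitch_deg": 85.0, "turn_deg": 180.0, "blend": 0.12}),
            ("cruise", {"duration": 0.7}),
        ],
        speed=1.6 * s,
        fps=fps,
        **noise,
    )
    return [translational, vertical, rotations, arc, prt]


# ----------------------------------------------------------------------
# population-level generator


def trial_structure(n_birds: int = 20) -> "pd.DataFrame":
    """The study's trial design: solo plus paired competition trials.

    Twenty birds across three experiments — 8 birds with two competition
    rounds, 4 with two rounds, 8 with one round — give 20 solo records
    and 32 competition records (16 paired trials), 52 in total.  For
    other ``n_birds`` the same pattern is scaled approximately.
    """
    import pandas as pd

    if n_birds == 20:
        groups = [("CA1", 8, 2), ("CA2", 4, 2), ("BC", 8, 1)]
    else:
        half = max(2, (n_birds // 2) // 2 * 2)
        groups = [("CA1", half, 2), ("BC", n_birds - half, 1)]
    rows = []
    bird = 0
    for exp, count, comp_rounds in groups:
        birds = [f"bird{bird + i:02d}" for i in range(count)]
        bird += count
        for b in birds:
            rows.append({"bird_id": b, "trial_id": f"{b}_solo", "competitor": 0, "experiment": exp})
        for rnd in range(comp_rounds):
            order = birds if rnd == 0 else birds[1:] + birds[:1]
            for k in range(0, len(order) - 1, 2):
                pair = (order[k], order[k + 1])
                tid = f"{exp}_comp{rnd}_{k // 2}"
                for b in pair:
                    rows.append({"bird_id": b, "trial_id": tid, "competitor": 1, "experiment": exp})
    return pd.DataFrame(rows)


@dataclass
class PopulationPlan:
    """Generating parameters for bird-trial performance records.

    Metric grand means default to the published descriptive statistics;
    among-bird SDs default to a quarter of the published range of bird
    means, and residual SDs are set from the target repeatability
    (``icc``) via sd_resid = sd_among * sqrt(1/ICC - 1).  ``betas`` maps
    metric -> predictor -> coefficient on centered predictors
    (predictors: ``competitor``, ``body_mass``, ``burst``,
    ``wing_length``, ``aspect_ratio``, ``days_post_capture``).
    """

    n_birds: int = 20
    icc: dict[str, float] | float | None = None
    among_sd: dict[str, float] | None = None
    betas: dict[str, dict[str, float]] = field(default_factory=dict)
    metrics: tuple[str, ...] = tuple(TABLE_GRAND_MEANS)
    days_max: int = 23

    def metric_params(self, metric: str) -> tuple[float, float, float]:
        mean, lo, hi = TABLE_GRAND_MEANS[metric]
        among = (self.among_sd or {}).get(metric, (hi - lo) / 4.0)
        if isinstance(self.icc, dict):
            icc = self.icc.get(metric, DEFAULT_ICC[metric])
        elif self.icc is not None:
            icc = float(self.icc)
        else:
            icc = DEFAULT_ICC[metric]
        icc = min(max(icc, 1e-3), 0.999)
        resid = among * np.sqrt(1.0 / icc - 1.0)
        return mean, among, resid


def _draw_traits(n_birds: int, experiments: list[str], rng) -> "pd.DataFrame":
    import pandas as pd

    def clipped_normal(mean, sd, lo, hi, size):
        x = rng.normal(mean, sd, size)
        return np.clip(x, lo, hi)

    wing_length = clipped_normal(50.97, 2.2, 45.76, 55.45, n_birds)
    aspect = clipped_normal(7.73, 0.30, 7.13, 8.46, n_birds)
    wing_area = 4.0 * wing_length**2 / aspect
    mass = clipped_normal(4.64, 0.35, 4.09, 5.61, n_birds)
    # load lifted declines mildly with aspect ratio (site-controlled)
    load = 5.93 - 0.8 * (aspect - 7.73) + rng.normal(0.0, 0.7, n_birds)
    load = np.clip(load, 4.00, 7.24)
    return pd.DataFrame(
        {
            "bird_id": [f"bird{i:02d}" for i in range(n_birds)],
            "experiment": experiments,
            "body_mass": mass,
            "wing_length": wing_length,
            "wing_area": wing_area,
            "aspect_ratio": aspect,
            "load_lifted": load,
        }
    )


def gen_population(
    plan: PopulationPlan | None = None, seed: int | np.random.Generator | None = None
):
    """Bird-trial performance records from a known linear mixed model.

    Returns ``(records, traits, truth)``: a record table (one row per
    bird-trial with all metric means), a trait table (with residual
    burst filled in), and the generating parameters (per-metric ICC and
    fixed-effect coefficients) for recovery tests.
    """
    import pandas as pd

    from .stats import residual_burst

    if plan is None:
        plan = PopulationPlan()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = trial_structure(plan.n_birds)
    bird_exp = design.drop_duplicates("bird_id").set_index("bird_id")["experiment"]
    traits = _draw_traits(plan.n_birds, bird_exp.tolist(), rng)
    traits["residual_burst"] = residual_burst(traits)
    design = design.merge(traits, on=["bird_id", "experiment"], how="left")
    design["days_post_capture"] = np.where(
        design["competitor"] == 1, rng.integers(0, plan.days_max + 1, len(design)), 0
    )

    centered = {
        "competitor": design["competitor"].to_numpy(dtype=float),
        "body_mass": design["body_mass"] - design["body_mass"].mean(),
        "burst": design["residual_burst"].to_numpy(dtype=float),
        "wing_length": design["wing_length"] - design["wing_length"].mean(),
        "aspect_ratio": design["aspect_ratio"] - design["aspect_ratio"].mean(),
        "days_post_capture": design["days_post_capture"] - design["days_post_capture"].mean(),
    }
    birds = design["bird_id"].to_numpy()
    unique_birds = design["bird_id"].unique()
    truth: dict[str, dict] = {}
    for metric in plan.metrics:
        mean, among, resid = plan.metric_params(metric)
        b = dict.fromkeys(unique_birds, 0.0)
        for k, v in zip(unique_birds, rng.normal(0.0, among, len(unique_birds))):
            b[k] = v
        y = mean + np.array([b[k] for k in birds]) + rng.normal(0.0, resid, len(design))
        for pred, coef in plan.betas.get(metric, {}).items():
            y = y + coef * np.asarray(centered[pred], dtype=float)
        if metric == "PRT_pct":
            y = np.clip(y, 0.0, 1.0)
        design[metric] = y
        truth[metric] = {
            "icc": among**2 / (among**2 + resid**2),
            "among_sd": among,
            "resid_sd": resid,
            "betas": dict(plan.betas.get(metric, {})),
        }
    records = design[
        ["bird_id", "trial_id", "competitor", "experiment", "days_post_capture", *plan.metrics]
    ].copy()
    return records, traits, truth


def gen_trial_set(
    n_birds: int = 20,
    noise_sd: float = 0.012,
    ori_noise_sd: float = 0.002,
    sign_flip_p: float = 0.5,
    among_cv: float = 0.08,
    resid_cv: float = 0.03,
    fps: float = 200.0,
    seed: int | np.random.Generator | None = None,
):
    """Full-trajectory dataset for exercising the pipeline end to end.

    Every bird-trial yields the five standard bouts, with the bird's
    characteristic speed scale drawn from a between-individual
    distribution (CV ``among_cv``) plus within-bird trial variation
    (CV ``resid_cv``), then corrupted with tracking noise.  Returns
    ``(trajectories, traits, design)``.
    """
    import pandas as pd

    from .stats import residual_burst

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = trial_structure(n_birds)
    bird_exp = design.drop_duplicates("bird_id").set_index("bird_id")["experiment"]
    traits = _draw_traits(n_birds, bird_exp.tolist(), rng)
    traits["residual_burst"] = residual_burst(traits)
    design["days_post_capture"] = np.where(
        design["competitor"] == 1, rng.integers(0, 24, len(design)), 0
    )
    bird_scale = {
        b: float(np.clip(1.0 + rng.normal(0.0, among_cv), 0.7, 1.3))
        for b in design["bird_id"].unique()
    }
    trajectories = []
    for _, row in design.iterrows():
        scale = float(
            np.clip(bird_scale[row["bird_id"]] + rng.normal(0.0, resid_cv), 0.6, 1.4)
        )
        plans = standard_bouts(
            scale=scale,
            fps=fps,
            noise_sd=noise_sd,
            ori_noise_sd=ori_noise_sd,
            sign_flip_p=sign_flip_p,
        )
        for k, plan in enumerate(plans):
            traj, _ = gen_bout(
                plan,
                rng=rng,
                object_id=f"{row['trial_id']}_{row['bird_id']}_b{k}",
                bird_id=row["bird_id"],
                trial_id=row["trial_id"],
                competitor_present=bool(row["competitor"]),
            )
            trajectories.append(traj)
    return trajectories, traits, design
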