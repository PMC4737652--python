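"""Domain types and tabular file formats for the maneuverability pipeline.

Trajectories are stored as plain CSV with one row per frame and columns
``object_id, bird_id, trial_id, competitor, frame, t, x, y, z, ox, oy,
oz``.  Coordinates are metres in a right-handed frame with z up;
orientation columns hold the (possibly sign-ambiguous) body-axis vector.
Maneuvers are written in long format (one row per maneuver metric) so
they round-trip losslessly and aggregate easily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Maneuver",
    "PerformanceRecord",
    "BirdTraits",
    "read_trajectories",
    "write_trajectories",
    "read_maneuvers",
    "write_maneuvers",
]

logger = logging.getLogger("flightmaneuvers")

TRAJECTORY_COLUMNS = [
    "object_id",
    "bird_id",
    "trial_id",
    "competitor",
    "frame",
    "t",
    "x",
    "y",
    "z",
    "ox",
    "oy",
    "oz",
]

#: relative tolerance on the uniformity of the frame interval
TIME_STEP_RTOL = 1e-6


@dataclass
class Trajectory:
    """One continuously tracked object: positions and body-axis vectors.

    ``position`` is (n, 3) in metres, ``orientation`` (n, 3) — unit
    vectors once resolved, but raw tracker output may be unnormalized
    and sign-ambiguous.  ``time`` must advance with a constant step.
    """

    object_id: str
    bird_id: str
    trial_id: str
    competitor_present: bool
    time: np.ndarray
    position: np.ndarray
    orientation: np.ndarray
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = len(self.time)
        if self.position.shape != (n, 3) or self.orientation.shape != (n, 3):
            raise ValueError("position and orientation must have shape (n, 3)")
        if not (
            np.all(np.isfinite(self.time))
            and np.all(np.isfinite(self.position))
            and np.all(np.isfinite(self.orientation))
        ):
            raise ValueError("trajectory contains non-finite values")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            step = dt[0]
            if np.any(np.abs(dt - step) > max(1e-9, TIME_STEP_RTOL * step)):
                raise ValueError("time step is not uniform")
        if self.frame_index is None:
            self.frame_index = np.arange(n)
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)
            if self.frame_index.shape != (n,):
                raise ValueError("frame_index must match the number of frames")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_interval(self) -> float:
        if self.n_frames < 2:
            raise ValueError("frame interval undefined for a single frame")
        return float(self.time[1] - self.time[0])


#: metric symbols attached to each maneuver class
CLASS_METRICS = {
    "accel3D": ("Vel_max",),
    "accelHor": ("AccHor_max",),
    "decelHor": ("DecHor_max",),
    "accelVU": ("AccVU_max",),
    "accelVD": ("AccVD_max",),
    "pitchUp": ("PitchU_vel_avg",),
    "pitchDown": ("PitchD_vel_avg",),
    "yawTurn": ("Yaw_vel_avg",),
    "arcingTurn": ("Arc_vel_avg", "Arc_rad", "Arc_cent_max"),
    "pitchRollTurn": ("PRT_time", "PRT_deg"),
}

MANEUVER_CLASSES = tuple(CLASS_METRICS)


@dataclass
class Maneuver:
    """A classified trajectory segment with its performance metrics.

    ``clip_start``/``clip_end`` bound the 25 cm clip used by the complex
    turns (arcing and pitch-roll); other classes leave them None.
    """

    maneuver_class: str
    start_frame: int
    end_frame: int
    metrics: dict[str, float]
    clip_start: int | None = None
    clip_end: int | None = None
    bird_id: str = ""
    trial_id: str = ""
    object_id: str = ""

    def __post_init__(self) -> None:
        if self.maneuver_class not in CLASS_METRICS:
            raise ValueError(f"unknown maneuver class {self.maneuver_class!r}")
        if not self.start_frame < self.end_frame:
            raise ValueError("start_frame must precede end_frame")


@dataclass
class PerformanceRecord:
    """Bird-trial means of the performance metrics plus covariates."""

    bird_id: str
    trial_id: str
    competitor_present: bool
    experiment: str
    days_post_capture: float
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.metrics.get("PRT_pct")
        if p is not None and not np.isnan(p) and not 0.0 <= p <= 1.0:
            raise ValueError("PRT_pct must lie in [0, 1]")


@dataclass
class BirdTraits:
    """Morphology and burst (load-lifting) capacity of one bird.

    ``wing_area`` is the single-wing area in mm^2; ``aspect_ratio`` uses
    the 4 * length^2 / area convention.  ``residual_burst`` is the
    residual of load lifted after regressing out aspect ratio and site.
    """

    bird_id: str
    body_mass: float
    wing_length: float
    wing_area: float
    aspect_ratio: float
    load_lifted: float
    residual_burst: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("body_mass", "wing_length", "wing_area", "aspect_ratio", "load_lifted"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        implied = 4.0 * self.wing_length**2 / self.wing_area
        if abs(implied - self.aspect_ratio) > 0.05 * implied:
            raise ValueError(
                f"aspect_ratio {self.aspect_ratio:.3f} inconsistent with "
                f"4 L^2 / S = {implied:.3f}"
            )


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write trajectories to the flat per-frame CSV schema."""
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "object_id": tr.object_id,
                    "bird_id": tr.bird_id,
                    "trial_id": tr.trial_id,
                    "competitor": int(tr.competitor_present),
                    "frame": tr.frame_index,
                    "t": tr.time,
                    "x": tr.position[:, 0],
                    "y": tr.position[:, 1],
                    "z": tr.position[:, 2],
                    "ox": tr.orientation[:, 0],
                    "oy": tr.orientation[:, 1],
                    "oz": tr.orientation[:, 2],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectories(path, frame_rate: float = 200.0) -> list[Trajectory]:
    """Read per-frame CSV into trajectories, splitting at frame gaps.

    One :class:`Trajectory` is produced per object and per contiguous
    run of frame numbers; missing frames terminate a trajectory rather
    than being interpolated (the tracker itself ends objects when it
    loses them).  Raises on missing columns or a time step that departs
    from 1 / ``frame_rate``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")
    if df.empty:
        logger.warning("trajectory file %s is empty", path)
        return []
    bad = df[TRAJECTORY_COLUMNS[4:]].apply(pd.to_numeric, errors="coerce")
    bad_rows = bad.isna().any(axis=1)
    if bad_rows.any():
        raise ValueError(f"malformed trajectory row(s): {list(df.index[bad_rows][:5])}")
    expected_step = 1.0 / frame_rate
    out: list[Trajectory] = []
    for object_id, group in df.groupby("object_id", sort=False):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy(dtype=int)
        t = group["t"].to_numpy(dtype=float)
        if len(t) >= 2:
            dt = np.diff(t) / np.diff(frames)
            if np.any(np.abs(dt - expected_step) > 1e-6 * expected_step + 1e-9):
                raise ValueError(
                    f"object {object_id}: time step departs from 1/{frame_rate} Hz"
                )
        breaks = np.flatnonzero(np.diff(frames) != 1)
        pieces = np.split(np.arange(len(frames)), breaks + 1)
        for j, piece in enumerate(pieces):
            sub = group.iloc[piece]
            out.append(
                Trajectory(
                    object_id=str(object_id) if len(pieces) == 1 else f"{object_id}#{j}",
                    bird_id=str(sub["bird_id"].iloc[0]),
                    trial_id=str(sub["trial_id"].iloc[0]),
                    competitor_present=bool(sub["competitor"].iloc[0]),
                    time=sub["t"].to_numpy(dtype=float),
                    position=sub[["x", "y", "z"]].to_numpy(dtype=float),
                    orientation=sub[["ox", "oy", "oz"]].to_numpy(dtype=float),
                    frame_index=sub["frame"].to_numpy(dtype=int),
                )
            )
    return out


def maneuvers_to_frame(maneuvers: list[Maneuver]) -> pd.DataFrame:
    """Long-format table: one row per (maneuver, metric)."""
    rows = []
    for i, m in enumerate(maneuvers):
        for metric, value in m.metrics.items():
            rows.append(
                {
                    "maneuver_id": i,
                    "bird_id": m.bird_id,
                    "trial_id": m.trial_id,
                    "object_id": m.object_id,
                    "maneuver_class": m.maneuver_class,
                    "start_frame": m.start_frame,
                    "end_frame": m.end_frame,
                    "clip_start": -1 if m.clip_start is None else m.clip_start,
                    "clip_end": -1 if m.clip_end is None else m.clip_end,
                    "metric": metric,
                    "value": value,
                }
            )
    columns = [
        "maneuver_id",
        "bird_id",
        "trial_id",
        "object_id",
        "maneuver_class",
        "start_frame",
        "end_frame",
        "clip_start",
        "clip_end",
        "metric",
        "value",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_maneuvers(maneuvers: list[Maneuver], path) -> None:
    maneuvers_to_frame(maneuvers).to_csv(path, index=False, float_format="%.17g")


def read_maneuvers(path) -> list[Maneuver]:
    df = pd.read_csv(path)
    out: list[Maneuver] = []
    if df.empty:
        return out
    for _, group in df.groupby("maneuver_id", sort=True):
        first = group.iloc[0]
        clip_start = None if first["clip_start"] < 0 else int(first["clip_start"])
        clip_end = None if first["clip_end"] < 0 else int(first["clip_end"])
        out.append(
            Maneuver(
                maneuver_class=str(first["maneuver_class"]),
                start_frame=int(first["start_frame"]),
                end_frame=int(first["end_frame"]),
                metrics={
                    str(r["metric"]): float(r["value"]) for _, r in group.iterrows()
                },
                clip_start=clip_start,
                clip_end=clip_end,
                bird_id="" if pd.isna(first["bird_id"]) else str(first["bird_id"]),
                trial_id="" if pd.isna(first["trial_id"]) else str(first["trial_id"]),
                object_id="" if pd.isna(first["object_id"]) else str(first["object_id"]),
            )
        )
    return out
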