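"""Novel-tank trajectories and the behavioral measures derived from them.

A fish exploring an unfamiliar tank is tracked as a single 3D point per
frame.  From that time series we extract the six standard novel-tank
measures: mean height above the tank floor (``bottom_distance``), mean
horizontal distance from the tank's central vertical axis
(``center_distance``, the thigmotaxis readout), total path length
(``distance_traveled``), the percentage of an axis-aligned voxel grid the
fish visited (``percent_explored``), the percentage of inter-frame steps
slower than an immobility cut-off (``percent_immobile``), and a robust
maximum swimming speed (``max_velocity``, the median of the top 5% of
frame-to-frame speeds).

Positions are in centimetres, speeds in mm/s, times in seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TankGeometry",
    "Trajectory3D",
    "VelocitySeries",
    "BehaviorProfile",
    "ImmobilityThreshold",
    "compute_velocity",
    "distance_traveled",
    "mean_bottom_distance",
    "mean_center_distance",
    "percent_explored",
    "voxel_indices",
    "detect_immobility_threshold",
    "percent_immobile",
    "max_velocity",
    "extract_profile",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_pose_csv",
    "profiles_to_frame",
]

#: default immobility cut-off in mm/s (break in the speed distribution)
DEFAULT_IMMOBILITY_THRESHOLD = 1.5

#: fraction of top speeds whose median defines max_velocity
TOP_SPEED_FRACTION = 0.05

#: minimum number of speed samples for a meaningful top-5% median
MIN_SPEED_SAMPLES = 20


@dataclass(frozen=True)
class TankGeometry:
    """Axis-aligned tank with its exploration grid.

    Default is the 15x15x15 cm novel tank divided 10x10x10 into 1000
    voxels.  Extents are in cm.
    """

    width_x: float = 15.0
    depth_y: float = 15.0
    height_z: float = 15.0
    grid_divisions_per_axis: int = 10

    def __post_init__(self) -> None:
        for name in ("width_x", "depth_y", "height_z"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"TankGeometry.{name} must be a positive finite number, got {v!r}")
        if self.grid_divisions_per_axis < 1:
            raise ValueError("grid_divisions_per_axis must be >= 1")

    @property
    def extents(self) -> np.ndarray:
        return np.array([self.width_x, self.depth_y, self.height_z], dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.grid_divisions_per_axis) ** 3

    @property
    def horizontal_center(self) -> tuple[float, float]:
        return (self.width_x / 2.0, self.depth_y / 2.0)

    def contains(self, positions: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which rows of an (n, 3) array lie inside the tank."""
        p = np.asarray(positions, dtype=float)
        return np.all((p >= -atol) & (p <= self.extents + atol), axis=-1)


@dataclass
class Trajectory3D:
    """Uniformly sampled 3D positions of one fish inside a tank.

    ``times`` must be strictly increasing with a uniform frame interval
    (relative tolerance 1e-6); every position must lie within the tank.
    """

    times: np.ndarray
    positions: np.ndarray
    geometry: TankGeometry
    fish_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.positions.shape != (self.times.size, 3):
            raise ValueError(
                f"positions must have shape ({self.times.size}, 3), got {self.positions.shape}"
            )
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.abs(dt - dt[0]) > 1e-6 * abs(dt[0])):
            raise ValueError("frame interval must be uniform (relative tolerance 1e-6)")
        if not np.all(self.geometry.contains(self.positions)):
            bad = int(np.flatnonzero(~self.geometry.contains(self.positions))[0])
            raise ValueError(
                f"position at frame {bad} lies outside the tank: {self.positions[bad]}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class VelocitySeries:
    """Frame-to-frame speeds in mm/s; one value per inter-frame step."""

    speeds: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.speeds.ndim != 1 or self.speeds.size < 1:
            raise ValueError("a velocity series needs at least one step")
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class ImmobilityThreshold:
    """Outcome of data-driven immobility cut-off detection."""

    value: float
    used_default: bool = False
    note: str = ""


@dataclass
class BehaviorProfile:
    """The six per-fish novel-tank measures.

    ``max_velocity`` is NaN when the trajectory has too few steps for the
    top-5% median to be defined.
    """

    bottom_distance: float
    center_distance: float
    distance_traveled: float
    percent_explored: float
    percent_immobile: float
    max_velocity: float
    fish_id: str = ""


def compute_velocity(traj: Trajectory3D) -> VelocitySeries:
    """Raw frame-to-frame speeds (no smoothing), converted cm -> mm/s."""
    steps = np.diff(traj.positions, axis=0)
    dist_cm = np.sqrt((steps**2).sum(axis=1))
    speeds = dist_cm * 10.0 / traj.frame_interval
    return VelocitySeries(speeds=speeds, frame_interval=traj.frame_interval)


def distance_traveled(traj: Trajectory3D) -> float:
    """Total path length in cm (sum of inter-frame Euclidean displacements)."""
    steps = np.diff(traj.positions, axis=0)
    return float(np.sqrt((steps**2).sum(axis=1)).sum())


def mean_bottom_distance(traj: Trajectory3D) -> float:
    """Time-average height above the tank floor, cm."""
    return float(traj.positions[:, 2].mean())


def mean_center_distance(traj: Trajectory3D, convention: str = "horizontal") -> float:
    """Time-average distance from the tank center, cm.

    ``convention="horizontal"`` (default) measures distance from the
    central vertical axis in the x-y plane, the usual thigmotaxis
    reading.  ``convention="3d"`` measures distance from the tank's 3D
    center point instead.
    """
    if convention == "horizontal":
        cx, cy = traj.geometry.horizontal_center
        d = np.hypot(traj.positions[:, 0] - cx, traj.positions[:, 1] - cy)
    elif convention == "3d":
        center = traj.geometry.extents / 2.0
        d = np.sqrt(((traj.positions - center) ** 2).sum(axis=1))
    else:
        raise ValueError(f"unknown center-distance convention {convention!r}")
    return float(d.mean())


def voxel_indices(traj: Trajectory3D) -> np.ndarray:
    """Flat voxel index of each frame on the geometry's grid.

    Cells are half-open [k*w/g, (k+1)*w/g) per axis with the last cell
    closed at the tank wall, so boundary positions always bin.
    """
    g = traj.geometry.grid_divisions_per_axis
    cell = traj.geometry.extents / g
    idx = np.floor(traj.positions / cell).astype(np.int64)
    np.clip(idx, 0, g - 1, out=idx)
    return (idx[:, 0] * g + idx[:, 1]) * g + idx[:, 2]


def percent_explored(traj: Trajectory3D) -> float:
    """Percentage of grid voxels visited at least once (0-100)."""
    visited = np.unique(voxel_indices(traj)).size
    return 100.0 * visited / traj.geometry.n_voxels


def detect_immobility_threshold(
    vel: VelocitySeries,
    default: float = DEFAULT_IMMOBILITY_THRESHOLD,
    grid_points: int = 512,
) -> ImmobilityThreshold:
    """Locate the break between the immobile and swimming speed modes.

    Kernel-smooths the histogram of log10(speed) and returns the speed at
    the deepest valley between the two dominant density modes.  When no
    two-mode structure exists (unimodal, near-constant, or all-zero
    speeds) the conventional default cut-off is returned with
    ``used_default=True``.
    """
    from scipy.signal import find_peaks
    from scipy.stats import gaussian_kde

    pos = vel.speeds[vel.speeds > 0]
    if pos.size < 10 or np.ptp(np.log10(pos)) < 1e-6:
        return ImmobilityThreshold(default, True, "too few distinct positive speeds")
    logs = np.log10(pos)
    try:
        kde = gaussian_kde(logs)
    except np.linalg.LinAlgError:
        return ImmobilityThreshold(default, True, "degenerate speed distribution")
    grid = np.linspace(logs.min() - 0.25, logs.max() + 0.25, grid_points)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=0.05 * dens.max())
    if peaks.size < 2:
        return ImmobilityThreshold(default, True, "speed distribution is unimodal")
    # two dominant modes = the two tallest prominent peaks, in grid order
    top2 = np.sort(peaks[np.argsort(dens[peaks])[-2:]])
    lo, hi = int(top2[0]), int(top2[1])
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    if dens[valley] > 0.9 * min(dens[lo], dens[hi]):
        return ImmobilityThreshold(default, True, "no clear valley between speed modes")
    return ImmobilityThreshold(float(10.0 ** grid[valley]), False, "")


def percent_immobile(
    vel: VelocitySeries, threshold: float = DEFAULT_IMMOBILITY_THRESHOLD
) -> float:
    """Percentage of steps strictly below the immobility cut-off (0-100)."""
    return 100.0 * float(np.count_nonzero(vel.speeds < threshold)) / vel.speeds.size


def max_velocity(vel: VelocitySeries) -> float:
    """Median of the top 5% of speeds — a robust maximum, mm/s.

    The top subset has ceil(0.05*n) elements so it is never empty; with an
    even subset the midpoint of the two central values is returned.
    Requires at least 20 samples.
    """
    n = vel.speeds.size
    if n < MIN_SPEED_SAMPLES:
        raise ValueError(
            f"max_velocity needs at least {MIN_SPEED_SAMPLES} speed samples, got {n}"
        )
    k = math.ceil(TOP_SPEED_FRACTION * n)
    top = np.partition(vel.speeds, n - k)[n - k :]
    return float(np.median(top))


def extract_profile(
    traj: Trajectory3D,
    immobility_threshold: float = DEFAULT_IMMOBILITY_THRESHOLD,
    center_convention: str = "horizontal",
) -> BehaviorProfile:
    """Compute all six behavioral measures of one trajectory.

    Pure function of its inputs; ``max_velocity`` is NaN (with a warning)
    when fewer than 20 inter-frame steps exist.
    """
    vel = compute_velocity(traj)
    if vel.speeds.size >= MIN_SPEED_SAMPLES:
        mv = max_velocity(vel)
    else:
        warnings.warn(
            f"trajectory {traj.fish_id or '<unnamed>'} has {vel.speeds.size} steps; "
            "max_velocity undefined (needs >= 20)",
            stacklevel=2,
        )
        mv = float("nan")
    return BehaviorProfile(
        bottom_distance=mean_bottom_distance(traj),
        center_distance=mean_center_distance(traj, convention=center_convention),
        distance_traveled=distance_traveled(traj),
        percent_explored=percent_explored(traj),
        percent_immobile=percent_immobile(vel, immobility_threshold),
        max_velocity=mv,
        fish_id=traj.fish_id,
    )


# ---------------------------------------------------------------------------
# file formats

TRAJECTORY_COLUMNS = ["time_s", "x_cm", "y_cm", "z_cm"]


def read_trajectory_csv(path, geometry: TankGeometry, fish_id: str = "") -> Trajectory3D:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {missing}")
    return Trajectory3D(
        times=df["time_s"].to_numpy(),
        positions=df[["x_cm", "y_cm", "z_cm"]].to_numpy(),
        geometry=geometry,
        fish_id=fish_id,
    )


def write_trajectory_csv(traj: Trajectory3D, path) -> None:
    pd.DataFrame(
        {
            "time_s": traj.times,
            "x_cm": traj.positions[:, 0],
            "y_cm": traj.positions[:, 1],
            "z_cm": traj.positions[:, 2],
        }
    ).to_csv(path, index=False)


def read_pose_csv(
    path, geometry: TankGeometry, body_point: str, fish_id: str = ""
) -> Trajectory3D:
    """Reduce a multi-keypoint pose file to the designated body point.

    Expects long-format columns time_s, point_name, x_cm, y_cm, z_cm.
    """
    df = pd.read_csv(path)
    needed = ["time_s", "point_name", "x_cm", "y_cm", "z_cm"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pose columns {missing}")
    sel = df[df["point_name"] == body_point].sort_values("time_s")
    if sel.empty:
        raise ValueError(
            f"{path}: body point {body_point!r} not found; "
            f"available: {sorted(df['point_name'].unique())}"
        )
    return Trajectory3D(
        times=sel["time_s"].to_numpy(),
        positions=sel[["x_cm", "y_cm", "z_cm"]].to_numpy(),
        geometry=geometry,
        fish_id=fish_id,
    )


def profiles_to_frame(profiles: list[BehaviorProfile]) -> pd.DataFrame:
    """Tidy one-row-per-fish table of behavioral measures."""
    return pd.DataFrame(
        [
            {
                "fish_id": p.fish_id,
                "bottom_distance": p.bottom_distance,
                "center_distance": p.center_distance,
                "distance_traveled": p.distance_traveled,
                "percent_explored": p.percent_explored,
                "percent_immobile": p.percent_immobile,
                "max_velocity": p.max_velocity,
            }
            for p in profiles
        ]
    )
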