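"""Synthetic zebrafish cohorts with known latent structure.

Every downstream stage of the pipeline — trajectory metrics, blank-
corrected respirometry, the boldness index, and the statistical battery —
is exercised against cohorts generated here, where the ground truth is
known by construction:

* each fish carries two latent standard-normal traits, a *metabolic
  trait* and a *boldness trait*, drawn jointly at a configurable
  correlation ``rho_true`` (the pace-of-life-syndrome link under test);
* the boldness trait drives swimming behavior through exactly two
  channels — preferred height in the water column and locomotor speed —
  so the boldness index's two ingredients (height above bottom, percent
  of the tank explored) are its direct readouts;
* the metabolic trait multiplies O2 consumption, which also scales
  allometrically with body mass (``mass ** mass_exponent``);
* a 16-h fasting manipulation scales consumption down by a fixed factor,
  either within fish (crossover respirometry design) or between groups
  (behavior design).

Movement is a persistent (autocorrelated) random walk with an
Ornstein–Uhlenbeck-style vertical attraction toward the preferred
height, gated by a two-state moving/frozen Markov chain, inside
reflecting tank walls.  All randomness is reproducible bit-exactly from
the configuration and a seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .respirometry import RespirometryRecord
from .trajectory import TankGeometry, Trajectory3D, write_trajectory_csv

__all__ = [
    "LatentTraits",
    "TrajectorySimParams",
    "RespirometrySimParams",
    "GroundTruth",
    "CohortConfig",
    "CohortTable",
    "simulate_trajectory",
    "simulate_respirometry",
    "generate_cohort",
    "make_scripted_trajectory",
    "write_cohort",
    "read_cohort",
    "cohort_config_from_dict",
]

# boldness -> behavior mapping gains (per SD of the latent trait)
BOLDNESS_HEIGHT_GAIN = 0.6   # logit shift of the preferred height fraction
BOLDNESS_SPEED_GAIN = 0.25   # log multiplier of locomotor speed

#: E|v| = 2*sigma*sqrt(2/pi) for an isotropic 3D normal velocity
_SPEED_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 / math.pi))

_SEED_MAX = 2**31 - 1


@dataclass
class LatentTraits:
    """Per-fish latent state the simulator conditions on."""

    fish_id: str
    metabolic_trait: float = 0.0
    boldness_trait: float = 0.0
    mass_g: float = 0.7
    strain: str = "TU"
    sex: str = "female"
    feed_state: str = "fed"

    def __post_init__(self) -> None:
        if not (self.mass_g > 0):
            raise ValueError(f"fish {self.fish_id}: mass must be positive")


@dataclass
class TrajectorySimParams:
    """Movement-model parameters for one simulated novel-tank trial.

    ``speed_scale`` (mm/s) sets the long-run mean swimming speed and
    ``preferred_height_fraction`` the resting depth preference; both are
    modulated upward by the fish's boldness trait.  The frame interval
    defaults to 1/30 s (a plain assumption about tracking cameras; the
    trial duration of 360 s is the standard 6-min novel-tank trial).
    """

    frame_interval: float = 1.0 / 30.0
    duration: float = 360.0
    speed_scale: float = 40.0
    velocity_persistence: float = 0.9
    depth_attraction_strength: float = 1.0
    preferred_height_fraction: float = 0.45
    immobility_onset_rate: float = 0.02
    immobility_offset_rate: float = 0.2
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "frame_interval",
            "duration",
            "speed_scale",
            "velocity_persistence",
            "depth_attraction_strength",
            "preferred_height_fraction",
            "immobility_onset_rate",
            "immobility_offset_rate",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"TrajectorySimParams.{name} must be finite, got {v!r}")
        if self.frame_interval <= 0:
            raise ValueError("TrajectorySimParams.frame_interval must be positive")
        if round(self.duration / self.frame_interval) < 1:
            raise ValueError("duration/frame_interval must yield at least 2 frames")
        if not (0.0 <= self.velocity_persistence < 1.0):
            raise ValueError("TrajectorySimParams.velocity_persistence must be in [0, 1)")
        if not (0.0 <= self.preferred_height_fraction <= 1.0):
            raise ValueError("TrajectorySimParams.preferred_height_fraction must be in [0, 1]")
        for name in ("speed_scale", "depth_attraction_strength",
                     "immobility_onset_rate", "immobility_offset_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"TrajectorySimParams.{name} must be >= 0")
        if self.depth_attraction_strength * self.frame_interval > 1.0:
            raise ValueError(
                "depth_attraction_strength * frame_interval must be <= 1 "
                "(discrete relaxation would overshoot)"
            )


@dataclass
class RespirometrySimParams:
    """Closed-chamber session parameters.

    ``rmr_per_gram`` is the consumption of a 1 g reference fish with an
    average metabolic trait, in mg O2/l per trial; consumption scales as
    ``mass ** mass_exponent`` and multiplicatively in
    ``exp(metabolic_trait_sd * metabolic_trait)``.  ``blank_drift`` is
    the fish-independent O2 change both chambers experience; reading
    noise is i.i.d. per O2 measurement.  ``session_sd`` is log-scale
    day-to-day biological variability of a fish's consumption (activity
    state differs between sessions even though the trait is stable); it
    is what keeps day-to-day repeatability below 1.
    """

    baseline_o2: float = 8.0
    rmr_per_gram: float = 2.0
    blank_drift: float = 0.1
    measurement_noise_sd: float = 0.1
    session_sd: float = 0.08
    duration: float = 30.0
    tank_volume: float = 500.0
    mass_exponent: float = 0.8
    metabolic_trait_sd: float = 0.2
    rng_seed: int = 0

    def validate(self) -> None:
        if not (self.baseline_o2 > 0):
            raise ValueError("RespirometrySimParams.baseline_o2 must be positive")
        if self.measurement_noise_sd < 0:
            raise ValueError("RespirometrySimParams.measurement_noise_sd must be >= 0")
        if self.session_sd < 0:
            raise ValueError("RespirometrySimParams.session_sd must be >= 0")
        if self.duration <= 0:
            raise ValueError("RespirometrySimParams.duration must be positive")


@dataclass
class GroundTruth:
    """Latent state recorded verbatim from the generating configuration."""

    traits: list[LatentTraits]
    rho_true: float
    fasting_rmr_multiplier: float
    mass_exponent: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.traits])

    def to_json(self, path) -> None:
        payload = {
            "rho_true": self.rho_true,
            "fasting_rmr_multiplier": self.fasting_rmr_multiplier,
            "mass_exponent": self.mass_exponent,
            "traits": [dataclasses.asdict(t) for t in self.traits],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            traits=[LatentTraits(**t) for t in payload["traits"]],
            rho_true=payload["rho_true"],
            fasting_rmr_multiplier=payload["fasting_rmr_multiplier"],
            mass_exponent=payload["mass_exponent"],
        )


@dataclass
class CohortConfig:
    """Design of one simulated cohort.

    ``n_per_cell`` may be an int (same n for every strain x sex cell) or
    a mapping ``{(strain, sex): n}``.  ``fasting`` selects the design:
    ``"none"`` (all fed; ``n_days`` consecutive respirometry sessions for
    repeatability), ``"crossover"`` (each fish measured fed and 16-h
    fasted two days apart, order randomized), or ``"between"`` (separate
    fed and unfed groups, the behavior-cohort design).
    """

    strains: tuple = ("TU", "WIK")
    sexes: tuple = ("female", "male")
    n_per_cell: int | dict = 30
    rho_true: float = 0.0
    fasting: str = "none"
    fasting_rmr_multiplier: float = 0.85
    n_unfed_per_cell: int | dict | None = None
    n_days: int = 2
    mass_median_g: dict = field(default_factory=lambda: {"female": 0.9, "male": 0.6})
    mass_sigma_log: float = 0.25
    geometry: TankGeometry = field(default_factory=TankGeometry)
    trajectory: TrajectorySimParams = field(default_factory=TrajectorySimParams)
    respirometry: RespirometrySimParams = field(default_factory=RespirometrySimParams)
    simulate_behavior: bool = True

    def cell_n(self, strain: str, sex: str, unfed: bool = False) -> int:
        spec = self.n_per_cell
        if unfed and self.n_unfed_per_cell is not None:
            spec = self.n_unfed_per_cell
        if isinstance(spec, dict):
            return int(spec[(strain, sex)])
        return int(spec)

    def validate(self) -> None:
        if not (-1.0 <= self.rho_true <= 1.0):
            raise ValueError("rho_true must be in [-1, 1]")
        if self.fasting not in ("none", "crossover", "between"):
            raise ValueError(f"unknown fasting design {self.fasting!r}")
        if not (0.0 < self.fasting_rmr_multiplier <= 1.0):
            raise ValueError("fasting_rmr_multiplier must be in (0, 1]")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for strain in self.strains:
            for sex in self.sexes:
                if self.cell_n(strain, sex) < 2:
                    raise ValueError(
                        f"cell ({strain}, {sex}) needs n >= 2 for downstream statistics"
                    )
        self.trajectory.validate()
        self.respirometry.validate()


@dataclass
class CohortTable:
    """Per-fish metadata joined to simulated raw data."""

    metadata: pd.DataFrame
    trajectories: dict
    respirometry: list

    @property
    def fish_ids(self) -> list[str]:
        return list(self.metadata["fish_id"])


# ---------------------------------------------------------------------------
# trajectory simulation


def effective_height_fraction(base: float, boldness: float) -> float:
    """Preferred height fraction, monotone increasing in boldness."""
    base = min(max(base, 1e-3), 1.0 - 1e-3)
    logit = math.log(base / (1.0 - base)) + BOLDNESS_HEIGHT_GAIN * boldness
    return 1.0 / (1.0 + math.exp(-logit))


def effective_speed(base: float, boldness: float) -> float:
    """Locomotor speed scale (mm/s), monotone increasing in boldness."""
    return base * math.exp(BOLDNESS_SPEED_GAIN * boldness)


def _fold(x: np.ndarray, extent: float) -> np.ndarray:
    """Reflect an unconstrained path into [0, extent] (tent map)."""
    r = np.mod(x, 2.0 * extent)
    return np.where(r > extent, 2.0 * extent - r, r)


def _moving_gate(n_steps: int, p_on: float, p_off: float, rng) -> np.ndarray:
    """Two-state moving(1)/frozen(0) Markov chain, started moving."""
    if p_on == 0.0:
        return np.ones(n_steps, dtype=float)
    u = rng.random(n_steps).tolist()
    out = np.empty(n_steps, dtype=float)
    state = 1
    for i in range(n_steps):
        if state == 1:
            if u[i] < p_on:
                state = 0
        else:
            if u[i] < p_off:
                state = 1
        out[i] = state
    return out


def simulate_trajectory(
    params: TrajectorySimParams,
    geometry: TankGeometry,
    traits: LatentTraits,
) -> Trajectory3D:
    """Simulate one novel-tank trial for one fish.

    The fish starts at the horizontal center of the tank at its preferred
    height ``z* = h_eff * height_z``.  Velocity follows a per-axis AR(1)
    process (persistence ``velocity_persistence``); the vertical position
    additionally relaxes toward z* at rate ``depth_attraction_strength``;
    a moving/frozen Markov chain gates all displacement; walls reflect.
    Identical (params, geometry, traits) give a bit-identical trajectory.
    """
    params.validate()
    dt = params.frame_interval
    n = int(round(params.duration / dt)) + 1

    h_eff = effective_height_fraction(params.preferred_height_fraction, traits.boldness_trait)
    speed_cm = effective_speed(params.speed_scale, traits.boldness_trait) / 10.0
    sigma = speed_cm * _SPEED_TO_SIGMA
    phi = params.velocity_persistence
    lam_dt = params.depth_attraction_strength * dt

    z_star = h_eff * geometry.height_z
    start = np.array([geometry.width_x / 2.0, geometry.depth_y / 2.0, z_star])

    rng = np.random.default_rng(params.rng_seed)
    p_on = 1.0 - math.exp(-params.immobility_onset_rate * dt)
    p_off = 1.0 - math.exp(-params.immobility_offset_rate * dt)
    moving = _moving_gate(n - 1, p_on, p_off, rng)

    v0 = rng.normal(0.0, 1.0, size=3) * sigma
    w = rng.normal(0.0, 1.0, size=(n - 1, 3)) * (sigma * math.sqrt(1.0 - phi * phi))
    v, _ = lfilter([1.0], [1.0, -phi], w, axis=0, zi=(phi * v0)[None, :])

    pos = np.empty((n, 3))
    pos[0] = start
    # x, y: gated random walk, reflected by folding the free path
    steps_xy = moving[:, None] * v[:, :2] * dt
    free_xy = start[:2] + np.cumsum(steps_xy, axis=0)
    pos[1:, 0] = _fold(free_xy[:, 0], geometry.width_x)
    pos[1:, 1] = _fold(free_xy[:, 1], geometry.depth_y)
    # z: AR(1) relaxation toward z* plus gated velocity input
    a = 1.0 - lam_dt
    u = lam_dt * z_star + moving * v[:, 2] * dt
    z_free, _ = lfilter([1.0], [1.0, -a], u, zi=np.array([a * z_star]))
    pos[1:, 2] = _fold(z_free, geometry.height_z)

    times = np.arange(n) * dt
    return Trajectory3D(times=times, positions=pos, geometry=geometry,
                        fish_id=traits.fish_id)


def make_scripted_trajectory(
    waypoints,
    frame_interval: float,
    geometry: TankGeometry,
    fish_id: str = "scripted",
) -> Trajectory3D:
    """Trajectory passing through exactly the given points, one per frame.

    Oracle-fixture builder: voxel counts, path length and per-step speeds
    of the result are hand-computable from the waypoint list.
    """
    pts = np.asarray(waypoints, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("waypoints must be an (n >= 2, 3) array of 3D points")
    inside = geometry.contains(pts)
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"waypoint {bad} lies outside the tank: {pts[bad]}")
    times = np.arange(pts.shape[0]) * float(frame_interval)
    return Trajectory3D(times=times, positions=pts, geometry=geometry, fish_id=fish_id)


# ---------------------------------------------------------------------------
# respirometry simulation


def true_consumption(
    params: RespirometrySimParams,
    traits: LatentTraits,
    feed_state: str = "fed",
    fasting_rmr_multiplier: float = 1.0,
) -> float:
    """Noise-free O2 consumption (mg O2/l per trial) for one session."""
    c = (
        params.rmr_per_gram
        * traits.mass_g ** params.mass_exponent
        * math.exp(params.metabolic_trait_sd * traits.metabolic_trait)
    )
    if feed_state == "unfed":
        c *= fasting_rmr_multiplier
    return c


def simulate_respirometry(
    params: RespirometrySimParams,
    traits: LatentTraits,
    session_day: int = 1,
    feed_state: str | None = None,
    fasting_rmr_multiplier: float = 1.0,
) -> RespirometryRecord:
    """Simulate one closed-chamber session.

    Fish-tank drop = true consumption + blank drift (+ reading noise);
    blank-tank drop = blank drift (+ independent reading noise).  A drop
    that would exhaust the chamber's O2 is flagged invalid (anoxia).
    """
    params.validate()
    state = traits.feed_state if feed_state is None else feed_state
    rng = np.random.default_rng(params.rng_seed)
    consumption = true_consumption(params, traits, state, fasting_rmr_multiplier)
    if params.session_sd > 0:
        consumption *= math.exp(params.session_sd * rng.standard_normal())
    eps = rng.normal(0.0, params.measurement_noise_sd, size=4) \
        if params.measurement_noise_sd > 0 else np.zeros(4)
    f1 = params.baseline_o2 + eps[0]
    f2 = params.baseline_o2 - consumption - params.blank_drift + eps[1]
    b1 = params.baseline_o2 + eps[2]
    b2 = params.baseline_o2 - params.blank_drift + eps[3]

    flagged, reason = False, ""
    if f2 <= 0 or b2 <= 0:
        flagged, reason = True, "anoxia: O2 drop exceeds chamber baseline"
        f2, b2 = max(f2, 0.0), max(b2, 0.0)

    return RespirometryRecord(
        fish_id=traits.fish_id,
        session_day=session_day,
        o2_fish_t1=f1,
        o2_fish_t2=f2,
        o2_blank_t1=b1,
        o2_blank_t2=b2,
        duration_min=params.duration,
        mass_g=traits.mass_g,
        feed_state=state,
        flagged_invalid=flagged,
        flag_reason=reason,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _draw_traits(config: CohortConfig, rng) -> list[LatentTraits]:
    traits: list[LatentTraits] = []
    rho = config.rho_true
    for strain in config.strains:
        for sex in config.sexes:
            cells = [("fed", config.cell_n(strain, sex))]
            if config.fasting == "between":
                cells.append(("unfed", config.cell_n(strain, sex, unfed=True)))
            for state, n in cells:
                median = config.mass_median_g.get(sex, 0.7)
                for i in range(n):
                    zm = rng.standard_normal()
                    e = rng.standard_normal()
                    zb = rho * zm + math.sqrt(max(0.0, 1.0 - rho * rho)) * e
                    mass = median * math.exp(rng.normal(0.0, config.mass_sigma_log))
                    suffix = "" if state == "fed" and config.fasting != "between" else f"_{state}"
                    traits.append(
                        LatentTraits(
                            fish_id=f"{strain}_{sex}{suffix}_{i:03d}",
                            metabolic_trait=zm,
                            boldness_trait=zb,
                            mass_g=mass,
                            strain=strain,
                            sex=sex,
                            feed_state=state,
                        )
                    )
    return traits


def generate_cohort(config: CohortConfig, seed: int) -> tuple[CohortTable, GroundTruth]:
    """Simulate a full cohort: latent traits, trajectories, respirometry.

    Deterministic given (config, seed).  When the crossover fasting
    design is selected, each fish is measured twice (days 1 and 3), once
    fed and once 16-h fasted, in randomized order; with ``n_days >= 2``
    and no fasting, consecutive-day sessions support repeatability
    analysis.  Ground truth is returned alongside the raw-data tables.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    traits = _draw_traits(config, rng)

    multiplier = config.fasting_rmr_multiplier if config.fasting != "none" else 1.0
    trajectories: dict[str, Trajectory3D] = {}
    records: list[RespirometryRecord] = []
    meta_rows = []

    for t in traits:
        if config.simulate_behavior:
            tp = dataclasses.replace(
                config.trajectory, rng_seed=int(rng.integers(0, _SEED_MAX))
            )
            trajectories[t.fish_id] = simulate_trajectory(tp, config.geometry, t)

        if config.fasting == "crossover":
            order = ["fed", "unfed"] if rng.random() < 0.5 else ["unfed", "fed"]
            days = [1, 3]
        elif config.fasting == "between":
            order, days = [t.feed_state], [1]
        else:
            order = ["fed"] * config.n_days
            days = list(range(1, config.n_days + 1))
        for day, state in zip(days, order):
            rp = dataclasses.replace(
                config.respirometry, rng_seed=int(rng.integers(0, _SEED_MAX))
            )
            records.append(
                simulate_respirometry(
                    rp, t, session_day=day, feed_state=state,
                    fasting_rmr_multiplier=multiplier,
                )
            )
        meta_rows.append(
            {
                "fish_id": t.fish_id,
                "strain": t.strain,
                "sex": t.sex,
                "feed_state": t.feed_state,
                "mass_g": t.mass_g,
                "session_day": 1,
            }
        )

    table = CohortTable(
        metadata=pd.DataFrame(meta_rows),
        trajectories=trajectories,
        respirometry=records,
    )
    truth = GroundTruth(
        traits=traits,
        rho_true=config.rho_true,
        fasting_rmr_multiplier=multiplier,
        mass_exponent=config.respirometry.mass_exponent,
    )
    return table, truth


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_cohort(table: CohortTable, truth: GroundTruth | None, outdir) -> None:
    """Write a cohort directory: metadata.csv, respirometry.csv,
    trajectories/<fish_id>.csv, cohort_info.json, ground_truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.metadata.to_csv(out / "metadata.csv", index=False)

    rows = []
    for r in table.respirometry:
        rows.append(
            {
                "fish_id": r.fish_id,
                "session_day": r.session_day,
                "o2_fish_t1": r.o2_fish_t1,
                "o2_fish_t2": r.o2_fish_t2,
                "o2_blank_t1": r.o2_blank_t1,
                "o2_blank_t2": r.o2_blank_t2,
                "duration_min": r.duration_min,
                "mass_g": r.mass_g,
                "feed_state": r.feed_state,
            }
        )
    pd.DataFrame(rows).to_csv(out / "respirometry.csv", index=False)

    if table.trajectories:
        tdir = out / "trajectories"
        tdir.mkdir(exist_ok=True)
        geom = next(iter(table.trajectories.values())).geometry
        for fid, traj in table.trajectories.items():
            write_trajectory_csv(traj, tdir / f"{fid}.csv")
    else:
        geom = TankGeometry()
    info = {
        "width_x": geom.width_x,
        "depth_y": geom.depth_y,
        "height_z": geom.height_z,
        "grid_divisions_per_axis": geom.grid_divisions_per_axis,
    }
    (out / "cohort_info.json").write_text(json.dumps(info, indent=1, sort_keys=True))
    if truth is not None:
        truth.to_json(out / "ground_truth.json")


def read_cohort(indir) -> CohortTable:
    """Read a cohort directory written by :func:`write_cohort`."""
    from .respirometry import read_respirometry_csv
    from .trajectory import read_trajectory_csv

    ind = Path(indir)
    metadata = pd.read_csv(ind / "metadata.csv")
    info_path = ind / "cohort_info.json"
    if info_path.exists():
        geom = TankGeometry(**json.loads(info_path.read_text()))
    else:
        geom = TankGeometry()
    records = read_respirometry_csv(ind / "respirometry.csv")
    trajectories = {}
    tdir = ind / "trajectories"
    if tdir.is_dir():
        for path in sorted(tdir.glob("*.csv")):
            fid = path.stem
            trajectories[fid] = read_trajectory_csv(path, geom, fish_id=fid)
    return CohortTable(metadata=metadata, trajectories=trajectories, respirometry=records)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a plain (YAML/JSON-loaded) mapping."""
    d = dict(d)
    if "geometry" in d:
        d["geometry"] = TankGeometry(**d["geometry"])
    if "trajectory" in d:
        d["trajectory"] = TrajectorySimParams(**d["trajectory"])
    if "respirometry" in d:
        d["respirometry"] = RespirometrySimParams(**d["respirometry"])
    for key in ("strains", "sexes"):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("n_per_cell", "n_unfed_per_cell"):
        if isinstance(d.get(key), dict):
            d[key] = {
                (k.split(":")[0], k.split(":")[1]): v for k, v in d[key].items()
            }
    config = CohortConfig(**d)
    config.validate()
    return config
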