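"""Closed-chamber respirometry: blank-corrected O2 consumption and RMR.

A fish swims for 30 min in a sealed 500 ml chamber while dissolved O2
(mg O2/l) is read at the start (t1) and end (t2) of the trial.  A
fish-free "blank" chamber run in parallel captures O2 drift from
degassing and temperature, which is subtracted:

    o2_consumed = (o2_fish_t1 - o2_fish_t2) - (o2_blank_t1 - o2_blank_t2)

Routine metabolic rate (RMR) is consumption normalized by body mass,
mg O2/l per g of fish per trial.  Records with non-positive consumption
fail QC (a live fish must consume oxygen over 30 min; negatives indicate
data-entry or instrument error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RespirometryRecord",
    "MetabolicResult",
    "compute_o2_consumed",
    "compute_rmr",
    "pair_sessions",
    "read_respirometry_csv",
    "write_results_csv",
    "results_to_frame",
]

RESPIROMETRY_COLUMNS = [
    "fish_id",
    "session_day",
    "o2_fish_t1",
    "o2_fish_t2",
    "o2_blank_t1",
    "o2_blank_t2",
    "duration_min",
    "mass_g",
]


@dataclass
class RespirometryRecord:
    """Paired fish/blank O2 readings for one fish on one session day."""

    fish_id: str
    session_day: int
    o2_fish_t1: float
    o2_fish_t2: float
    o2_blank_t1: float
    o2_blank_t2: float
    duration_min: float = 30.0
    mass_g: float = float("nan")
    feed_state: str = "fed"
    flagged_invalid: bool = False
    flag_reason: str = ""

    def __post_init__(self) -> None:
        readings = (self.o2_fish_t1, self.o2_fish_t2, self.o2_blank_t1, self.o2_blank_t2)
        if any(not math.isfinite(v) for v in readings):
            # missing blank or fish reading: the correction cannot be formed
            self.flagged_invalid = True
            if not self.flag_reason:
                self.flag_reason = "missing O2 reading"
        elif any(v < 0 for v in readings):
            raise ValueError(f"fish {self.fish_id}: O2 readings must be >= 0")
        if self.duration_min <= 0:
            raise ValueError(f"fish {self.fish_id}: duration must be positive")


@dataclass
class MetabolicResult:
    """Blank-corrected consumption and mass-normalized RMR with QC."""

    fish_id: str
    session_day: int
    o2_consumed: float
    rmr: float
    qc_pass: bool
    qc_reason: str = ""
    mass_g: float = float("nan")
    feed_state: str = "fed"


def compute_o2_consumed(record: RespirometryRecord) -> float:
    """Blank-corrected O2 drop over the trial, mg O2/l.

    Linear in the four readings with coefficients (+1, -1, -1, +1); any
    drift common to fish and blank chambers cancels identically.
    """
    return (record.o2_fish_t1 - record.o2_fish_t2) - (
        record.o2_blank_t1 - record.o2_blank_t2
    )


def compute_rmr(record: RespirometryRecord, absolute_mg: bool = False,
                volume_ml: float = 500.0) -> MetabolicResult:
    """Mass-normalized routine metabolic rate for one session.

    Reported per trial (no per-hour rescaling) in mg O2/l/g, matching the
    convention of equal-duration trials in equal-volume chambers.  With
    ``absolute_mg=True`` consumption is instead scaled by the chamber
    volume to absolute mg O2 before normalization.
    """
    if not (record.mass_g > 0):
        raise ValueError(f"fish {record.fish_id}: mass must be positive to compute RMR")
    if record.flagged_invalid:
        return MetabolicResult(
            fish_id=record.fish_id,
            session_day=record.session_day,
            o2_consumed=float("nan"),
            rmr=float("nan"),
            qc_pass=False,
            qc_reason=record.flag_reason or "record flagged invalid",
            mass_g=record.mass_g,
            feed_state=record.feed_state,
        )
    consumed = compute_o2_consumed(record)
    if absolute_mg:
        consumed = consumed * volume_ml / 1000.0
    qc_pass = consumed > 0
    reason = "" if qc_pass else (
        "negative consumption" if consumed < 0 else "zero consumption"
    )
    return MetabolicResult(
        fish_id=record.fish_id,
        session_day=record.session_day,
        o2_consumed=consumed,
        rmr=consumed / record.mass_g if qc_pass else float("nan"),
        qc_pass=qc_pass,
        qc_reason=reason,
        mass_g=record.mass_g,
        feed_state=record.feed_state,
    )


def pair_sessions(
    results: list[MetabolicResult], day1: int = 1, day2: int = 2
) -> tuple[pd.DataFrame, list[str]]:
    """Join two measurement days per fish for repeatability analysis.

    Returns (pairs, dropped): ``pairs`` has one row per fish with
    QC-passing results on both days (columns fish_id, o2_consumed_day1/2,
    rmr_day1/2), ordered by fish_id; ``dropped`` names fish lacking a
    usable result on either day.  Duplicate (fish, day) results are
    rejected.
    """
    seen: dict[tuple[str, int], MetabolicResult] = {}
    for r in results:
        key = (r.fish_id, r.session_day)
        if key in seen:
            raise ValueError(f"duplicate result for fish {r.fish_id} day {r.session_day}")
        seen[key] = r
    fish_ids = sorted({fid for fid, _ in seen})
    rows, dropped = [], []
    for fid in fish_ids:
        r1, r2 = seen.get((fid, day1)), seen.get((fid, day2))
        if r1 is None or r2 is None or not (r1.qc_pass and r2.qc_pass):
            dropped.append(fid)
            continue
        rows.append(
            {
                "fish_id": fid,
                "o2_consumed_day1": r1.o2_consumed,
                "o2_consumed_day2": r2.o2_consumed,
                "rmr_day1": r1.rmr,
                "rmr_day2": r2.rmr,
            }
        )
    cols = ["fish_id", "o2_consumed_day1", "o2_consumed_day2", "rmr_day1", "rmr_day2"]
    return pd.DataFrame(rows, columns=cols), dropped


def read_respirometry_csv(path) -> list[RespirometryRecord]:
    df = pd.read_csv(path)
    missing = [c for c in RESPIROMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing respirometry columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            RespirometryRecord(
                fish_id=str(row.fish_id),
                session_day=int(row.session_day),
                o2_fish_t1=float(row.o2_fish_t1),
                o2_fish_t2=float(row.o2_fish_t2),
                o2_blank_t1=float(row.o2_blank_t1),
                o2_blank_t2=float(row.o2_blank_t2),
                duration_min=float(row.duration_min),
                mass_g=float(row.mass_g),
                feed_state=str(getattr(row, "feed_state", "fed")),
            )
        )
    return records


def results_to_frame(results: list[MetabolicResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fish_id": r.fish_id,
                "session_day": r.session_day,
                "o2_consumed": r.o2_consumed,
                "rmr": r.rmr,
                "qc_pass": r.qc_pass,
                "qc_reason": r.qc_reason,
                "mass_g": r.mass_g,
                "feed_state": r.feed_state,
            }
            for r in results
        ]
    )


def write_results_csv(results: list[MetabolicResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)
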