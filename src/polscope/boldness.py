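"""Composite boldness index from within-group z-scores.

Boldness in the novel tank is scored by combining the two measures that
best separate bold from shy fish: the percentage of the tank explored
and the mean height above the bottom.  Each is z-scored *within* its
sex x strain group (sample SD, n-1 denominator) so that strains and
sexes with different baselines contribute on a common scale, and the
index is their sum.  By construction every group's index has mean 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["zscore_within_groups", "boldness_index", "BOLDNESS_METRICS"]

#: the two behavioral ingredients of the index
BOLDNESS_METRICS = ("percent_explored", "bottom_distance")


def zscore_within_groups(values, groups) -> np.ndarray:
    """z-score values within groups using the sample SD (ddof=1).

    ``groups`` is a same-length sequence of hashable group keys (e.g.
    (sex, strain) tuples).  Groups of fewer than 2 fish or with zero
    variance are rejected by name — a z-score is undefined there.
    Output order matches input order.
    """
    values = np.asarray(values, dtype=float)
    keys = pd.Series(list(groups))
    if len(keys) != values.size:
        raise ValueError("values and groups must have equal length")
    out = np.empty_like(values)
    for key, idx in keys.groupby(keys).groups.items():
        idx = np.asarray(idx)
        v = values[idx]
        if v.size < 2:
            raise ValueError(f"group {key!r} has fewer than 2 fish; z-score undefined")
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"group {key!r} has zero variance; z-score undefined")
        out[idx] = (v - v.mean()) / sd
    return out


def boldness_index(
    metrics: pd.DataFrame,
    group_cols: tuple = ("sex", "strain"),
    explored_col: str = "percent_explored",
    bottom_col: str = "bottom_distance",
) -> pd.DataFrame:
    """Append z-score columns and the boldness index to a metrics table.

    Returns a copy of ``metrics`` with three added columns:
    ``z_percent_explored``, ``z_bottom_distance`` and ``boldness_index``
    (their sum).  Rows are untouched otherwise; edits to one sex x strain
    group can never change another group's scores.
    """
    for col in (*group_cols, explored_col, bottom_col):
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks required column {col!r}")
    keys = list(map(tuple, metrics[list(group_cols)].to_numpy()))
    out = metrics.copy()
    out["z_percent_explored"] = zscore_within_groups(metrics[explored_col], keys)
    out["z_bottom_distance"] = zscore_within_groups(metrics[bottom_col], keys)
    out["boldness_index"] = out["z_percent_explored"] + out["z_bottom_distance"]
    return out
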