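"""Independent naive-loop oracles for the behavioral metrics.

Deliberately dumb pure-Python implementations, kept free of any code
shared with the package so they can serve as an independent check.
"""

from __future__ import annotations

import math


def naive_speeds(times, positions):
    """Per-step speeds in mm/s by explicit per-step distance."""
    out = []
    for i in range(len(times) - 1):
        d = math.sqrt(
            sum((positions[i + 1][k] - positions[i][k]) ** 2 for k in range(3))
        )
        out.append(d * 10.0 / (times[i + 1] - times[i]))
    return out


def naive_distance(positions):
    total = 0.0
    for i in range(len(positions) - 1):
        total += math.sqrt(
            sum((positions[i + 1][k] - positions[i][k]) ** 2 for k in range(3))
        )
    return total


def naive_bottom_distance(positions):
    return sum(p[2] for p in positions) / len(positions)


def naive_center_distance(positions, width_x, depth_y):
    cx, cy = width_x / 2.0, depth_y / 2.0
    return sum(
        math.hypot(p[0] - cx, p[1] - cy) for p in positions
    ) / len(positions)


def naive_percent_explored(positions, extents, grid):
    """Exact voxel-set counting with half-open cells, last cell closed."""
    visited = set()
    for p in positions:
        idx = []
        for k in range(3):
            j = int(p[k] // (extents[k] / grid))
            if j >= grid:
                j = grid - 1
            idx.append(j)
        visited.add(tuple(idx))
    return 100.0 * len(visited) / grid**3


def naive_percent_immobile(speeds, threshold):
    return 100.0 * sum(1 for s in speeds if s < threshold) / len(speeds)


def naive_max_velocity(speeds):
    """Median of the ceil(0.05 n) largest speeds."""
    n = len(speeds)
    k = math.ceil(0.05 * n)
    top = sorted(speeds)[n - k :]
    m = len(top)
    if m % 2 == 1:
        return top[m // 2]
    return 0.5 * (top[m // 2 - 1] + top[m // 2])


def naive_anova_ss_balanced(y, a, b):
    """Textbook sums of squares for a balanced 2x2 design.

    Returns (ss_a, ss_b, ss_ab, ss_error, ss_total).
    """
    n = len(y)
    grand = sum(y) / n
    levels_a = sorted(set(a))
    levels_b = sorted(set(b))

    def mean_where(pred):
        vals = [y[i] for i in range(n) if pred(i)]
        return sum(vals) / len(vals), len(vals)

    ss_a = sum(
        cnt * (m - grand) ** 2
        for m, cnt in (mean_where(lambda i, la=la: a[i] == la) for la in levels_a)
    )
    ss_b = sum(
        cnt * (m - grand) ** 2
        for m, cnt in (mean_where(lambda i, lb=lb: b[i] == lb) for lb in levels_b)
    )
    ss_cells = 0.0
    ss_error = 0.0
    for la in levels_a:
        for lb in levels_b:
            m, cnt = mean_where(lambda i, la=la, lb=lb: a[i] == la and b[i] == lb)
            ss_cells += cnt * (m - grand) ** 2
            ss_error += sum(
                (y[i] - m) ** 2
                for i in range(n)
                if a[i] == la and b[i] == lb
            )
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = sum((v - grand) ** 2 for v in y)
    return ss_a, ss_b, ss_ab, ss_error, ss_total


def exact_wilcoxon_signed_rank_p(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Assumes no zero differences and no tied absolute values.
    p = min(1, 2 * min(P(W <= w), P(W >= w))) for the observed W+ = sum of
    ranks of positive differences, matching the exact-distribution
    convention of standard implementations.
    """
    n = len(diffs)
    ranks = {}
    for rank, idx in enumerate(
        sorted(range(n), key=lambda i: abs(diffs[i])), start=1
    ):
        ranks[idx] = rank
    w_obs = sum(ranks[i] for i in range(n) if diffs[i] > 0)
    ws = []
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        ws.append(w)
    total = len(ws)
    p_le = sum(1 for w in ws if w <= w_obs) / total
    p_ge = sum(1 for w in ws if w >= w_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def exact_mannwhitney_one_sided_p(x, y):
    """One-sided (less) exact Mann–Whitney p by enumerating all labelings."""
    from itertools import combinations

    pooled = list(x) + list(y)
    n1 = len(x)
    idx = range(len(pooled))

    def u_stat(ix):
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in idx if i not in set(ix)]
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    us = [u_stat(ix) for ix in combinations(idx, n1)]
    return sum(1 for u in us if u <= u_obs) / len(us)
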