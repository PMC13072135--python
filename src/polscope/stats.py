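"""The study's statistical battery.

* Correlations gated by Shapiro–Wilk normality: Pearson's r when both
  variables look normal at alpha = 0.05, Spearman's rho otherwise.
* Repeatability as the one-way random-effects single-measure intraclass
  correlation (ICC) across two sessions, with a subject-level percentile
  bootstrap 95% CI.
* A 2x2 factorial permutation ANOVA: observed F per term from a fixed-
  effects two-way ANOVA with interaction (Type II sums of squares, so
  unbalanced cells are handled), null distribution from wholesale
  permutation of the response vector, p-values with +1 smoothing, and
  eta-squared from the observed decomposition.
* Two-group comparisons gated the same way: Welch's t or Mann–Whitney U
  (independent), paired t or Wilcoxon signed-rank (paired), with
  pooled-SD Cohen's d for independent designs.
* Effect-size labels on the conventional bands
  (small 0.01 < eta2 < 0.06, 0.2 < d < 0.5; medium 0.06 <= eta2 < 0.14,
  0.5 <= d < 0.8; large eta2 >= 0.14, d >= 0.8).

All resampling is reproducible bit-exactly from (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ICCResult",
    "PermAnovaTerm",
    "PermAnovaResult",
    "TwoGroupResult",
    "EffectSizeClass",
    "normality_test",
    "correlation_auto",
    "icc_oneway",
    "perm_anova_2x2",
    "two_group_test",
    "cohen_d_pooled",
    "classify_effect",
    "benjamini_hochberg",
]

ALPHA_DEFAULT = 0.05

#: below these per-group sizes, rank tests use exact null distributions
EXACT_RANK_TEST_MAX_N = 25


# ---------------------------------------------------------------------------
# normality and correlations


def normality_test(x) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, p).  Requires 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample (zero variance)")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float
    n: int
    gate_report: dict = field(default_factory=dict)


def correlation_auto(x, y, alpha: float = ALPHA_DEFAULT) -> CorrelationResult:
    """Pearson's r when both variables pass the normality gate, else
    Spearman's rho (tie-corrected p via the t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError(f"correlation needs n >= 4 pairs, got {x.size}")
    gate = {}
    for name, v in (("x", x), ("y", y)):
        w, p = normality_test(v)
        gate[name] = {"W": w, "p": p, "normal": p >= alpha}
    if gate["x"]["normal"] and gate["y"]["normal"]:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method=method, coefficient=float(r), p_value=float(p),
                             n=int(x.size), gate_report=gate)


# ---------------------------------------------------------------------------
# repeatability (one-way random-effects single-measure ICC)


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_subjects: int
    flagged: bool = False
    note: str = ""


def _icc1_pairs(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """ICC(1) for two sessions; broadcasts over leading axes.

    From the one-way ANOVA decomposition with k = 2 raters/sessions:
    ICC = (MSB - MSW) / (MSB + (k-1) MSW).
    """
    y = np.stack([d1, d2], axis=-1)
    n = y.shape[-2]
    row = y.mean(axis=-1)
    grand = row.mean(axis=-1, keepdims=True)
    msb = 2.0 * ((row - grand) ** 2).sum(axis=-1) / (n - 1)
    msw = ((y - row[..., None]) ** 2).sum(axis=(-1, -2)) / n
    denom = msb + msw
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (msb - msw) / denom, np.nan)


def icc_oneway(day1, day2, n_boot: int = 1000, seed: int | None = None) -> ICCResult:
    """Repeatability of a trait measured on two sessions.

    Point estimate is ICC(1) (one-way random effects, single measure);
    the 95% CI is the percentile interval over ``n_boot`` resamples of
    subjects with replacement.  A degenerate between-subject variance
    can push the estimate to or below 0; it is reported as computed and
    flagged, not truncated.
    """
    d1 = np.asarray(day1, dtype=float)
    d2 = np.asarray(day2, dtype=float)
    if d1.size != d2.size:
        raise ValueError("day1 and day2 must have equal length")
    n = d1.size
    if n < 5:
        raise ValueError(f"ICC needs at least 5 paired subjects, got {n}")
    est = float(_icc1_pairs(d1, d2))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = _icc1_pairs(d1[idx], d2[idx])
    boots = boots[np.isfinite(boots)]
    if boots.size == 0 or not math.isfinite(est):
        return ICCResult(est, float("nan"), float("nan"), n_boot, n,
                         flagged=True, note="degenerate variance decomposition")
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ICCResult(est, float(lo), float(hi), n_boot, n,
                     flagged=est <= 0, note="non-positive estimate" if est <= 0 else "")


# ---------------------------------------------------------------------------
# 2x2 permutation ANOVA


@dataclass
class PermAnovaTerm:
    F: float
    p_value: float
    eta_squared: float
    df: int


@dataclass
class PermAnovaResult:
    terms: dict  # name -> PermAnovaTerm
    n_perm: int
    seed: int | None
    n_obs: int
    df_error: int


def _rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y's columns after projection onto Q."""
    return (Y * Y).sum(axis=0) - ((Q.T @ Y) ** 2).sum(axis=0)


def perm_anova_2x2(
    y,
    a,
    b,
    n_perm: int = 10000,
    seed: int | None = None,
    factor_names: tuple = ("A", "B"),
) -> PermAnovaResult:
    """Permutation test of a 2x2 factorial design.

    Observed F statistics come from the classical two-way fixed-effects
    ANOVA with interaction using Type II sums of squares (each main
    effect adjusted for the other; the interaction adjusted for both),
    which reduces to Type I on balanced data.  The null distribution is
    built by permuting the response vector wholesale ``n_perm`` times;
    p = (1 + #{F* >= F_obs}) / (1 + n_perm), exact under the global
    null.  eta-squared is SS_term / SS_total from the observed data.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    if not (y.size == a.size == b.size):
        raise ValueError("y, a, b must have equal length")
    lev_a, lev_b = np.unique(a), np.unique(b)
    if lev_a.size != 2 or lev_b.size != 2:
        raise ValueError("perm_anova_2x2 needs exactly two levels per factor")
    for la in lev_a:
        for lb in lev_b:
            if np.count_nonzero((a == la) & (b == lb)) < 2:
                raise ValueError(f"cell ({la!r}, {lb!r}) has fewer than 2 observations")
    n = y.size
    A = np.where(a == lev_a[1], 1.0, -1.0)
    B = np.where(b == lev_b[1], 1.0, -1.0)
    ones = np.ones(n)
    designs = {
        "1+A": np.column_stack([ones, A]),
        "1+B": np.column_stack([ones, B]),
        "1+A+B": np.column_stack([ones, A, B]),
        "full": np.column_stack([ones, A, B, A * B]),
    }
    Qs = {k: np.linalg.qr(X, mode="reduced")[0] for k, X in designs.items()}

    name_a, name_b = factor_names
    term_names = [name_a, name_b, f"{name_a}:{name_b}"]
    ss_total = float(((y - y.mean()) ** 2).sum())
    df_error = n - 4

    def term_ss(Y: np.ndarray) -> dict:
        r_a = _rss(Qs["1+A"], Y)
        r_b = _rss(Qs["1+B"], Y)
        r_ab = _rss(Qs["1+A+B"], Y)
        r_full = _rss(Qs["full"], Y)
        return {
            name_a: r_b - r_ab,
            name_b: r_a - r_ab,
            f"{name_a}:{name_b}": r_ab - r_full,
            "_error": r_full,
        }

    Y_obs = y[:, None]
    ss_obs = {k: float(v[0]) for k, v in term_ss(Y_obs).items()}

    if ss_total == 0.0:
        terms = {t: PermAnovaTerm(0.0, 1.0, 0.0, 1) for t in term_names}
        return PermAnovaResult(terms, n_perm, seed, n, df_error)

    mse_obs = ss_obs["_error"] / df_error
    f_obs = {
        t: (ss_obs[t] / 1.0) / mse_obs if mse_obs > 0 else math.inf
        for t in term_names
    }

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perm_idx].T  # (n, n_perm)
    ss_perm = term_ss(Yp)
    mse_perm = ss_perm["_error"] / df_error
    terms = {}
    for t in term_names:
        with np.errstate(invalid="ignore", divide="ignore"):
            f_perm = np.where(mse_perm > 0, ss_perm[t] / mse_perm, np.inf)
        count = int(np.count_nonzero(f_perm >= f_obs[t]))
        p = (1 + count) / (1 + n_perm)
        terms[t] = PermAnovaTerm(
            F=f_obs[t], p_value=p, eta_squared=max(ss_obs[t], 0.0) / ss_total, df=1
        )
    return PermAnovaResult(terms, n_perm, seed, n, df_error)


# ---------------------------------------------------------------------------
# two-group comparisons


@dataclass
class TwoGroupResult:
    method: str  # welch_t | mann_whitney | paired_t | wilcoxon_paired | none
    statistic: float
    p_value: float
    cohen_d: float | None
    n1: int
    n2: int
    gate_report: dict = field(default_factory=dict)
    note: str = ""


def cohen_d_pooled(y1, y2) -> float:
    """Classical pooled-SD Cohen's d for two independent samples."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n1, n2 = y1.size, y2.size
    sp2 = ((n1 - 1) * y1.var(ddof=1) + (n2 - 1) * y2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0 if y1.mean() == y2.mean() else math.inf
    return float((y1.mean() - y2.mean()) / math.sqrt(sp2))


def _rank_method(n1: int, n2: int, *values) -> str:
    """Exact null distribution for small samples without ties, else the
    tie/continuity-corrected normal approximation."""
    allv = np.concatenate([np.asarray(v, dtype=float) for v in values])
    has_ties = np.unique(allv).size < allv.size
    small = max(n1, n2) <= EXACT_RANK_TEST_MAX_N
    return "exact" if (small and not has_ties) else "asymptotic"


def two_group_test(
    y1,
    y2,
    paired: bool = False,
    alpha: float = ALPHA_DEFAULT,
    alternative: str = "two-sided",
    method: str = "auto",
) -> TwoGroupResult:
    """Normality-gated two-group comparison.

    Independent samples: Welch's t when both groups pass the Shapiro–Wilk
    gate, Mann–Whitney U otherwise; pooled-SD Cohen's d attached.
    Paired samples: the gate is applied to the per-subject differences;
    paired t when they look normal, Wilcoxon signed-rank otherwise.
    All-zero paired differences admit no test and are flagged.

    ``method`` overrides the gate: one of ``auto`` (default),
    ``welch_t``/``mann_whitney`` (independent), or
    ``paired_t``/``wilcoxon_paired`` (paired).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    gate: dict = {}
    if paired:
        if y1.size != y2.size:
            raise ValueError("paired samples must have equal length")
        if y1.size < 5:
            raise ValueError(f"paired comparison needs n >= 5 pairs, got {y1.size}")
        diff = y1 - y2
        if np.all(diff == 0):
            return TwoGroupResult("none", float("nan"), float("nan"), None,
                                  y1.size, y2.size, {},
                                  note="all paired differences are zero; no test")
        w, p = normality_test(diff)
        gate["differences"] = {"W": w, "p": p, "normal": p >= alpha}
        use_t = gate["differences"]["normal"] if method == "auto" else method == "paired_t"
        if method not in ("auto", "paired_t", "wilcoxon_paired"):
            raise ValueError(f"invalid paired method {method!r}")
        if use_t:
            stat, pval = sps.ttest_rel(y1, y2, alternative=alternative)
            method = "paired_t"
        else:
            nz = diff[diff != 0]
            mode = _rank_method(nz.size, 0, np.abs(nz))
            stat, pval = sps.wilcoxon(y1, y2, alternative=alternative, method=mode)
            method = "wilcoxon_paired"
        return TwoGroupResult(method, float(stat), float(pval), None,
                              y1.size, y2.size, gate)

    if min(y1.size, y2.size) < 3:
        raise ValueError("independent comparison needs n >= 3 per group")
    for name, v in (("group1", y1), ("group2", y2)):
        if np.ptp(v) == 0:
            gate[name] = {"W": float("nan"), "p": 0.0, "normal": False}
        else:
            w, p = normality_test(v)
            gate[name] = {"W": w, "p": p, "normal": p >= alpha}
    d = cohen_d_pooled(y1, y2)
    if method not in ("auto", "welch_t", "mann_whitney"):
        raise ValueError(f"invalid independent-samples method {method!r}")
    use_t = (
        gate["group1"]["normal"] and gate["group2"]["normal"]
        if method == "auto"
        else method == "welch_t"
    )
    if use_t:
        stat, pval = sps.ttest_ind(y1, y2, equal_var=False, alternative=alternative)
        method = "welch_t"
    else:
        mode = _rank_method(y1.size, y2.size, y1, y2)
        stat, pval = sps.mannwhitneyu(y1, y2, alternative=alternative, method=mode)
        method = "mann_whitney"
    return TwoGroupResult(method, float(stat), float(pval), d, y1.size, y2.size, gate)


# ---------------------------------------------------------------------------
# effect sizes


@dataclass
class EffectSizeClass:
    measure: str  # "eta_squared" | "cohen_d"
    value: float
    label: str  # negligible | small | medium | large


def classify_effect(measure: str, value: float) -> EffectSizeClass:
    """Label an effect size on the conventional bands.

    eta2: small 0.01 < eta2 < 0.06, medium 0.06 <= eta2 < 0.14, large
    eta2 >= 0.14.  d (absolute value): small 0.2 < d < 0.5, medium
    0.5 <= d < 0.8, large d >= 0.8.  Values below the small band are
    negligible; boundary values follow the inequalities exactly.
    """
    if measure == "eta_squared":
        if not (0.0 <= value):
            raise ValueError("eta_squared must be >= 0")
        if value > 1.0:
            raise ValueError(f"eta_squared cannot exceed 1, got {value}")
        v = value
        if v >= 0.14:
            label = "large"
        elif v >= 0.06:
            label = "medium"
        elif v > 0.01:
            label = "small"
        else:
            label = "negligible"
    elif measure == "cohen_d":
        v = abs(value)
        if v >= 0.8:
            label = "large"
        elif v >= 0.5:
            label = "medium"
        elif v > 0.2:
            label = "small"
        else:
            label = "negligible"
    else:
        raise ValueError(f"unknown effect-size measure {measure!r}")
    return EffectSizeClass(measure=measure, value=float(value), label=label)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional report column)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
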