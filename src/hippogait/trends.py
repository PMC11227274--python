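"""Cross-trial statistics: regressions on duty factor, paired fore/hind
comparison, and the duty-factor frequency distribution.

Stride parameters vary systematically with duty factor (DF), which is
roughly inversely proportional to speed: stride frequency falls linearly
with DF, while stance and swing durations follow power laws.  Fore- and
hindlimb DFs are compared per trial with a Wilcoxon matched-pairs
signed-rank test.  The distribution of trial-mean DFs is binned to expose
clustering (e.g. separate walking and running clusters with an empty range
between them).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LinearFit",
    "PowerFit",
    "PairedTestResult",
    "DFHistogram",
    "fit_linear",
    "fit_power",
    "fit_power_loglog",
    "paired_sign_rank",
    "df_distribution",
]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares fit y = slope*x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope
    n: int


@dataclass(frozen=True)
class PowerFit:
    """Power-law fit y = a * x**b (r_squared on the linear scale)."""

    a: float
    b: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon matched-pairs signed-rank test result (two-tailed)."""

    statistic: float  # W+ (sum of ranks of positive differences a-b)
    p_value: float
    n: int  # pairs entering the ranking (after zero handling)
    median_a: float
    median_b: float
    median_difference: float
    method: str  # "exact" | "normal-approx"


@dataclass(frozen=True)
class DFHistogram:
    """Fixed-width histogram of trial-mean duty factors over [0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    empty_range: tuple[float, float] | None  # longest interior run of empty bins


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_linear(x, y) -> LinearFit:
    """OLS fit of y on x with the slope's two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("fit_linear needs at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fit_linear requires finite values")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope is not identifiable")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    r2 = _r_squared(y, fitted)
    p = 1.0 if math.isnan(res.pvalue) else float(res.pvalue)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p_value=p,
        n=int(x.size),
    )


def fit_power_loglog(x, y) -> PowerFit:
    """Power-law fit via OLS on log y ~ log x (the classic linearisation).

    Differs from :func:`fit_power` under noise (log-scale least squares
    down-weights large responses); identical on noiseless power-law data.
    r_squared is still reported on the linear scale for comparability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_power_inputs(x, y)
    res = stats.linregress(np.log(x), np.log(y))
    a, b = float(np.exp(res.intercept)), float(res.slope)
    return PowerFit(a=a, b=b, r_squared=_r_squared(y, a * x**b), n=int(x.size))


def fit_power(x, y) -> PowerFit:
    """Power-law fit y = a*x**b by nonlinear least squares on the linear
    scale, initialised from the log-log OLS fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_power_inputs(x, y)
    init = fit_power_loglog(x, y)
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * np.power(x, b),
            x,
            y,
            p0=[init.a, init.b],
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"power fit did not converge (started from a={init.a:.4g}, "
            f"b={init.b:.4g}): {err}"
        ) from None
    a, b = float(popt[0]), float(popt[1])
    return PowerFit(a=a, b=b, r_squared=_r_squared(y, a * x**b), n=int(x.size))


def _check_power_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size or x.size < 3:
        raise ValueError("power fit needs at least 3 paired observations")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power fit requires strictly positive x and y")


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------

EXACT_LIMIT = 20  # nonzero pairs up to which the exact null is enumerated


def _exact_sign_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed exact p over all sign assignments of the given ranks.

    Tie-aware: average ranks are multiples of 1/2, so doubling them gives
    integers and the full null distribution of 2*W+ is built by dynamic
    programming (polynomial multiplication over sign assignments), which is
    equivalent to enumerating all 2^n assignments.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    w_small = min(w2, total - w2)
    p = 2.0 * float(dist[: w_small + 1].sum())
    return min(p, 1.0)


def paired_sign_rank(a, b, zero_method: str = "wilcox") -> PairedTestResult:
    """Wilcoxon matched-pairs signed-rank test, two-tailed.

    Differences d = a - b are ranked by |d| with average ranks for ties.
    Zero differences are dropped before ranking (``zero_method="wilcox"``,
    the classic treatment) or included in the ranking and then discarded
    (``"pratt"``).  Up to 20 nonzero pairs the exact null distribution is
    enumerated; above that a normal approximation with continuity
    correction and exact tie-aware variance (sum of squared ranks / 4) is
    used.  All-zero differences give p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired_sign_rank requires equal-length samples")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    d = a - b
    med_a, med_b = float(np.median(a)), float(np.median(b))
    med_d = float(np.median(d))

    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return PairedTestResult(0.0, 1.0, 0, med_a, med_b, med_d, "degenerate")

    if zero_method == "wilcox":
        d_used = d[nonzero]
        ranks = stats.rankdata(np.abs(d_used))
    else:  # pratt: rank with zeros included, then discard their ranks
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    n = int(d_used.size)
    if n < 5:
        warnings.warn(
            f"only {n} nonzero pairs; the signed-rank test has little power",
            stacklevel=2,
        )
    w_plus = float(ranks[d_used > 0].sum())

    if n <= EXACT_LIMIT:
        p = _exact_sign_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mean = float(ranks.sum()) / 2.0
        var = float(np.sum(ranks**2)) / 4.0
        # continuity correction of 0.5 toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
        p = min(p, 1.0)
        method = "normal-approx"
    return PairedTestResult(w_plus, p, n, med_a, med_b, med_d, method)


def df_distribution(df_means, bin_width: float = 0.05) -> DFHistogram:
    """Histogram of trial-mean duty factors with empty-range detection.

    Fixed-width bins tile [0, 1]; the detected empty range is the longest
    run of empty bins strictly between the first and last occupied bins
    (``None`` when every interior bin is occupied or fewer than two bins
    are occupied).
    """
    values = np.asarray(df_means, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if np.any((values <= 0) | (values > 1)):
        raise ValueError("duty factors must lie in (0, 1]")
    n_bins = int(math.ceil(1.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    # index-based binning with an epsilon so values on a bin edge (e.g.
    # 0.75 with width 0.05) land in the upper bin despite float rounding
    idx = np.floor(values / bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # 1.0 belongs to the last bin
    counts = np.bincount(idx, minlength=n_bins)

    occupied = np.nonzero(counts)[0]
    empty_range = None
    if occupied.size >= 2:
        best_len, best = 0, None
        run_start = None
        for i in range(occupied[0], occupied[-1] + 1):
            if counts[i] == 0:
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None and i - run_start > best_len:
                    best_len, best = i - run_start, (run_start, i)
                run_start = None
        if best is not None:
            empty_range = (float(edges[best[0]]), float(edges[best[1]]))
    return DFHistogram(bin_edges=edges, counts=counts, empty_range=empty_range)
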