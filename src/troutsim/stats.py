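"""Nonparametric statistics for scenario comparisons and trends.

* Kruskal-Wallis one-way ANOVA on ranks across scenarios, with a
  Nemenyi-type pairwise comparison on joint ranks (studentized-range
  reference) when differences exist.
* Mann-Kendall trend test with tie-corrected variance, ±1 continuity
  correction, an optional serial-correlation variance inflation computed
  from significant lag autocorrelations of the Sen-detrended ranks
  (effective-sample-size approach), and the Sen slope reported per decade.
* Wilcoxon signed-rank paired test with continuity correction, the
  Hodges–Lehmann pseudomedian of differences, and a distribution-based
  confidence interval from ordered Walsh averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test result; ``sen_slope`` is in units per decade."""

    s: float
    var_s: float
    z: float
    p: float
    sen_slope: float
    correction_factor: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank result with Hodges–Lehmann estimate and CI."""

    v: float
    p: float
    pseudomedian: float
    ci_low: float
    ci_high: float
    n: int  # nonzero differences used
    degenerate: bool = False  # all differences were zero


def _mk_s_and_var(x: np.ndarray) -> tuple[float, float]:
    """Kendall S statistic and its tie-corrected variance."""
    n = x.size
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diff_sign, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    tie_term = float((counts * (counts - 1) * (2 * counts + 5)).sum())
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var


def sen_slope(x: np.ndarray, per: float = 1.0) -> float:
    """Median of pairwise slopes; ``per`` rescales (10 = per decade for
    annual data).  0 for constant series."""
    x = np.asarray(x, dtype=float)
    n = x.size
    i, j = np.triu_indices(n, 1)
    slopes = (x[j] - x[i]) / (j - i)
    return float(np.median(slopes)) * per


def mann_kendall(
    series,
    serial_correction: bool = True,
    acf_alpha: float = 0.05,
    slope_per: float = 10.0,
) -> TrendResult:
    """Mann-Kendall trend test on a yearly series.

    With ``serial_correction`` the variance of S is inflated by the
    effective-sample-size factor n/n* computed from the autocorrelations of
    the ranks of the Sen-detrended series, keeping only lags whose
    autocorrelation is significant at ``acf_alpha`` (two-sided normal
    bounds).  The Sen slope is reported per ``slope_per`` time steps
    (default: per decade for annual data).
    """
    x = np.asarray(list(series), dtype=float)
    if x.size < 4:
        raise InsufficientDataError("Mann-Kendall requires at least 4 values")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    n = x.size
    s, var = _mk_s_and_var(x)

    slope_yr = sen_slope(x, per=1.0)

    cf = 1.0
    if serial_correction and var > 0:
        detrended = x - slope_yr * np.arange(n)
        r = sps.rankdata(detrended)
        r = r - r.mean()
        denom = float(r @ r)
        crit = sps.norm.ppf(1.0 - acf_alpha / 2.0)
        acc = 0.0
        for k in range(1, n - 2):
            if denom <= 0:
                break
            rho = float(r[:-k] @ r[k:]) / denom
            if abs(rho) > crit / math.sqrt(n):
                acc += (n - k) * (n - k - 1) * (n - k - 2) * rho
        cf = 1.0 + 2.0 / (n * (n - 1) * (n - 2)) * acc
        # the factor is used only to guard against serial-correlation-induced
        # anticonservatism: variance is inflated, never shrunk (random
        # negative sample autocorrelations on white noise would otherwise
        # deflate it and inflate the type-I error)
        if cf < 1.0:
            cf = 1.0
    var_corr = var * cf

    if s > 0:
        z = (s - 1.0) / math.sqrt(var_corr) if var_corr > 0 else math.inf
    elif s < 0:
        z = (s + 1.0) / math.sqrt(var_corr) if var_corr > 0 else -math.inf
    else:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z)) if math.isfinite(z) else 0.0

    return TrendResult(
        s=s, var_s=var_corr, z=z, p=min(p, 1.0),
        sen_slope=sen_slope(x, per=slope_per), correction_factor=cf, n=n,
    )


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all values identical: no evidence of any difference
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def pairwise_rank_tukey(groups, labels=None) -> "np.ndarray | object":
    """Nemenyi-type pairwise comparisons on joint ranks.

    Group mean ranks are compared with a studentized-range reference
    (infinite df), with a tie correction on the rank variance.  Returns a
    symmetric p-value matrix with unit diagonal (a DataFrame when pandas
    labels are given).
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    mean_ranks = np.array(mean_ranks)

    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float((counts**3 - counts).sum()) / (n_tot**3 - n_tot)
    tie_corr = max(tie_corr, 1e-12)

    pmat = np.ones((k, k))
    base_var = n_tot * (n_tot + 1) / 12.0 * tie_corr
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * math.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, np.inf))
            pmat[i, j] = pmat[j, i] = min(max(p, 0.0), 1.0)
    if labels is not None:
        import pandas as pd

        return pd.DataFrame(pmat, index=labels, columns=labels)
    return pmat


def signed_rank_cdf(n: int) -> np.ndarray:
    """Null CDF of the signed-rank statistic V for sample size n (exact DP)."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[: m + 1 - r]
    return np.cumsum(counts) / counts.sum()


def _qsignrank(prob: float, n: int) -> int:
    """Smallest q with P(V <= q) >= prob under the null (exact)."""
    cdf = signed_rank_cdf(n)
    return int(np.searchsorted(cdf, prob - 1e-12))


def walsh_averages(d: np.ndarray) -> np.ndarray:
    """All pairwise means (d_i + d_j)/2 for i <= j, sorted ascending."""
    d = np.asarray(d, dtype=float)
    i, j = np.triu_indices(d.size)
    return np.sort((d[i] + d[j]) / 2.0)


def wilcoxon_signed_rank(x, y, conf_level: float = 0.95) -> PairedTestResult:
    """Paired signed-rank test of ``x − y`` with continuity correction.

    Zero differences are dropped before ranking; ties receive average ranks
    with a tie-corrected variance.  The pseudomedian is the Hodges–Lehmann
    median of Walsh averages; the CI comes from signed-rank distribution
    quantiles applied to the ordered Walsh averages.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return PairedTestResult(v=0.0, p=1.0, pseudomedian=0.0, ci_low=0.0,
                                ci_high=0.0, n=0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        (counts**3 - counts).sum()
    ) / 48.0
    if sigma2 > 0:
        z = (v - mu - 0.5 * np.sign(v - mu)) / math.sqrt(sigma2)
        p = min(2.0 * sps.norm.sf(abs(z)), 1.0)
    else:
        p = 1.0

    w = walsh_averages(d)
    pseudomedian = float(np.median(w))
    alpha = 1.0 - conf_level
    m = w.size
    # largest c with P(V <= c) <= alpha/2 gives [w_(c+1), w_(m-c)]
    q = _qsignrank(alpha / 2.0, n)
    cdf = signed_rank_cdf(n)
    c = q if (q < len(cdf) and cdf[q] <= alpha / 2.0 + 1e-12) else q - 1
    c = max(c, 0)
    ci_low = float(w[min(c, m - 1)])
    ci_high = float(w[max(m - 1 - c, 0)])
    return PairedTestResult(v=v, p=p, pseudomedian=pseudomedian,
                            ci_low=ci_low, ci_high=ci_high, n=n)
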