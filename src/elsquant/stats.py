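"""Nonparametric statistics for grouped gland metrics.

First-principles implementations of the tests used to compare quantification
endpoints between groups: Mann–Whitney U (exact permutation enumeration for
small samples, tie-corrected normal approximation otherwise), Wilcoxon
signed-rank, Spearman correlation matrices with Benjamini–Hochberg FDR
adjustment, Grubbs' single-outlier test, and ΔΔCt relative qPCR
quantification.

Conventions: midranks for ties throughout; all tests two-sided by default;
exact p values are defined as the permutation probability of a statistic at
least as far from its null mean as observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import rankdata
from scipy.stats import t as _t

__all__ = [
    "TestResult",
    "CorrelationMatrixResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "spearman_matrix",
    "benjamini_hochberg",
    "grubbs",
    "grubbs_critical",
    "ddct_fold_change",
    "significance_stars",
]

_EPS = 1e-9


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p_value out of range: {self.p_value}")
        self.p_value = min(self.p_value, 1.0)


def significance_stars(p: float, levels=(0.05, 0.01, 0.001, 0.0001)) -> str:
    """Figure-legend stars: * P<0.05, ** P<0.01, *** P<0.001, **** P<0.0001."""
    stars = sum(p < lv for lv in levels)
    return "*" * stars if stars else "ns"


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

def _p_from_distribution(values: np.ndarray, observed: float, mean: float,
                         alternative: str) -> float:
    """Permutation p value from an enumerated null distribution."""
    n = len(values)
    if alternative == "two-sided":
        return float(np.sum(np.abs(values - mean) >= abs(observed - mean) - _EPS)) / n
    if alternative == "less":
        return float(np.sum(values <= observed + _EPS)) / n
    if alternative == "greater":
        return float(np.sum(values >= observed - _EPS)) / n
    raise ValueError("alternative must be 'two-sided', 'less' or 'greater'")


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 12,
) -> TestResult:
    """Mann–Whitney U test on two independent samples.

    Midranks handle ties.  For ``n1 + n2 <= exact_limit`` the p value is an
    exact permutation probability obtained by enumerating all group
    labelings of the pooled (mid)ranks; otherwise a tie-corrected normal
    approximation with continuity correction is used.  The statistic is U for
    the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    n = n1 + n2

    if n <= exact_limit:
        # enumerate every assignment of n1 pooled ranks to group x
        us = np.array(
            [sum(ranks[list(idx)]) for idx in combinations(range(n), n1)]
        ) - n1 * (n1 + 1) / 2.0
        p = _p_from_distribution(us, u_x, mu, alternative)
        return TestResult(u_x, p, "Mann-Whitney U (exact)", n1, n2, True)

    # tie-corrected normal approximation with continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(u_x, 1.0, "Mann-Whitney U (normal approx.)", n1, n2, False)
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u_x - mu) - 0.5) / sd
        p = 2.0 * _norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u_x - mu - 0.5) / sd
        p = _norm.sf(z)
    else:
        z = (u_x - mu + 0.5) / sd
        p = _norm.cdf(z)
    return TestResult(u_x, min(p, 1.0), "Mann-Whitney U (normal approx.)", n1, n2, False)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 15,
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking (Wilcoxon's original
    convention); if every difference is zero the test is degenerate and
    returns p = 1 with a warning.  The statistic is W+, the sum of ranks of
    positive differences.  Exact p by enumeration of all 2^n sign patterns
    when the effective n <= ``exact_limit``; otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D samples")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; test is degenerate")
        return TestResult(0.0, 1.0, "Wilcoxon signed-rank (degenerate)", len(x), len(x), True)
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= exact_limit:
        # distribution of W+ over all 2^n sign assignments of the ranks
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        ws = signs @ ranks
        p = _p_from_distribution(ws, w_pos, mu, alternative)
        return TestResult(w_pos, p, "Wilcoxon signed-rank (exact)", n, n, True)

    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = (n * (n + 1) * (2 * n + 1) - tie_term / 2.0) / 24.0
    if var <= 0:
        return TestResult(w_pos, 1.0, "Wilcoxon signed-rank (normal approx.)", n, n, False)
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(w_pos - mu) - 0.5) / sd
        p = 2.0 * _norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (w_pos - mu - 0.5) / sd
        p = _norm.sf(z)
    else:
        z = (w_pos - mu + 0.5) / sd
        p = _norm.cdf(z)
    return TestResult(w_pos, min(p, 1.0), "Wilcoxon signed-rank (normal approx.)", n, n, False)


# ---------------------------------------------------------------------------
# Spearman correlation matrix with BH-FDR
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values.

    ``p_adj[i] = min_{j: p_j >= p_i} (m / rank_j) * p_j`` clipped at 1; NaN
    entries are passed through and excluded from the family size.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    tmp = np.empty(m)
    tmp[order] = adj
    out[ok] = tmp
    return out


@dataclass
class CorrelationMatrixResult:
    """Spearman correlation matrix with raw and FDR-adjusted p values.
    Matrices are DataFrames indexed by variable name; ``n`` holds the
    pairwise-complete sample sizes."""

    variables: list[str]
    r: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n: pd.DataFrame


def _spearman_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan"), n
    ra, rb = rankdata(a), rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt(float(ra @ ra) * float(rb @ rb))
    r = float(ra @ rb) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    tstat = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _t.sf(abs(tstat), n - 2)
    return r, min(p, 1.0), n


def spearman_matrix(
    data: pd.DataFrame, fdr: str = "bh"
) -> CorrelationMatrixResult:
    """Spearman correlation matrix over the columns of ``data`` with
    Benjamini–Hochberg adjustment applied over the strict upper triangle
    (each pair tested once; constant or too-short pairs are NaN and excluded
    from the family)."""
    if fdr != "bh":
        raise ValueError("only Benjamini-Hochberg ('bh') adjustment is supported")
    cols = list(data.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(p, 0.0)
    pairs = list(combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        ri, pi, ni = _spearman_pair(
            data[cols[i]].to_numpy(dtype=float), data[cols[j]].to_numpy(dtype=float)
        )
        r[i, j] = r[j, i] = ri
        p[i, j] = p[j, i] = pi
        nmat[i, j] = nmat[j, i] = ni
        raw.append(pi)
    adj = benjamini_hochberg(raw)
    p_adj = np.full((k, k), np.nan)
    np.fill_diagonal(p_adj, 0.0)
    for (i, j), a in zip(pairs, adj):
        p_adj[i, j] = p_adj[j, i] = a
    mk = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationMatrixResult(cols, mk(r), mk(p), mk(p_adj), mk(nmat))


# ---------------------------------------------------------------------------
# Grubbs outlier test
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value:
    ``G_crit = ((n-1)/sqrt(n)) * sqrt(t² / (n-2+t²))`` with t the upper
    ``alpha/(2n)`` quantile of Student's t with n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    tq = _t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return ((n - 1) / math.sqrt(n)) * math.sqrt(tq**2 / (n - 2 + tq**2))


def grubbs(
    values: Sequence[float], alpha: float = 0.05, iterate: bool = False
) -> list[int]:
    """Indices of outliers flagged by Grubbs' test (two-sided).

    The statistic is ``G = max|x_i - mean| / sd`` with the sample standard
    deviation (n-1 denominator); the extreme value is flagged when
    ``G > G_crit(n, alpha)``.  With ``iterate=True`` the test repeats on the
    reduced sample until no value is flagged or only three remain.  Returned
    indices refer to the original input order.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Grubbs test requires a 1-D sample with n >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    active = list(range(len(x)))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        sd = float(np.std(sub, ddof=1))
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        g = float(dev[k]) / sd
        if g > grubbs_critical(len(sub), alpha):
            flagged.append(active.pop(k))
            if not iterate:
                break
        else:
            break
    return sorted(flagged)


# ---------------------------------------------------------------------------
# ΔΔCt
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct_target_sample: float | Sequence[float],
    ct_ref_sample: float | Sequence[float],
    ct_target_calibrator: float | Sequence[float],
    ct_ref_calibrator: float | Sequence[float],
) -> float:
    """Relative expression by the ΔΔCt method: ``2^-ΔΔCt`` with
    ``ΔΔCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator``.
    Replicate wells (e.g. duplicates) are averaged on the Ct scale first.
    """
    cts = []
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if not np.all(np.isfinite(arr)):
            raise ValueError("Ct values must be finite")
        cts.append(float(arr.mean()))
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))
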