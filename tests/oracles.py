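"""Independent brute-force oracles used to pin down the analysis operations.

Each oracle implements the *definition* of a quantity by exhaustive
enumeration or quadrature, staying deliberately independent of the package's
implementation path (no shared code, no dynamic programming shortcuts).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations, product

import numpy as np
from scipy import integrate
from scipy.stats import chi2, norm, rankdata


# ---------------------------------------------------------------- DTW oracle

@lru_cache(maxsize=None)
def monotone_paths(n: int, m: int) -> tuple[tuple[tuple[int, int], ...], ...]:
    """All monotone warping paths from (0,0) to (n-1,m-1) with unit steps
    right/down/diagonal."""
    if n == 1 and m == 1:
        return (((0, 0),),)
    paths = []
    if n > 1:
        for p in monotone_paths(n - 1, m):
            paths.append(p + ((n - 1, m - 1),))
    if m > 1:
        for p in monotone_paths(n, m - 1):
            paths.append(p + ((n - 1, m - 1),))
    if n > 1 and m > 1:
        for p in monotone_paths(n - 1, m - 1):
            paths.append(p + ((n - 1, m - 1),))
    return tuple(paths)


@lru_cache(maxsize=None)
def _padded_path_indices(n: int, m: int) -> tuple[np.ndarray, int]:
    """Paths as flat indices into an (n+1, m+1) cost matrix whose last
    row/column is zero padding; shape (n_paths, max_len)."""
    paths = monotone_paths(n, m)
    max_len = max(len(p) for p in paths)
    idx = np.full((len(paths), max_len), n * (m + 1) + m, dtype=np.int64)  # pad cell
    for r, p in enumerate(paths):
        for c, (i, j) in enumerate(p):
            idx[r, c] = i * (m + 1) + j
    return idx, max_len


def dtw_by_path_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """DTW distance as the minimum over all explicit monotone warping paths
    of the summed absolute differences along the path."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    C = np.zeros((n + 1, m + 1))
    C[:n, :m] = np.abs(a[:, None] - b[None, :])
    idx, _ = _padded_path_indices(n, m)
    return float(C.ravel()[idx].sum(axis=1).min())


# ------------------------------------------------- rank-test exact oracles

def wilcoxon_by_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact Wilcoxon signed-rank (W = min(W+, W-), two-sided p) by
    enumerating all 2^n sign patterns. Requires no zero differences and no
    tied |differences|."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    assert np.unique(np.abs(d)).size == n, "oracle requires untied |differences|"
    w_plus = ranks[d > 0].sum()
    dist = np.array([np.sum(ranks[list(signs)]) for signs in
                     product([False, True], repeat=n)])
    # distribution of W+ over equiprobable sign patterns
    p_le = np.mean(dist <= w_plus)
    p_ge = np.mean(dist >= w_plus)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(min(w_plus, ranks.sum() - w_plus)), float(p)


def mannwhitney_by_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact Mann-Whitney (U of x, two-sided p) by enumerating all
    C(n1+n2, n1) group assignments of the pooled sample. No ties allowed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires untied values"
    n1 = x.size

    def u_of(group_a: np.ndarray, group_b: np.ndarray) -> float:
        return float(np.sum(group_a[:, None] > group_b[None, :]))

    u_obs = u_of(x, y)
    all_idx = set(range(pooled.size))
    dist = []
    for a_idx in combinations(range(pooled.size), n1):
        a = pooled[list(a_idx)]
        b = pooled[list(all_idx - set(a_idx))]
        dist.append(u_of(a, b))
    dist = np.array(dist)
    p = min(1.0, 2.0 * min(np.mean(dist <= u_obs), np.mean(dist >= u_obs)))
    return u_obs, float(p)


# ------------------------------------------------------------ other oracles

def silhouette_by_formula(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Direct silhouette evaluation: s(i) = (b - a) / max(a, b), a = mean
    intra-cluster distance (excluding self), b = min over other clusters of
    the mean distance; singleton clusters score 0."""
    labels = np.asarray(labels)
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        if own.size == 0:
            out[i] = 0.0
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == lab].mean() for lab in np.unique(labels)
                if lab != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


def power_by_quadrature(d: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided one-sample t-test power by integrating over the chi-square
    distribution of the variance estimate (no noncentral-t CDF involved)."""
    from scipy.stats import t as t_dist

    df = n - 1
    t_crit = t_dist.ppf(1 - alpha / 2, df)
    nc = d * np.sqrt(n)

    def integrand(v: float) -> float:
        s = t_crit * np.sqrt(v / df)
        return chi2.pdf(v, df) * (norm.sf(s - nc) + norm.cdf(-s - nc))

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(val)


def max_ncc_by_scan(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Maximum normalized cross-correlation over all zero-padded integer
    shifts of y, by direct scanning. Returns (max NCC, maximizing lag)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    L = x.size
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    best, best_lag = -np.inf, 0
    for lag in range(-(L - 1), L):
        # r[lag] = sum_i y[i + lag] * x[i] with zero padding
        if lag >= 0:
            val = float(np.dot(y[lag:], x[: L - lag]))
        else:
            val = float(np.dot(y[: L + lag], x[-lag:]))
        if val / denom > best:
            best, best_lag = val / denom, lag
    return best, best_lag
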