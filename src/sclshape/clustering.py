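"""k-Shape clustering of nSCL series and 12-condition consensus.

k-Shape is partitional clustering for z-normalized time series under the
shape-based distance SBD(x, y) = 1 - max_w NCC_w(x, y), where NCC_w is the
cross-correlation at integer shift w (zero padding) normalized by
||x||*||y||; SBD lies in [0, 2] and is shift-invariant. Centroids are
updated as the leading eigenvector of the centered scatter of the
members aligned (optimally shifted) to the current centroid, with the sign
chosen to maximize summed correlation with the members.

Partitions are validated with the silhouette score on the SBD distance
matrix. Per-condition partitions (six scenes x two modalities = 12) are
combined by consensus: counting, for every pair of participants, how many
conditions assign them to the same cluster (0-12; invariant to cluster
relabeling) and keeping edges at or above a threshold (default 10) in a
connectivity graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.linalg import eigh
from sklearn.metrics import silhouette_samples

from .errors import (
    DegenerateSeriesError,
    InvalidKError,
    InvalidParameterError,
    UndefinedScoreError,
)

__all__ = [
    "sbd", "sbd_matrix", "kshape", "silhouette", "consensus", "compare_k",
    "ClusterResult", "ConsensusGraph", "zscore_rows",
]


def zscore_rows(X: np.ndarray) -> np.ndarray:
    """Z-normalize each row; raises on constant rows (no shape)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd.ravel() == 0)
        raise DegenerateSeriesError(f"constant series at rows {bad.tolist()}")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def _ncc_all_lags(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of each row of X with y at all lags.

    Returns an array of shape (n_rows, 2L-1) for lags -(L-1)..(L-1),
    normalized by the product of Euclidean norms (coefficient normalization).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    L = y.size
    n = next_fast_len(2 * L - 1)
    cc = irfft(rfft(X, n) * np.conj(rfft(y, n)), n)
    cc = np.concatenate([cc[:, -(L - 1):], cc[:, :L]], axis=1)
    norms = np.linalg.norm(X, axis=1) * np.linalg.norm(y)
    if np.any(norms == 0):
        raise DegenerateSeriesError("zero-norm series in NCC")
    return cc / norms[:, None]


def sbd(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Shape-based distance and the copy of ``y`` aligned to ``x``.

    Returns (distance in [0, 2], y shifted by the maximizing lag with zero
    padding, lag). ``lag`` is how many samples ``y`` trails ``x``: for y a
    5-sample-delayed copy of x, lag = 5 and the returned series is y
    advanced by 5 samples. sbd(x, x) = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("sbd requires equal-length series")
    ncc = _ncc_all_lags(y[None, :], x)[0]  # r[k] = sum_i y[i+k] * x[i]
    L = x.size
    best = int(np.argmax(ncc))
    lag = best - (L - 1)
    dist = float(1.0 - ncc[best])
    return dist, _shift(y, -lag), lag


def _shift(y: np.ndarray, lag: int) -> np.ndarray:
    """Shift with zero padding: positive lag delays the series."""
    out = np.zeros_like(y)
    if lag == 0:
        out[:] = y
    elif lag > 0:
        out[lag:] = y[: y.size - lag]
    else:
        out[:lag] = y[-lag:]
    return out


def sbd_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise SBD distance matrix over rows of X (z-normalize first)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        ncc = _ncc_all_lags(X[i + 1:], X[i])
        if ncc.size:
            d = 1.0 - ncc.max(axis=1)
            D[i, i + 1:] = d
            D[i + 1:, i] = d
    return D


def _extract_shape(members: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """k-Shape centroid update: leading eigenvector of the centered scatter
    of members aligned to the current centroid."""
    L = members.shape[1]
    if centroid.any():
        aligned = np.stack([sbd(centroid, m)[1] for m in members])
    else:
        aligned = members
    S = aligned.T @ aligned
    Q = np.eye(L) - np.full((L, L), 1.0 / L)
    M = Q @ S @ Q
    _, vec = eigh(M, subset_by_index=[L - 1, L - 1])
    v = vec[:, 0]
    # Eigenvector sign is arbitrary; pick the sign better correlated with members.
    if np.sum(aligned @ v) < 0:
        v = -v
    sd = v.std()
    if sd == 0:
        return np.zeros(L)
    return (v - v.mean()) / sd


def _min_dists(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, k = X.shape[0], centroids.shape[0]
    dists = np.full((n, k), 2.0)
    for c in range(k):
        if centroids[c].any():
            dists[:, c] = 1.0 - _ncc_all_lags(X, centroids[c]).max(axis=1)
    return dists.argmin(axis=1), dists.min(axis=1)


@dataclass
class ClusterResult:
    """One condition's k-Shape partition with its silhouette validation."""

    condition: str
    persons: list[str]
    labels: np.ndarray
    k: int
    seed: int
    n_iter: int
    objective: float
    sil_samples: np.ndarray | None = None
    sil_mean: float | None = None
    degenerate: bool = False


def kshape(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 10,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Cluster rows of X (equal-length series) into k shape clusters.

    Rows are z-normalized internally. Initialization is a random partition
    from the seeded RNG; ``n_init`` restarts keep the partition with the
    lowest total member-to-centroid SBD. Empty clusters are reseeded from
    the series farthest from its centroid. Deterministic for a fixed seed.

    Returns (labels, centroids, objective, iterations, degenerate) where
    ``degenerate`` flags a collapsed partition (fewer than k non-empty
    clusters, e.g. when all series are identical).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise InvalidKError(f"k must be in [2, {n}], got {k}")
    Z = zscore_rows(X)
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(max(n_init, 1)):
        labels, centroids, obj, it, _ = _kshape_once(Z, k, rng, max_iter)
        if best is None or obj < best[2]:
            best = (labels, centroids, obj, it)
    labels, centroids, obj, it = best
    # Collapsed partitions: fewer than k populated clusters, or a partition
    # held apart only by the empty-cluster reseeding rule (all series alike).
    degenerate = len(np.unique(labels)) < k or (n > k and obj <= 1e-10)
    return labels, centroids, obj, it, degenerate


def _kshape_once(Z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    n, L = Z.shape
    labels = rng.integers(0, k, size=n)
    # ensure every cluster starts non-empty
    labels[rng.permutation(n)[:k]] = np.arange(k)
    centroids = np.zeros((k, L))
    it = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        for c in range(k):
            members = Z[labels == c]
            if members.shape[0] > 0:
                centroids[c] = _extract_shape(members, centroids[c])
        new_labels, dists = _min_dists(Z, centroids)
        # reseed empty clusters with the worst-fit series
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(dists))
                new_labels[far] = c
                dists[far] = 0.0
        history.append(float(dists.sum()))
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    _, dists = _min_dists(Z, centroids)
    return labels, centroids, float(dists.sum()), it, history


def silhouette(D: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Silhouette values and their mean from a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)); members of singleton clusters
    score 0. Raises :class:`UndefinedScoreError` with a single cluster.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise UndefinedScoreError("silhouette undefined for a single cluster")
    values = silhouette_samples(np.asarray(D, dtype=float), labels, metric="precomputed")
    return values, float(values.mean())


@dataclass
class ConsensusGraph:
    """Pairwise co-assignment counts across conditions plus thresholded edges."""

    persons: list[str]
    counts: np.ndarray
    threshold: int
    n_conditions: int
    edges: list[tuple[str, str, int]]
    tiers: dict[str, str] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for p in self.persons:
            g.add_node(p, tier=self.tiers.get(p, ""))
        for a, b, c in self.edges:
            g.add_edge(a, b, count=int(c))
        return g


def consensus(
    results: list[ClusterResult],
    threshold: int = 10,
    tiers: dict[str, str] | None = None,
) -> ConsensusGraph:
    """Count per-pair co-assignments over conditions and threshold into edges.

    Counts are invariant to any per-condition relabeling of clusters. All
    results must cover the same persons in the same order.
    """
    if not results:
        raise InvalidParameterError("no cluster results to combine")
    persons = results[0].persons
    for r in results[1:]:
        if r.persons != persons:
            raise InvalidParameterError(
                f"condition {r.condition!r} covers a different person set"
            )
    n = len(persons)
    counts = np.zeros((n, n), dtype=int)
    for r in results:
        same = (r.labels[:, None] == r.labels[None, :]).astype(int)
        counts += same
    np.fill_diagonal(counts, 0)
    edges = [
        (persons[i], persons[j], int(counts[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if counts[i, j] >= threshold
    ]
    return ConsensusGraph(persons=persons, counts=counts, threshold=threshold,
                          n_conditions=len(results), edges=edges,
                          tiers=dict(tiers or {}))


def cluster_conditions(
    conditions: dict[tuple[str, str], dict[str, np.ndarray]],
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> list[ClusterResult]:
    """k-Shape every condition; series are truncated to the condition's
    shortest length so SBD sees equal-length inputs."""
    out: list[ClusterResult] = []
    for (scene, modality), series in sorted(conditions.items()):
        persons = sorted(series)
        L = min(series[p].size for p in persons)
        X = np.stack([series[p][:L] for p in persons])
        labels, _, obj, it, degenerate = kshape(X, k, seed=seed, n_init=n_init,
                                                max_iter=max_iter)
        D = sbd_matrix(zscore_rows(X))
        try:
            vals, mean = silhouette(D, labels)
        except UndefinedScoreError:
            vals, mean = None, None
        out.append(ClusterResult(condition=f"{scene}/{modality}", persons=persons,
                                 labels=labels, k=k, seed=seed, n_iter=it,
                                 objective=obj, sil_samples=vals, sil_mean=mean,
                                 degenerate=degenerate))
    return out


def compare_k(
    conditions: dict[tuple[str, str], dict[str, np.ndarray]],
    ks: tuple[int, ...] = (2, 3, 4),
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> dict[int, float]:
    """Mean silhouette over all conditions for each candidate k."""
    out: dict[int, float] = {}
    for k in ks:
        results = cluster_conditions(conditions, k=k, seed=seed, n_init=n_init,
                                     max_iter=max_iter)
        means = [r.sil_mean for r in results if r.sil_mean is not None]
        if not means:
            raise UndefinedScoreError(f"no valid silhouette at k={k}")
        out[k] = float(np.mean(means))
    return out
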