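"""Shape-based pairwise similarity of nSCL series via dynamic time warping.

Shape-only comparison is realized by z-normalizing each series (removing
per-person offset and amplitude) after block-mean downsampling to 4 Hz
(tonic SCL bandwidth is well below 1 Hz, and downsampling shrinks the DTW
dynamic program from 2400^2 to 240^2 cells). The DTW distance uses the
classic recurrence with absolute local cost and no warping-window
constraint by default.

Distances within one condition (scene x modality) are mapped onto the
0-100 similarity scale by per-condition min-max scaling,
S_ij = 100 * (1 - d_ij / d_max); the per-scene matrices are then averaged
element-wise per modality to give a person x person similarity, from which
within-tier averages are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import ANALYSIS_SCENES, MODALITIES, NormalizedSegment
from .errors import InvalidParameterError, TooShortError

__all__ = [
    "znorm", "resample_block", "dtw_distance", "SimilarityMatrix",
    "similarity_matrix", "average_similarity", "group_similarity",
    "condition_series", "modality_similarity",
]


def znorm(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Zero-mean unit-variance (population sd) rescaling.

    Returns (normalized, degenerate). A constant input has no shape: it maps
    to all zeros with ``degenerate=True`` so callers can exclude it.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise TooShortError(f"znorm needs >= 2 samples, got {x.size}")
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def resample_block(series: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Downsample by non-overlapping block means of size fs_in/fs_out.

    A trailing partial block is kept if it is at least half full. The ratio
    must be (near-)integer.
    """
    if not fs_in >= fs_out > 0:
        raise InvalidParameterError(f"need fs_in >= fs_out > 0, got {fs_in}, {fs_out}")
    ratio = fs_in / fs_out
    block = int(round(ratio))
    if abs(ratio - block) > 1e-9:
        raise InvalidParameterError(f"fs_in/fs_out must be an integer, got {ratio}")
    x = np.asarray(series, dtype=float)
    if block == 1:
        return x.copy()
    n_full = x.size // block
    out = x[: n_full * block].reshape(n_full, block).mean(axis=1)
    rem = x.size - n_full * block
    if rem * 2 >= block:
        out = np.append(out, x[n_full * block :].mean())
    return out


@njit(cache=False)
def _dtw_abs(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        c = abs(a[0] - b[j])
        prev[j] = c + (prev[j - 1] if j > 0 else 0.0)
    for i in range(1, n):
        cur[0] = abs(a[i] - b[0]) + prev[0]
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = abs(a[i] - b[j]) + best
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=False)
def _dtw_abs_band(a: np.ndarray, b: np.ndarray, band: int) -> float:  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    D = np.full((n, m), big)
    for i in range(n):
        lo = max(0, i - band)
        hi = min(m, i + band + 1)
        for j in range(lo, hi):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                D[i, j] = c
            else:
                best = big
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                D[i, j] = c + best
    return D[n - 1, m - 1]


def dtw_distance(a: np.ndarray, b: np.ndarray, window: int | None = None) -> float:
    """Classic DTW distance with absolute local cost.

    D(i,j) = |a_i - b_j| + min(D(i-1,j), D(i,j-1), D(i-1,j-1)) with
    D(0,0) = |a_0 - b_0|; returns D(n-1, m-1). Symmetric in its arguments.
    ``window`` optionally imposes a Sakoe-Chiba band (in samples).
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise TooShortError("dtw_distance requires non-empty series")
    if window is None:
        return float(_dtw_abs(a, b))
    band = max(int(window), abs(a.size - b.size))
    return float(_dtw_abs_band(a, b, band))


@dataclass
class SimilarityMatrix:
    """Person x person similarity for one condition (or the scene average).

    ``sim`` is on the 0-100 scale (diagonal 100), ``dist`` holds the raw DTW
    distances (NaN on the scene-averaged matrix), ``counts`` the number of
    conditions contributing to each averaged entry, and ``excluded`` lists
    participants dropped for degenerate (constant) segments.
    """

    persons: list[str]
    condition: str
    sim: np.ndarray
    dist: np.ndarray
    counts: np.ndarray | None = None
    excluded: list[str] = field(default_factory=list)

    def index(self, person: str) -> int:
        return self.persons.index(person)


def similarity_matrix(
    series: dict[str, np.ndarray],
    condition: str = "",
    window: int | None = None,
    already_normalized: bool = False,
) -> SimilarityMatrix:
    """Pairwise DTW similarity (0-100) among participants of one condition.

    ``series`` maps person -> nSCL series (resampled); each is z-normalized
    here unless ``already_normalized``. Degenerate constant series are
    excluded and reported. S_ij = 100 * (1 - d_ij / d_max) with d_max the
    largest pairwise distance in the condition; if every pair is identical
    (d_max = 0) similarity is 100 throughout.
    """
    prepared: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for person, x in series.items():
        if already_normalized:
            prepared[person] = np.asarray(x, dtype=float)
            continue
        z, degenerate = znorm(x)
        if degenerate:
            excluded.append(person)
        else:
            prepared[person] = z
    persons = sorted(prepared)
    n = len(persons)
    if n < 2:
        raise InvalidParameterError(
            f"condition {condition!r}: need >= 2 valid participants, got {n}"
        )
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(prepared[persons[i]], prepared[persons[j]], window)
            dist[i, j] = dist[j, i] = d
    d_max = dist.max()
    sim = np.full((n, n), 100.0) if d_max == 0 else 100.0 * (1.0 - dist / d_max)
    np.fill_diagonal(sim, 100.0)
    return SimilarityMatrix(persons=persons, condition=condition, sim=sim,
                            dist=dist, excluded=excluded)


def average_similarity(
    matrices: list[SimilarityMatrix], condition: str = "averaged"
) -> SimilarityMatrix:
    """Element-wise mean of per-scene similarity matrices.

    Pairs absent from some conditions (excluded participants) are averaged
    over the conditions where both members are present; ``counts`` reports
    how many conditions contributed to each entry.
    """
    if not matrices:
        raise InvalidParameterError("no matrices to average")
    persons = sorted({p for m in matrices for p in m.persons})
    n = len(persons)
    idx = {p: i for i, p in enumerate(persons)}
    total = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for m in matrices:
        sel = np.array([idx[p] for p in m.persons])
        total[np.ix_(sel, sel)] += m.sim
        counts[np.ix_(sel, sel)] += 1
    if counts.max() == 0 or not np.any(counts.diagonal()):
        raise InvalidParameterError("no overlap in persons across matrices")
    with np.errstate(invalid="ignore"):
        sim = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(sim, 100.0)
    return SimilarityMatrix(persons=persons, condition=condition, sim=sim,
                            dist=np.full((n, n), np.nan), counts=counts)


def group_similarity(
    matrix: SimilarityMatrix, labels: dict[str, str]
) -> dict[str, float | None]:
    """Mean off-diagonal similarity among persons sharing each label.

    Singleton groups have no within-group pair; they are reported as None.
    """
    groups: dict[str, list[int]] = {}
    for i, person in enumerate(matrix.persons):
        groups.setdefault(labels[person], []).append(i)
    out: dict[str, float | None] = {}
    for label, members in groups.items():
        if len(members) < 2:
            out[label] = None
            continue
        sel = matrix.sim[np.ix_(members, members)]
        mask = ~np.eye(len(members), dtype=bool)
        out[label] = float(np.nanmean(sel[mask]))
    return out


def condition_series(
    segments: list[NormalizedSegment],
    fs_in: float = 40.0,
    fs_out: float = 4.0,
    scenes: tuple[str, ...] = ANALYSIS_SCENES,
) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Group nSCL series by condition: (scene, modality) -> person -> series.

    Series are block-mean resampled to ``fs_out`` here; z-normalization is
    left to the consumers (DTW similarity and k-Shape both require it).
    """
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for seg in segments:
        if seg.phase not in MODALITIES or seg.scene not in scenes:
            continue
        out.setdefault((seg.scene, seg.phase), {})[seg.person] = resample_block(
            seg.nscl, fs_in, fs_out
        )
    return out


def modality_similarity(
    segments: list[NormalizedSegment],
    fs_in: float = 40.0,
    fs_out: float = 4.0,
    scenes: tuple[str, ...] = ANALYSIS_SCENES,
    window: int | None = None,
) -> dict[str, SimilarityMatrix]:
    """Scene-averaged person x person similarity per modality."""
    conditions = condition_series(segments, fs_in, fs_out, scenes)
    out: dict[str, SimilarityMatrix] = {}
    for modality in MODALITIES:
        mats = [
            similarity_matrix(series, condition=f"{scene}/{modality}", window=window)
            for (scene, mod), series in sorted(conditions.items())
            if mod == modality
        ]
        if mats:
            out[modality] = average_similarity(mats, condition=f"averaged/{modality}")
    return out
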