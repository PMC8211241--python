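"""One-dimensional k-means tissue classification.

In-mask voxel densities are clustered with k = 3 (k-means++ seeding,
Lloyd iterations, 100-iteration cap) and classes are assigned by
centroid order: lowest density → lung, middle → intermediate, highest →
soft tissue.  One model is fitted per scan, which makes the
classification an intra-scan normalization — robust to calibration
drift and reconstruction differences without pre-defined thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import INTERMEDIATE, LUNG, OUTSIDE, SOFT, CtVolume, ThoracicMask

log = logging.getLogger(__name__)

#: class codes ordered by ascending centroid density
_ORDERED_CLASSES = (LUNG, INTERMEDIATE, SOFT)

#: above this many values the model is fitted on a deterministic stride
#: subsample (classification still labels every voxel)
MAX_FIT_VALUES = 5_000_000


@dataclass
class ClusterModel:
    """Fitted 1-D k-means model with the ordered centroid→class map."""

    centroids: np.ndarray  # (k,) ascending
    class_map: dict[int, str] = field(
        default_factory=lambda: {0: "lung", 1: "intermediate", 2: "soft"}
    )
    n_iterations: int = 0
    converged: bool = False
    objective: float = np.inf

    def __post_init__(self) -> None:
        self.centroids = np.sort(np.asarray(self.centroids, dtype=float))
        if len(self.centroids) >= 2 and np.any(np.diff(self.centroids) <= 0):
            raise ValueError("centroids must be strictly increasing")


@dataclass
class TissueSegmentation:
    """Per-voxel tissue classes over the full grid; outside-mask voxels are 0."""

    classes: np.ndarray  # int (nz, ny, nx) in {OUTSIDE, LUNG, INTERMEDIATE, SOFT}
    model: ClusterModel
    voxel_size_mm: float = 0.1


def kmeans_pp_seed(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: squared-distance-weighted initial centroids.

    The first centroid is drawn uniformly from ``values``; each subsequent
    one with probability proportional to the squared distance to its
    nearest already-chosen centroid, which guarantees k distinct seeds.
    """
    values = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(values)
    if len(uniq) < k:
        raise ValueError(
            f"degenerate intensity distribution: {len(uniq)} distinct values < k={k}"
        )
    centroids = [values[rng.integers(len(values))]]
    d2 = (values - centroids[0]) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:  # unreachable given the distinct-value precheck
            raise ValueError("degenerate intensity distribution")
        idx = rng.choice(len(values), p=d2 / total)
        centroids.append(values[idx])
        d2 = np.minimum(d2, (values - centroids[-1]) ** 2)
    return np.array(centroids)


def _assign(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment; exact ties go to the lower centroid."""
    # argmin returns the first minimum, i.e. the lower-density centroid
    return np.argmin(np.abs(values[:, None] - centroids[None, :]), axis=1)


def kmeans_1d(
    values: np.ndarray,
    k: int = 3,
    max_iter: int = 100,
    rng: np.random.Generator | None = None,
) -> ClusterModel:
    """Single Lloyd run of 1-D k-means with k++ seeding.

    Iterates nearest-centroid assignment and mean updates until the
    assignments stop changing or ``max_iter`` is reached.  An emptied
    cluster is re-seeded at the point farthest from its nearest centroid.
    """
    values = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng() if rng is None else rng
    centroids = np.sort(kmeans_pp_seed(values, k, rng))
    assign = np.full(len(values), -1)
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        new_assign = _assign(values, centroids)
        if np.array_equal(new_assign, assign):
            converged = True
            n_it -= 1
            break
        assign = new_assign
        new_centroids = np.empty(k)
        for j in range(k):
            sel = assign == j
            if sel.any():
                new_centroids[j] = values[sel].mean()
            else:
                d = np.abs(values[:, None] - centroids[None, :]).min(axis=1)
                new_centroids[j] = values[np.argmax(d)]
                log.debug("re-seeded empty cluster %d at %g", j, new_centroids[j])
        order = np.argsort(new_centroids)
        centroids = new_centroids[order]
        assign = np.argsort(order)[assign]
    objective = float(np.sum((values - centroids[assign]) ** 2))
    return ClusterModel(
        centroids=centroids,
        n_iterations=n_it,
        converged=converged,
        objective=objective,
    )


def fit_kmeans(
    values: np.ndarray,
    k: int = 3,
    max_iter: int = 100,
    restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> ClusterModel:
    """Best-of-``restarts`` k-means fit (lowest within-cluster SSE kept)."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    values = np.asarray(values, dtype=float).ravel()
    if len(values) > MAX_FIT_VALUES:
        stride = int(np.ceil(len(values) / MAX_FIT_VALUES))
        values = values[::stride]
    best: ClusterModel | None = None
    for _ in range(restarts):
        model = kmeans_1d(values, k=k, max_iter=max_iter, rng=rng)
        if best is None or model.objective < best.objective:
            best = model
    return best


def classify_tissue(
    v: CtVolume, mask: ThoracicMask, model: ClusterModel
) -> TissueSegmentation:
    """Label every in-mask voxel by its nearest centroid's tissue class.

    Exactly equidistant intensities go to the lower-density class.
    """
    m = mask.mask
    if not m.any():
        raise ValueError("thoracic mask is empty")
    vals = v.data[m]
    idx = _assign(vals, model.centroids)
    classes = np.full(v.shape, OUTSIDE, dtype=np.int16)
    classes[m] = np.array(_ORDERED_CLASSES)[idx]
    return TissueSegmentation(classes, model, voxel_size_mm=v.voxel_size_mm)


def exact_optimal_objective_1d(values: np.ndarray, k: int) -> float:
    """Globally optimal 1-D k-means SSE by dynamic programming.

    The 1-D optimum partitions the sorted values into contiguous runs, so
    an O(k·n²) DP over prefix sums finds it exactly.  Used as a reference
    for Lloyd-iteration quality, not in the pipeline itself.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    if n < k:
        raise ValueError("need at least k values")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:  # cost of x[i:j]
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    prev = np.array([0.0] + [sse(0, j) for j in range(1, n + 1)])
    for _ in range(1, k):
        cur = np.full(n + 1, np.inf)
        for j in range(1, n + 1):
            cands = [prev[i] + sse(i, j) for i in range(1, j)]
            if cands:
                cur[j] = min(cands)
        prev = cur
    return float(prev[n])
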