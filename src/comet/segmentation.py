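"""k-means segmentation of the rPWR–rCST plane into energy-signature clusters.

Each in-mask voxel is a 2D observation (its group-average rPWR and rCST).
Lloyd's algorithm with k-means++ seeding runs ``n_repeats`` times from
distinct seeded initializations; the reported labeling comes from the
best-inertia run, and stability is the fraction of runs whose final
labeling — after canonicalizing cluster ids by sorting centroids — matches
it.  Cluster ids are 1-based and ordered by centroid (rPWR, then rCST)
ascending, so a fixed seed yields a bit-identical result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .volume_io import ScalarMap

__all__ = ["SegmentationResult", "kmeans_segment", "project_clusters"]


@dataclass(frozen=True)
class SegmentationResult:
    """Canonicalized k-means labeling of the in-mask voxels."""

    labels: np.ndarray       # cluster id per in-mask voxel, in 1..k
    centroids: np.ndarray    # (k, 2), sorted by (rPWR, rCST) ascending
    inertia: float
    stability: float         # fraction of repeats matching the best run
    cluster_shares: np.ndarray  # percent of voxels per cluster, sums to 100
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        k = self.centroids.shape[0]
        if self.labels.min() < 1 or self.labels.max() > k:
            raise ValueError("labels must lie in 1..k")
        if abs(self.cluster_shares.sum() - 100.0) > 1e-9:
            raise ValueError("cluster shares must sum to 100")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _canonicalize(labels0: np.ndarray, centroids: np.ndarray):
    """Relabel clusters 1..k by lexicographic centroid order (x, then y)."""
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    new_id = np.empty(len(order), dtype=np.int64)
    new_id[order] = np.arange(1, len(order) + 1)
    return new_id[labels0], centroids[order]


def kmeans_segment(rpwr_mean: ScalarMap, rcst_mean: ScalarMap, k: int = 4,
                   max_iter: int = 1000, n_repeats: int = 100,
                   seed: int = 0) -> SegmentationResult:
    """Segment the (rPWR, rCST) plane into ``k`` clusters with a stability check.

    Parameters follow the protocol for group-level maps: k = 4, up to 1000
    Lloyd iterations, 100 independent seeded repeats.  Raises when ``k``
    exceeds the number of distinct in-mask points.
    """
    if not np.array_equal(rpwr_mean.mask.in_mask, rcst_mean.mask.in_mask):
        raise ValueError("rPWR and rCST masks differ")
    X = np.column_stack([rpwr_mean.values, rcst_mean.values])
    n_distinct = np.unique(X, axis=0).shape[0]
    if not 1 <= k <= n_distinct:
        raise ValueError(f"k={k} must be in [1, {n_distinct}] (distinct points)")

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    runs = []
    for s in run_seeds:
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                    algorithm="lloyd", random_state=int(s)).fit(X)
        labels, cents = _canonicalize(km.labels_, km.cluster_centers_)
        runs.append((float(km.inertia_), labels, cents))

    best = min(range(n_repeats), key=lambda i: runs[i][0])
    inertia, labels, cents = runs[best]
    stability = float(np.mean([np.array_equal(r[1], labels) for r in runs]))
    shares = 100.0 * np.bincount(labels, minlength=k + 1)[1:] / labels.size
    return SegmentationResult(
        labels, cents, inertia, stability, shares,
        {"k": k, "max_iter": max_iter, "n_repeats": n_repeats, "seed": seed,
         "init": "k-means++"},
    )


def project_clusters(seg: SegmentationResult, x: ScalarMap, y: ScalarMap) -> dict:
    """Project the segmentation into an alternative (x, y) plane.

    Returns, per cluster id, the (x, y) points of its voxels and the shares
    of those voxels in the four quadrants split at the in-mask means of x
    and y (values exactly at a mean count as "hi").
    """
    if not np.array_equal(x.mask.in_mask, y.mask.in_mask):
        raise ValueError("projection maps use different masks")
    if seg.labels.shape != x.values.shape:
        raise ValueError("segmentation and maps cover different voxel sets")
    mx, my = x.values.mean(), y.values.mean()
    out = {}
    for cid in range(1, seg.k + 1):
        sel = seg.labels == cid
        px, py = x.values[sel], y.values[sel]
        n = max(sel.sum(), 1)
        quad_shares = {
            "hiX_hiY": float(((px >= mx) & (py >= my)).sum()) / n * 100.0,
            "hiX_loY": float(((px >= mx) & (py < my)).sum()) / n * 100.0,
            "loX_hiY": float(((px < mx) & (py >= my)).sum()) / n * 100.0,
            "loX_loY": float(((px < mx) & (py < my)).sum()) / n * 100.0,
        }
        out[cid] = {"points": np.column_stack([px, py]),
                    "quadrant_shares": quad_shares,
                    "split": (float(mx), float(my))}
    return out
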