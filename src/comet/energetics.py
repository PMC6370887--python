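"""Relative power / relative cost: the π/4 rotation of standardized activity
and supply maps, with COMET histograms, quadrant occupancy and moments.

Given an activity index (log(lFCD) or fALFF) and a metabolic-supply index
(CMRglc or CBF), each standardized to zero mean and unit variance within the
gray-matter mask, a 45° counterclockwise rotation of the (activity, supply)
axes yields

    rPWR = (z_act + z_sup) / √2      (concurrent intensity of both)
    rCST = (z_sup − z_act) / √2      (excess of supply over activity)

Equivalently, in polar coordinates (R, θ) of each voxel,
rPWR = R·cos(θ − π/4) and rCST = R·sin(θ − π/4).  For positively correlated
standardized inputs this rotation coincides with PCA: the first principal
axis is exactly (1, 1)/√2.  Both outputs always have zero in-mask mean, are
uncorrelated, and split the variance as var(rPWR) = 1 + r, var(rCST) = 1 − r
where r is the in-mask correlation of the standardized pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volume_io import BrainMask, ScalarMap, check_grid_compatible

__all__ = [
    "StandardizedPair",
    "PowerCostMap",
    "CometHistogram",
    "QuadrantOccupancy",
    "QUADRANTS",
    "standardize",
    "rotate_power_cost",
    "verify_pca_equivalence",
    "comet_histogram",
    "quadrant_occupancy",
    "power_dominant_share",
    "distribution_moments",
    "power_cost_pipeline",
]

SQRT2 = np.sqrt(2.0)

#: Quadrant labels: hi/lo power (P) × hi/lo cost (C), split at the zero means.
QUADRANTS = ("hiP_hiC", "hiP_loC", "loP_hiC", "loP_loC")


class DegenerateMapError(ValueError):
    """Map has zero in-mask variance; standardization is undefined."""


def standardize(map: ScalarMap, mask: BrainMask | None = None) -> ScalarMap:
    """z-score within the mask: (x − mean) / SD with the population SD
    (divisor n), so the output has mean 0 and variance exactly 1."""
    mask = mask if mask is not None else map.mask
    if mask is not map.mask and not np.array_equal(mask.in_mask, map.mask.in_mask):
        raise ValueError("standardize: mask differs from the map's mask")
    mu = map.values.mean()
    sd = map.values.std()  # ddof=0: population SD
    if sd < 1e-300:
        raise DegenerateMapError("zero in-mask variance; cannot standardize")
    return map.with_values((map.values - mu) / sd, "z",
                           source_tag=map.quantity_tag, sd_divisor="n")


@dataclass(frozen=True)
class StandardizedPair:
    """Two z-scored maps on one grid/mask: activity and metabolic supply."""

    z_activity: ScalarMap
    z_supply: ScalarMap

    def __post_init__(self) -> None:
        a, s = self.z_activity, self.z_supply
        if not check_grid_compatible(a.grid, s.grid):
            raise ValueError("activity and supply maps live on different grids")
        if not np.array_equal(a.mask.in_mask, s.mask.in_mask):
            raise ValueError("activity and supply maps use different masks")
        for name, m in (("activity", a), ("supply", s)):
            if abs(m.values.mean()) > 1e-10 or abs(m.values.var() - 1.0) > 1e-10:
                raise ValueError(f"z_{name} is not standardized (mean 0, var 1)")

    @property
    def source_tags(self) -> tuple[str, str]:
        return (self.z_activity.meta.get("source_tag", "?"),
                self.z_supply.meta.get("source_tag", "?"))

    @property
    def correlation(self) -> float:
        """In-mask Pearson correlation (= mean product of the z-scores)."""
        return float(np.mean(self.z_activity.values * self.z_supply.values))

    def polar(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-voxel polar coordinates (R, θ) with θ ∈ (−π, π]."""
        x, y = self.z_activity.values, self.z_supply.values
        return np.hypot(x, y), np.arctan2(y, x)


@dataclass(frozen=True)
class PowerCostMap:
    """Paired voxelwise rPWR / rCST with the provenance of the two sources."""

    rpwr: ScalarMap
    rcst: ScalarMap
    source_tags: tuple[str, str] = ("?", "?")
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not np.array_equal(self.rpwr.mask.in_mask, self.rcst.mask.in_mask):
            raise ValueError("rPWR and rCST masks differ")

    @property
    def variance_split(self) -> tuple[float, float]:
        return float(self.rpwr.values.var()), float(self.rcst.values.var())


def rotate_power_cost(pair: StandardizedPair) -> PowerCostMap:
    """π/4 counterclockwise rotation of the standardized (activity, supply)
    axes: rPWR = (z_act + z_sup)/√2, rCST = (z_sup − z_act)/√2."""
    a, s = pair.z_activity.values, pair.z_supply.values
    rpwr = (a + s) / SQRT2
    rcst = (s - a) / SQRT2
    tags = pair.source_tags
    meta = {"source_tags": tags, "correlation": pair.correlation}
    return PowerCostMap(
        pair.z_activity.with_values(rpwr, "rPWR", **meta),
        pair.z_activity.with_values(rcst, "rCST", **meta),
        tags, meta,
    )


def rotate_power_cost_polar(pair: StandardizedPair) -> tuple[np.ndarray, np.ndarray]:
    """Polar form of the same rotation: R·cos(θ−π/4), R·sin(θ−π/4).

    Kept as an independent cross-check of the Cartesian implementation.
    """
    R, theta = pair.polar()
    return R * np.cos(theta - np.pi / 4), R * np.sin(theta - np.pi / 4)


def verify_pca_equivalence(pair: StandardizedPair) -> float:
    """Angle (radians) between the first principal axis of the standardized
    pair and the (1, 1)/√2 direction.

    For positively correlated standardized variables the leading eigenvector
    of their 2×2 correlation matrix is exactly (1, 1)/√2, so the deviation is
    numerically zero.  For r ≤ 0 the leading axis swaps to (−1, 1)/√2 and the
    equivalence no longer applies; a warning is emitted.
    """
    r = pair.correlation
    if r <= 0:
        warnings.warn(
            f"pair correlation r = {r:.4f} ≤ 0: first principal axis is not the "
            "rPWR direction; PCA equivalence does not apply", stacklevel=2,
        )
    X = np.column_stack([pair.z_activity.values, pair.z_supply.values])
    cov = (X.T @ X) / X.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    lead = eigvecs[:, np.argmax(eigvals)]
    target = np.array([1.0, 1.0]) / SQRT2
    # axis (sign-free) angle via atan2(cross, dot): numerically exact near 0,
    # where arccos would amplify rounding to ~1e-8
    cross = lead[0] * target[1] - lead[1] * target[0]
    dot = lead @ target
    return float(np.arctan2(abs(cross), abs(dot)))


@dataclass(frozen=True)
class CometHistogram:
    """2D in-mask histogram of an (activity, supply) association pair."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    axis_tags: tuple[str, str]
    pearson_r: float

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def comet_histogram(x: ScalarMap, y: ScalarMap, n_bins: int = 128) -> CometHistogram:
    """Connectivity–metabolism (COMET) map: joint frequency of the two voxel
    indices over the mask, plus their in-mask Pearson correlation."""
    if not check_grid_compatible(x.grid, y.grid) or \
            not np.array_equal(x.mask.in_mask, y.mask.in_mask):
        raise ValueError("COMET histogram needs maps on one grid and mask")
    counts, xe, ye = np.histogram2d(x.values, y.values, bins=n_bins)
    if x.values.std() == 0 or y.values.std() == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(x.values, y.values).statistic)
    return CometHistogram(xe, ye, counts, (x.quantity_tag, y.quantity_tag), r)


@dataclass(frozen=True)
class QuadrantOccupancy:
    """Per-quadrant 5×5 binning of the rPWR–rCST plane split at the (zero)
    whole-brain means, with per-quadrant overflow counts."""

    bins: dict          # quadrant label -> (nb, nb) counts over |value| ∈ [0, limit]
    overflow: dict      # quadrant label -> count outside the binning range
    totals: dict        # quadrant label -> total voxels in that quadrant
    range_limit: float
    bins_per_axis: int

    @property
    def shares(self) -> dict:
        """Quadrant totals as percent of all in-mask voxels."""
        grand = sum(self.totals.values())
        return {q: 100.0 * self.totals[q] / grand for q in QUADRANTS}


def quadrant_occupancy(pc: PowerCostMap, range_limit: float = 5.0,
                       bins_per_axis: int = 5) -> QuadrantOccupancy:
    """Energy-state occupancy: split voxels into the four quadrants of the
    rPWR–rCST plane at (0, 0) — the whole-brain means — and grid each
    quadrant ``bins_per_axis``² over |value| ∈ [0, range_limit] per axis.

    Voxels beyond the range accumulate in a per-quadrant overflow count, so
    quadrant totals always partition the mask exactly.  Values exactly at a
    mean are counted as "hi".
    """
    p, c = pc.rpwr.values, pc.rcst.values
    edges = np.linspace(0.0, range_limit, bins_per_axis + 1)
    bins, overflow, totals = {}, {}, {}
    for q in QUADRANTS:
        sel = ((p >= 0) if q.startswith("hiP") else (p < 0)) & \
              ((c >= 0) if q.endswith("hiC") else (c < 0))
        ap, ac = np.abs(p[sel]), np.abs(c[sel])
        inside = (ap <= range_limit) & (ac <= range_limit)
        h, _, _ = np.histogram2d(ap[inside], ac[inside], bins=[edges, edges])
        bins[q] = h
        overflow[q] = int((~inside).sum())
        totals[q] = int(sel.sum())
    return QuadrantOccupancy(bins, overflow, totals, range_limit, bins_per_axis)


def power_dominant_share(pc: PowerCostMap) -> float:
    """Percent of voxels in the high- and low-power quadrants of the source
    (activity, supply) plane.

    A voxel with concordant standardized activity and supply (z_act·z_sup > 0)
    sits in the high- or low-rPWR quadrant of that plane; algebraically this
    is exactly the set where |rPWR| > |rCST|.  For positively coupled inputs
    this share exceeds 50 % (orthant probability ½ + arcsin(r)/π under
    bivariate normality).  Note the four energy-state quadrants of
    :func:`quadrant_occupancy` split the *rotated* plane instead, where the
    two coordinates are uncorrelated and the diagonal share carries no such
    excess.
    """
    p, c = pc.rpwr.values, pc.rcst.values
    return float(100.0 * np.mean(np.abs(p) > np.abs(c)))


def distribution_moments(map: ScalarMap) -> tuple[float, float]:
    """Moment skewness m₃/m₂^{3/2} and Pearson kurtosis m₄/m₂² (normal → 3)."""
    v = np.asarray(map.values if isinstance(map, ScalarMap) else map, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for third/fourth moments")
    if v.std() == 0:
        raise DegenerateMapError("zero variance; moments undefined")
    skew = float(stats.skew(v, bias=True))
    kurt = float(stats.kurtosis(v, fisher=False, bias=True))
    return skew, kurt


def power_cost_pipeline(activity: ScalarMap, supply: ScalarMap,
                        mask: BrainMask | None = None) -> PowerCostMap:
    """Standardize an (activity, supply) pair and rotate into rPWR/rCST.

    Accepts any activity index (log_lFCD or fALFF) and supply index (CMRglc
    or CBF); provenance of the chosen pair is carried on the outputs.
    """
    pair = StandardizedPair(standardize(activity, mask), standardize(supply, mask))
    return rotate_power_cost(pair)
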