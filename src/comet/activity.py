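"""Voxelwise activity indices: lFCD by correlation-thresholded region growing,
its log transform, and fALFF.

lFCD treats each in-mask voxel as the seed of a local functional connectivity
graph: a voxel joins the seed's cluster when it is spatially contiguous with
the growing cluster (6/18/26 lattice adjacency) and its Pearson correlation
with the *seed* exceeds the threshold.  lFCD is the number of edges to the
seed through the grown cluster, i.e. cluster size minus one.  Because such
degree measures are roughly exponentially distributed, downstream analyses
use log(lFCD) (natural log, zero degrees floored at one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import BoldSeries, DegenerateSignalError
from .volume_io import ScalarMap

__all__ = [
    "LfcdConfig",
    "adjacency_structure",
    "local_fcd",
    "log_transform",
    "falff",
    "average_maps",
]

_ADJ_RANK = {6: 1, 18: 2, 26: 3}


def adjacency_structure(adjacency: int) -> np.ndarray:
    """3x3x3 boolean stencil for 6- (faces), 18- (+edges) or 26- (+corners)
    connectivity."""
    if adjacency not in _ADJ_RANK:
        raise ValueError(f"adjacency must be one of {sorted(_ADJ_RANK)}, got {adjacency}")
    return ndimage.generate_binary_structure(3, _ADJ_RANK[adjacency])


@dataclass(frozen=True)
class LfcdConfig:
    """lFCD parameters: seed-correlation threshold and lattice adjacency."""

    threshold: float = 0.6
    adjacency: int = 18

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.adjacency not in _ADJ_RANK:
            raise ValueError(f"adjacency must be one of {sorted(_ADJ_RANK)}")


def _neighbor_offsets(dims, adjacency: int) -> np.ndarray:
    """Flat-index offsets of the chosen stencil, as (n_neigh, 3) coordinate deltas."""
    st = adjacency_structure(adjacency)
    st[1, 1, 1] = False
    return np.argwhere(st) - 1


def _standardize_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean each row and scale to unit norm; rows with zero variance are
    zeroed (their correlation with anything is defined as 0)."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    out = np.zeros_like(centered)
    out[ok] = centered[ok] / norms[ok, None]
    return out, ok


def local_fcd(series: BoldSeries, config: LfcdConfig = LfcdConfig()) -> ScalarMap:
    """Local functional connectivity density for every in-mask seed voxel.

    For each seed, grow a cluster: start from the seed, repeatedly add any
    in-mask voxel adjacent to the current cluster whose correlation with the
    seed exceeds ``config.threshold``, until fixation.  The result equals the
    connected component (under ``config.adjacency``) containing the seed of
    the voxel set {seed} ∪ {v : corr(seed, v) > threshold}, so membership is
    independent of scan order.  lFCD(seed) = |cluster| - 1.
    """
    X, has_var = _standardize_rows(series.data)
    if not has_var.any():
        raise DegenerateSignalError("all voxels are temporally constant")

    mask = series.mask
    dims = mask.grid.dims
    coords = mask.coords
    # map lattice coordinate -> position in the in-mask vector; -1 = out of mask
    vox_id = np.full(dims, -1, dtype=np.int64)
    vox_id[tuple(coords.T)] = np.arange(mask.n_in)
    offsets = _neighbor_offsets(dims, config.adjacency)

    lfcd = np.zeros(mask.n_in, dtype=float)
    dims_arr = np.asarray(dims)
    for seed in range(mask.n_in):
        if not has_var[seed]:
            continue  # correlations with a flat seed are 0: no edges
        corr_ok = (X @ X[seed]) > config.threshold
        corr_ok[seed] = True
        in_cluster = np.zeros(mask.n_in, dtype=bool)
        in_cluster[seed] = True
        frontier = [seed]
        while frontier:
            cand = coords[frontier][:, None, :] + offsets[None, :, :]
            cand = cand.reshape(-1, 3)
            ok = np.all((cand >= 0) & (cand < dims_arr), axis=1)
            ids = vox_id[tuple(cand[ok].T)]
            ids = ids[ids >= 0]
            new = ids[corr_ok[ids] & ~in_cluster[ids]]
            new = np.unique(new)
            in_cluster[new] = True
            frontier = list(new)
        lfcd[seed] = in_cluster.sum() - 1

    return ScalarMap(series.grid, mask, lfcd, "lFCD",
                     {"threshold": config.threshold, "adjacency": config.adjacency})


def log_transform(lfcd: ScalarMap) -> ScalarMap:
    """Natural log of max(lFCD, 1): zero-degree voxels map to 0."""
    if lfcd.quantity_tag != "lFCD":
        raise ValueError("log_transform expects an lFCD map")
    if np.any(lfcd.values < 0):
        raise ValueError("lFCD values must be non-negative")
    return lfcd.with_values(np.log(np.maximum(lfcd.values, 1.0)), "log_lFCD")


def falff(series: BoldSeries, band_low: float = 0.01,
          band_high: float = 0.10) -> ScalarMap:
    """Fractional amplitude of low-frequency fluctuations.

    Per voxel: sum of Fourier amplitudes over [band_low, band_high] divided by
    the sum over (0, Nyquist].  Expects a full-spectrum (NOT band-pass
    filtered) series so the denominator is meaningful; motion should already
    be regressed out.  A Hann taper is applied before the FFT — without it,
    rectangular-window sidelobes leak a sizeable share of a narrowband
    signal's amplitude out of band, while the taper leaves the expected flat
    spectrum of broadband noise (and hence the band-fraction baseline)
    unchanged.
    """
    if any(h.startswith("bandpass") for h in series.history):
        raise ValueError("fALFF needs the full spectrum; do not band-pass first")
    n = series.n_frames
    freqs = np.fft.rfftfreq(n, d=series.tr)
    centered = series.data - series.data.mean(axis=1, keepdims=True)
    amp = np.abs(np.fft.rfft(centered * np.hanning(n), axis=1))
    nonzero = freqs > 0
    in_band = nonzero & (freqs >= band_low) & (freqs <= band_high)
    total = amp[:, nonzero].sum(axis=1)
    band = amp[:, in_band].sum(axis=1)
    vals = np.zeros(series.mask.n_in)
    scale = np.maximum(1.0, np.abs(series.data).max(axis=1))
    ok = (total > 0) & (series.data.std(axis=1) > 1e-12 * scale)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} zero-variance voxels assigned fALFF = 0",
                      stacklevel=2)
    vals[ok] = band[ok] / total[ok]
    return ScalarMap(series.grid, series.mask, vals, "fALFF",
                     {"band": (band_low, band_high)})


def average_maps(maps: list[ScalarMap]) -> ScalarMap:
    """Voxelwise average across sessions (applied AFTER any log transform)."""
    if not maps:
        raise ValueError("need at least one map")
    tag = maps[0].quantity_tag
    if any(m.quantity_tag != tag for m in maps):
        raise ValueError("all maps must share a quantity tag")
    stacked = np.stack([m.values for m in maps])
    return maps[0].with_values(stacked.mean(axis=0), n_sessions=len(maps))
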