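"""BOLD time-series preparation: band-pass filtering, motion scrubbing, nuisance regression.

The pipeline order is the one stated for the connectivity maps: band-pass
filter, then censor motion-corrupted frames (DVARS > 0.5 % or framewise
displacement > 0.5 mm), then regress residual motion out of each voxel's
series.  :func:`preprocess_pipeline` applies that order and logs it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .volume_io import BrainMask, VolumeGrid

__all__ = [
    "BoldSeries",
    "MotionRecord",
    "compute_dvars",
    "compute_fd",
    "scrub",
    "regress_nuisance",
    "bandpass",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)


class DegenerateSignalError(ValueError):
    """Signal has no usable variance (e.g. zero whole-series mean for DVARS)."""


class InsufficientFramesError(ValueError):
    """Too few frames remain after censoring."""


@dataclass(frozen=True)
class BoldSeries:
    """In-mask BOLD data, shape (n_in voxels, n retained frames).

    ``kept_frames`` records which original acquisition frames the columns
    correspond to; scrubbing subsets it but never reorders it.
    """

    grid: VolumeGrid
    mask: BrainMask
    data: np.ndarray  # (n_in, n_frames)
    tr: float
    kept_frames: np.ndarray = None  # original frame indices, strictly increasing
    history: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != self.mask.n_in:
            raise ValueError(
                f"data must be (n_in={self.mask.n_in}, n_frames), got {d.shape}"
            )
        if d.shape[1] < 2:
            raise ValueError("a BOLD series needs at least 2 frames")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        kf = self.kept_frames
        kf = np.arange(d.shape[1]) if kf is None else np.asarray(kf, dtype=int)
        if kf.shape != (d.shape[1],) or np.any(np.diff(kf) <= 0):
            raise ValueError("kept_frames must be strictly increasing, one per frame")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "kept_frames", kf)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_4d(cls, data4d: np.ndarray, grid: VolumeGrid, mask: BrainMask,
                tr: float) -> "BoldSeries":
        data4d = np.asarray(data4d, dtype=float)
        if data4d.ndim != 4:
            raise ValueError("expected a 4D (x, y, z, t) array")
        flat = data4d.reshape(-1, data4d.shape[3])[mask.flat_index]
        return cls(grid, mask, flat, tr)


@dataclass(frozen=True)
class MotionRecord:
    """Six rigid-body parameters per frame plus the derived FD/DVARS traces."""

    translations: np.ndarray  # (n_frames, 3) mm
    rotations: np.ndarray     # (n_frames, 3) radians
    fd: np.ndarray | None = None      # mm per frame
    dvars: np.ndarray | None = None   # percent per frame

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3 or r.shape != t.shape:
            raise ValueError("translations and rotations must both be (n_frames, 3)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("motion parameters must be finite")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)
        for name in ("fd", "dvars"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (t.shape[0],) or np.any(v < 0):
                    raise ValueError(f"{name} must be non-negative, one per frame")
                object.__setattr__(self, name, v)

    @classmethod
    def from_params(cls, params: np.ndarray) -> "MotionRecord":
        params = np.asarray(params, dtype=float)
        return cls(params[:, :3], params[:, 3:6])

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]

    def subset(self, frame_idx: np.ndarray) -> "MotionRecord":
        idx = np.asarray(frame_idx, dtype=int)
        return MotionRecord(
            self.translations[idx], self.rotations[idx],
            None if self.fd is None else self.fd[idx],
            None if self.dvars is None else self.dvars[idx],
        )


def compute_dvars(series: BoldSeries) -> np.ndarray:
    """Frame-to-frame RMS signal change as percent of the whole-series mean.

    dvars_t = RMS over in-mask voxels of (S_t - S_{t-1}), divided by the mean
    in-mask signal over the whole series, times 100.  Frame 0 is 0 by
    convention.
    """
    mean_signal = float(series.data.mean())
    if abs(mean_signal) < 1e-12:
        raise DegenerateSignalError("whole-series mean signal is zero; DVARS undefined")
    diffs = np.diff(series.data, axis=1)
    rms = np.sqrt(np.mean(diffs ** 2, axis=0))
    dvars = np.concatenate([[0.0], rms / abs(mean_signal) * 100.0])
    return dvars


def compute_fd(motion: MotionRecord, sphere_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement: sum of |Δtranslation| plus ``sphere_radius`` ×
    sum of |Δrotation| (rotations in radians projected onto a head-sized
    sphere).  Frame 0 is 0 by convention."""
    if motion.n_frames < 2:
        raise ValueError("FD needs at least 2 frames")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    return np.concatenate([[0.0], dt + sphere_radius * dr])


def scrub(series: BoldSeries, motion: MotionRecord, dvars_thr: float = 0.5,
          fd_thr: float = 0.5, min_frames: int = 50,
          fd_radius: float = 50.0) -> tuple[BoldSeries, MotionRecord]:
    """Censor frames with DVARS > ``dvars_thr`` (percent) or FD > ``fd_thr`` (mm).

    Returns the censored series and the identically subset motion record (with
    fd/dvars traces of the original series attached).  Raises
    :class:`InsufficientFramesError` when fewer than ``min_frames`` survive.
    """
    if dvars_thr <= 0 or fd_thr <= 0:
        raise ValueError("scrubbing thresholds must be positive")
    if motion.n_frames != series.n_frames:
        raise ValueError("motion record and series frame counts differ")
    dvars = motion.dvars if motion.dvars is not None else compute_dvars(series)
    fd = motion.fd if motion.fd is not None else compute_fd(motion, fd_radius)
    bad = (dvars > dvars_thr) | (fd > fd_thr)
    keep = np.flatnonzero(~bad)
    if keep.size < min_frames:
        raise InsufficientFramesError(
            f"only {keep.size} frames survive scrubbing (min_frames={min_frames})"
        )
    if bad.sum() > 0.1 * series.n_frames:
        warnings.warn(
            f"scrubbing removed {bad.sum()}/{series.n_frames} frames (>10%); "
            "band-pass filtering before censoring may have leaked spike energy",
            stacklevel=2,
        )
    out = BoldSeries(
        series.grid, series.mask, series.data[:, keep], series.tr,
        series.kept_frames[keep],
        series.history + (f"scrub(dvars>{dvars_thr}%, fd>{fd_thr}mm)",),
    )
    sub = MotionRecord(motion.translations[keep], motion.rotations[keep],
                       fd[keep], dvars[keep])
    return out, sub


def regress_nuisance(series: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Replace each voxel series with OLS residuals on [intercept | regressors]."""
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.shape[0] != series.n_frames:
        raise ValueError("regressor rows must match retained frames")
    X = np.column_stack([np.ones(series.n_frames), regressors])
    # drop exactly-duplicate/zero columns before rank check (all-zero regressors
    # are a legal no-op per the contract)
    keep_cols = [0] + [
        j for j in range(1, X.shape[1]) if np.abs(X[:, j]).max() > 0
    ]
    X = X[:, keep_cols]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("nuisance design is rank-deficient (collinear)")
    beta, *_ = np.linalg.lstsq(X, series.data.T, rcond=None)
    resid = series.data - (X @ beta).T
    return replace(series, data=resid,
                   history=series.history + (f"regress(k={regressors.shape[1]})",))


def bandpass(series: BoldSeries, low: float = 0.01, high: float = 0.10,
             order: int = 4) -> BoldSeries:
    """Zero-phase Butterworth band-pass per voxel (forward-backward filtering)."""
    nyq = 1.0 / (2.0 * series.tr)
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist {nyq:.4f}"
        )
    if series.n_frames < 60:
        warnings.warn("fewer than ~60 frames; band-pass filtering may be unstable",
                      stacklevel=2)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / series.tr,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=1)
    return replace(series, data=filtered,
                   history=series.history + (f"bandpass({low}-{high}Hz)",))


def preprocess_pipeline(series: BoldSeries, motion: MotionRecord,
                        low: float = 0.01, high: float = 0.10,
                        dvars_thr: float = 0.5, fd_thr: float = 0.5,
                        fd_radius: float = 50.0,
                        min_frames: int = 50) -> tuple[BoldSeries, MotionRecord]:
    """Fixed-order pipeline: band-pass -> scrub -> motion regression.

    DVARS for censoring is computed on the unfiltered series (the filter
    removes the mean signal the percent normalization needs); FD depends only
    on the motion parameters.  The motion regressors are band-pass filtered
    with the same filter as the data before regression, so motion-locked
    signal that survives the filter is matched by its regressor.
    """
    dvars = compute_dvars(series)
    fd = compute_fd(motion, fd_radius)
    motion = MotionRecord(motion.translations, motion.rotations, fd, dvars)
    log.info("pipeline order: bandpass(%.3g-%.3g Hz) -> scrub -> regress", low, high)
    filtered = bandpass(series, low, high)
    scrubbed, motion_kept = scrub(filtered, motion, dvars_thr, fd_thr, min_frames)
    params = np.column_stack([motion.translations, motion.rotations])
    sos = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / series.tr,
                        output="sos")
    params_f = signal.sosfiltfilt(sos, params, axis=0)
    keep_idx = np.searchsorted(series.kept_frames, scrubbed.kept_frames)
    regressors = params_f[keep_idx]
    regressors = regressors[:, regressors.std(axis=0) > 1e-12]  # constants = intercept
    cleaned = regress_nuisance(scrubbed, regressors)
    return cleaned, motion_kept
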