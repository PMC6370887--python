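"""Synthetic phantoms: coupled activity/supply maps, BOLD series with hub
regions and motion spikes, and multi-subject network cohorts.

These generators exist so the whole pipeline is exercisable with no external
data.  They emulate the structural features the indices rely on — spatially
autocorrelated scalar fields, a controllable voxelwise activity–supply
coupling, hubs of locally synchronous band-limited BOLD signal, frames
corrupted by head motion, and cohorts whose networks occupy distinct
positions in the (activity, supply) plane.  They do not attempt biophysical
realism (no hemodynamic response, physiological noise or PET count
statistics).

All generators are seed-deterministic: one spec + seed → bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .networks import NetworkAtlas
from .preprocess import BoldSeries, MotionRecord
from .volume_io import BrainMask, ScalarMap, VolumeGrid

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_coupled_pair",
    "make_bold_phantom",
    "make_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _smooth_field(rng: np.random.Generator, dims, fwhm_vox: float) -> np.ndarray:
    """Gaussian-smoothed white noise: a field with realistic spatial
    autocorrelation (smoothing width in voxels FWHM)."""
    field = rng.standard_normal(dims)
    if fwhm_vox > 0:
        field = ndimage.gaussian_filter(field, sigma=fwhm_vox * _FWHM_TO_SIGMA)
    return field


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the BOLD phantom.

    Hubs are spheres of voxels sharing one band-limited latent signal of the
    given amplitude (in noise-SD units); ``spike_frames`` receive persistent
    global-intensity and motion-parameter steps sized to trip both scrubbing
    thresholds at exactly those frames.
    """

    dims: tuple = (20, 20, 12)
    n_frames: int = 400
    tr: float = 1.5
    hub_definitions: tuple = (((10, 10, 6), 2, 2.0),)  # (center, radius, amplitude)
    coupling_r: float = 0.44
    noise_sd: float = 1.0
    baseline: float = 1000.0
    spike_frames: tuple = ()
    signal_step_pct: float = 1.5   # DVARS excursion of a spike, percent
    motion_step_mm: float = 0.8    # FD excursion of a spike, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling_r <= 1.0:
            raise ValueError("coupling_r must lie in [-1, 1]")
        if any(r < 0 for _, r, _ in self.hub_definitions):
            raise ValueError("hub radius must be non-negative")
        if self.n_frames < 2 or self.tr <= 0:
            raise ValueError("need n_frames >= 2 and tr > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Multi-subject cohort: network-offset templates plus subject noise.

    ``offsets`` is an (n_networks, 2) array of planted per-network positions
    in the (activity, supply) plane; each subject's map adds independent
    voxel noise of SD ``noise_sd`` on top of the template.  Real cohorts also
    carry subject-level global nuisance (scanner scaling, global metabolic
    level): ``subject_shift_sd`` / ``subject_scale_jitter`` add a random
    additive shift and multiplicative gain per subject and modality.  Within-
    subject standardization removes exactly this nuisance, which is why the
    rPWR–rCST embedding segregates networks better than the raw plane.
    """

    n_subjects: int = 10
    dims: tuple = (20, 20, 12)
    offsets: tuple = field(default_factory=lambda: tuple(
        (float(np.cos(a)), float(np.sin(a)))
        for a in np.linspace(0, 2 * np.pi, 10, endpoint=False)
    ))
    noise_sd: float = 0.1
    subject_shift_sd: float = 0.0
    subject_scale_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        off = np.asarray(self.offsets, dtype=float)
        if off.ndim != 2 or off.shape[1] != 2 or not np.all(np.isfinite(off)):
            raise ValueError("offsets must be a finite (n_networks, 2) array")

    @property
    def n_networks(self) -> int:
        return len(self.offsets)


def make_coupled_pair(dims=(20, 20, 12), coupling_r: float = 0.44, seed: int = 0,
                      smooth_fwhm_vox: float = 2.0, n_in: int | None = None,
                      activity_scale=(2.0, 0.5), supply_scale=(30.0, 6.0),
                      ) -> tuple[ScalarMap, ScalarMap]:
    """Two spatially smooth scalar maps whose in-mask correlation equals
    ``coupling_r``.

    The supply field is built as r × (standardized latent activity) +
    √(1 − r²) × (standardized residual of an independent field), with the
    residualization done empirically so the realized in-mask correlation
    matches the target to numerical precision.  Both maps are then put on
    "raw" scales (mean, SD) mimicking log(lFCD) and CMRglc units —
    standardization downstream removes them again.

    ``n_in`` optionally restricts the mask to the first ``n_in`` voxels in
    the canonical ordering, to hit an exact voxel count.
    """
    if not -1.0 <= coupling_r <= 1.0:
        raise ValueError("coupling_r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    grid = VolumeGrid.isotropic(dims)
    in_mask = np.ones(dims, dtype=bool)
    if n_in is not None:
        if not 1 <= n_in <= in_mask.size:
            raise ValueError(f"n_in must be in [1, {in_mask.size}]")
        flat = np.zeros(in_mask.size, dtype=bool)
        flat[:n_in] = True
        in_mask = flat.reshape(dims)
    mask = BrainMask(grid, in_mask)

    a = _zscore(_smooth_field(rng, dims, smooth_fwhm_vox).reshape(-1)[mask.flat_index])
    b = _zscore(_smooth_field(rng, dims, smooth_fwhm_vox).reshape(-1)[mask.flat_index])
    b = b - float(np.mean(a * b)) * a          # empirical residual against a
    if np.linalg.norm(b) > 0:
        b = _zscore(b)
    z_supply = coupling_r * a + np.sqrt(max(0.0, 1.0 - coupling_r ** 2)) * b

    act = activity_scale[0] + activity_scale[1] * a
    sup = supply_scale[0] + supply_scale[1] * z_supply
    return (
        ScalarMap(grid, mask, act, "log_lFCD", {"synthetic": True}),
        ScalarMap(grid, mask, sup, "CMRglc",
                  {"synthetic": True, "coupling_r": coupling_r}),
    )


def _bandlimited_signal(rng: np.random.Generator, n_frames: int, tr: float,
                        low: float = 0.01, high: float = 0.10) -> np.ndarray:
    """Unit-SD noise band-limited to the slow-fluctuation range."""
    white = rng.standard_normal(n_frames)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    sig = signal.sosfiltfilt(sos, white)
    return sig / sig.std()


def make_bold_phantom(spec: PhantomSpec = PhantomSpec()
                      ) -> tuple[BoldSeries, MotionRecord, np.ndarray]:
    """BOLD phantom with hubs of shared band-limited signal and motion spikes.

    Returns the series, a motion record, and the boolean in-mask hub
    ground-truth vector.  Hub voxels carry a common 0.01–0.1 Hz latent signal
    (amplitude in units of the voxel noise SD) so their seed correlations
    exceed the lFCD threshold; background voxels are pure noise.  Spike
    frames get persistent steps in global intensity and in the x-translation,
    each sized to exceed the DVARS 0.5 % and FD 0.5 mm thresholds at exactly
    the planted frame.
    """
    rng = np.random.default_rng(spec.seed)
    dims = spec.dims
    grid = VolumeGrid.isotropic(dims)
    mask = BrainMask(grid, np.ones(dims, dtype=bool))
    n_vox, n_t = mask.n_in, spec.n_frames

    data = spec.baseline + spec.noise_sd * rng.standard_normal((n_vox, n_t))
    hub_flat = np.zeros(n_vox, dtype=bool)
    coords = mask.coords
    for center, radius, amplitude in spec.hub_definitions:
        d2 = ((coords - np.asarray(center)) ** 2).sum(axis=1)
        members = d2 <= radius ** 2
        latent = _bandlimited_signal(rng, n_t, spec.tr)
        data[members] += spec.noise_sd * amplitude * latent
        hub_flat |= members

    translations = 0.005 * rng.standard_normal((n_t, 3))
    rotations = 0.0001 * rng.standard_normal((n_t, 3))
    for f in spec.spike_frames:
        if not 1 <= f < n_t:
            raise ValueError(f"spike frame {f} outside [1, {n_t - 1}]")
        data[:, f:] += spec.baseline * spec.signal_step_pct / 100.0
        translations[f:, 0] += spec.motion_step_mm

    series = BoldSeries(grid, mask, data, spec.tr)
    motion = MotionRecord(translations, rotations)
    return series, motion, hub_flat


def make_cohort(spec: CohortSpec = CohortSpec()
                ) -> tuple[list[tuple[ScalarMap, ScalarMap]], NetworkAtlas]:
    """Cohort of per-subject (activity, supply) map pairs over a block atlas.

    The atlas partitions the in-mask voxels into ``n_networks`` equal slabs
    (canonical voxel order).  Subject maps are the planted network offsets
    plus independent Gaussian voxel noise, so ``network_means`` recovers the
    offsets up to noise / √(voxels per network).
    """
    rng = np.random.default_rng(spec.seed)
    grid = VolumeGrid.isotropic(spec.dims)
    mask = BrainMask(grid, np.ones(spec.dims, dtype=bool))
    n_vox = mask.n_in
    if spec.n_networks > n_vox:
        raise ValueError("more networks than voxels")

    labels_in = 1 + (np.arange(n_vox) * spec.n_networks) // n_vox
    atlas = NetworkAtlas(grid, mask, mask.embed(labels_in.astype(float)).astype(int))

    off = np.asarray(spec.offsets, dtype=float)
    template_act = off[labels_in - 1, 0]
    template_sup = off[labels_in - 1, 1]
    subjects = []
    for _ in range(spec.n_subjects):
        act = template_act + spec.noise_sd * rng.standard_normal(n_vox)
        sup = template_sup + spec.noise_sd * rng.standard_normal(n_vox)
        if spec.subject_scale_jitter > 0:
            act = act * (1.0 + spec.subject_scale_jitter * abs(rng.standard_normal()))
            sup = sup * (1.0 + spec.subject_scale_jitter * abs(rng.standard_normal()))
        if spec.subject_shift_sd > 0:
            act = act + spec.subject_shift_sd * rng.standard_normal()
            sup = sup + spec.subject_shift_sd * rng.standard_normal()
        subjects.append((
            ScalarMap(grid, mask, act, "log_lFCD", {"synthetic": True}),
            ScalarMap(grid, mask, sup, "CMRglc", {"synthetic": True}),
        ))
    return subjects, atlas
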