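"""Volumetric I/O and the in-mask voxel indexing shared by every other module.

All volumes are NIfTI-1 (``.nii`` / ``.nii.gz``) read and written with
:mod:`nibabel`.  Algorithms downstream operate on the flat vector of in-mask
voxels; the mapping between that vector and the 3D lattice is fixed here once:
row-major (C-order) over the volume axes, 0-based voxel indices, world
coordinates ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "BrainMask",
    "ScalarMap",
    "QUANTITY_TAGS",
    "read_volume",
    "read_mask",
    "write_map",
    "check_grid_compatible",
]

#: Recognised quantity tags for :class:`ScalarMap`.
QUANTITY_TAGS = frozenset(
    {"lFCD", "log_lFCD", "CMRglc", "CBF", "fALFF", "z", "rPWR", "rCST", "raw"}
)


class VolumeFormatError(ValueError):
    """The file is not a parseable NIfTI-1 volume."""


class VolumeShapeError(ValueError):
    """Volume dimensionality does not match what the caller expected."""


class GridCompatibilityError(ValueError):
    """Two volumes do not live on the same voxel lattice."""


@dataclass(frozen=True)
class VolumeGrid:
    """The voxel lattice: shape, spacing and voxel-to-world affine."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    orientation_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be a triple of positive ints, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", aff)
        if not self.orientation_tag:
            object.__setattr__(
                self, "orientation_tag", "".join(nib.aff2axcodes(aff))
            )

    @classmethod
    def from_img(cls, img: nib.spatialimages.SpatialImage) -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(
            dims=tuple(int(d) for d in img.shape[:3]),
            voxel_size=tuple(float(z) for z in zooms),
            affine=np.asarray(img.affine, dtype=float),
        )

    @classmethod
    def isotropic(cls, dims, voxel_mm: float = 2.0) -> "VolumeGrid":
        """Convenience grid with a diagonal affine — the phantom default."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(int(d) for d in dims), (voxel_mm,) * 3, aff)


def check_grid_compatible(a: VolumeGrid, b: VolumeGrid, tol: float = 1e-6) -> bool:
    """True iff the two grids have equal dims and affines agreeing within ``tol``."""
    return a.dims == b.dims and bool(np.all(np.abs(a.affine - b.affine) <= tol))


def _require_compatible(a: VolumeGrid, b: VolumeGrid, what: str) -> None:
    if not check_grid_compatible(a, b):
        raise GridCompatibilityError(f"{what}: grids differ ({a.dims} vs {b.dims})")


@dataclass(frozen=True)
class BrainMask:
    """Binary gray-matter mask with the canonical in-mask linear ordering.

    ``flat_index`` enumerates in-mask voxels in row-major order over the
    lattice; this ordering is deterministic and identical across calls, so a
    flat vector of length ``n_in`` is an unambiguous voxel map.
    """

    grid: VolumeGrid
    in_mask: np.ndarray  # boolean, shape == grid.dims

    def __post_init__(self) -> None:
        m = np.asarray(self.in_mask, dtype=bool)
        if m.shape != self.grid.dims:
            raise ValueError("mask shape does not match grid dims")
        if not m.any():
            raise ValueError("mask must contain at least one voxel")
        object.__setattr__(self, "in_mask", m)

    @property
    def n_in(self) -> int:
        return int(self.in_mask.sum())

    @property
    def flat_index(self) -> np.ndarray:
        """Row-major flat indices of in-mask voxels (fixed ordering)."""
        return np.flatnonzero(self.in_mask.reshape(-1))

    @property
    def coords(self) -> np.ndarray:
        """(n_in, 3) integer voxel coordinates, same ordering as flat_index."""
        return np.column_stack(np.unravel_index(self.flat_index, self.grid.dims))

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an in-mask vector back into a full 3D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_in,):
            raise ValueError(f"expected {self.n_in} in-mask values, got {values.shape}")
        out = np.full(int(np.prod(self.grid.dims)), fill, dtype=float)
        out[self.flat_index] = values
        return out.reshape(self.grid.dims)


@dataclass(frozen=True)
class ScalarMap:
    """One real value per in-mask voxel, with provenance via ``quantity_tag``."""

    grid: VolumeGrid
    mask: BrainMask
    values: np.ndarray  # shape (mask.n_in,)
    quantity_tag: str = "raw"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        _require_compatible(self.grid, self.mask.grid, "ScalarMap")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.mask.n_in,):
            raise ValueError(
                f"values length {v.shape} != mask n_in {self.mask.n_in}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("ScalarMap values must be finite for all in-mask voxels")
        if self.quantity_tag not in QUANTITY_TAGS:
            raise ValueError(f"unknown quantity_tag {self.quantity_tag!r}")
        object.__setattr__(self, "values", v)

    def with_values(self, values: np.ndarray, quantity_tag: str | None = None,
                    **meta) -> "ScalarMap":
        return ScalarMap(
            self.grid, self.mask, values,
            quantity_tag if quantity_tag is not None else self.quantity_tag,
            {**self.meta, **meta},
        )

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        return self.mask.embed(self.values, fill=fill)


def _load_img(path) -> nib.spatialimages.SpatialImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types for bad headers
        raise VolumeFormatError(f"could not parse {path} as NIfTI: {exc}") from exc


def read_volume(path, expected_kind: str, mask: BrainMask | None = None):
    """Read a NIfTI volume.

    ``expected_kind`` is ``"3D"`` or ``"4D"``.  For 3D, a :class:`ScalarMap` is
    returned when a mask is supplied (NaN inside the mask is a hard error since
    downstream standardization needs a well-defined voxel set), otherwise the
    raw 3D array plus its grid.  For 4D, the raw (x, y, z, t) array plus grid.
    """
    if expected_kind not in ("3D", "4D"):
        raise ValueError("expected_kind must be '3D' or '4D'")
    img = _load_img(path)
    data = np.asanyarray(img.dataobj)
    ndim = data.ndim
    if ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
        ndim = 3
    want = 3 if expected_kind == "3D" else 4
    if ndim != want:
        raise VolumeShapeError(
            f"{path}: expected a {expected_kind} volume, got {ndim}D shape {data.shape}"
        )
    grid = VolumeGrid.from_img(img)
    data = np.asarray(data, dtype=float)
    if expected_kind == "4D":
        return data, grid
    if mask is None:
        return data, grid
    _require_compatible(grid, mask.grid, str(path))
    vals = data.reshape(-1)[mask.flat_index]
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{path}: non-finite values inside the mask")
    return ScalarMap(grid, mask, vals)


def read_mask(path) -> BrainMask:
    """Read a binary (or probabilistic, thresholded at > 0.5) mask volume."""
    img = _load_img(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeShapeError(f"{path}: mask must be 3D, got shape {data.shape}")
    grid = VolumeGrid.from_img(img)
    data = np.asarray(data, dtype=float)
    uniq = np.unique(data)
    if set(uniq.tolist()) <= {0.0, 1.0}:
        m = data > 0
    else:
        m = data > 0.5  # probabilistic map
    return BrainMask(grid, m)


def write_map(map_or_volume, path, mask: BrainMask | None = None,
              dtype=np.float64) -> None:
    """Write a ScalarMap (embedded in its mask), a 3D or a 4D array to NIfTI."""
    if isinstance(map_or_volume, ScalarMap):
        vol = map_or_volume.to_volume()
        affine = map_or_volume.grid.affine
    else:
        vol = np.asarray(map_or_volume)
        if mask is not None:
            affine = mask.grid.affine
        else:
            affine = np.eye(4)
    img = nib.Nifti1Image(vol.astype(dtype), affine)
    nib.save(img, str(path))


def read_motion_params(path) -> np.ndarray:
    """Whitespace-delimited motion table: 6 columns per frame.

    Columns 0-2 are translations (mm), 3-5 rotations (radians).
    """
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {arr.shape[1]}")
    return arr.astype(float)
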