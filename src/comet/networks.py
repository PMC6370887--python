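"""ROI/network summaries of voxel maps and the network segregation index (NSI).

The NSI quantifies how well a network separates from the others when each
subject contributes one 2D point per network (e.g. that subject's mean rPWR
and mean rCST over the network's voxels).  For network i with center of mass
CM_i (coordinate-wise mean over subjects):

    AWND_i = mean Euclidean distance of network-i subject points to CM_i
    ABND_i = mean Euclidean distance from CM_i to the other networks' CMs
    NSI_i  = ABND_i / AWND_i

The ratio is dimensionless: invariant to rigid motions and to uniform
scaling of the whole point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import BrainMask, ScalarMap, VolumeGrid, check_grid_compatible

__all__ = [
    "NetworkAtlas",
    "NetworkEmbedding",
    "network_means",
    "network_segregation_index",
    "embed_cohort",
    "compare_nsi",
]


class UndefinedNsiError(ValueError):
    """AWND is zero (coincident points) so the ratio is undefined."""


@dataclass(frozen=True)
class NetworkAtlas:
    """Integer-labeled parcellation; 0 = unassigned."""

    grid: VolumeGrid
    mask: BrainMask
    labels: np.ndarray  # integer per voxel, shape == grid.dims
    names: dict = field(default_factory=dict)  # label -> network name

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.dims:
            raise ValueError("label volume shape does not match grid")
        if np.any(lab < 0):
            raise ValueError("labels must be non-negative integers")
        lab = lab.astype(np.int64)
        object.__setattr__(self, "labels", lab)
        present = set(np.unique(lab).tolist()) - {0}
        names = dict(self.names) if self.names else {
            int(l): f"network{int(l)}" for l in sorted(present)
        }
        missing = [l for l in names if l not in present]
        if missing:
            raise ValueError(f"named labels with no voxels: {missing}")
        object.__setattr__(self, "names", names)

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.names)


def network_means(map: ScalarMap, atlas: NetworkAtlas) -> pd.Series:
    """Arithmetic mean of in-mask voxel values per atlas label.

    Unassigned (label 0) voxels are ignored; a label with no in-mask voxels
    raises, naming the offending label.
    """
    if not check_grid_compatible(map.grid, atlas.grid):
        raise ValueError("map and atlas grids differ")
    lab_in = atlas.labels.reshape(-1)[map.mask.flat_index]
    means = {}
    for l in atlas.label_ids:
        sel = lab_in == l
        if not sel.any():
            raise ValueError(
                f"network {l} ({atlas.names[l]}) has no voxels inside the mask"
            )
        means[atlas.names[l]] = float(map.values[sel].mean())
    return pd.Series(means, name=map.quantity_tag)


@dataclass(frozen=True)
class NetworkEmbedding:
    """Per-(subject, network) 2D points with the derived CM/AWND/ABND/NSI."""

    points: pd.DataFrame       # index (subject, network), columns (x, y)
    centers: pd.DataFrame      # per network: CM coordinates
    awnd: pd.Series
    abnd: pd.Series
    nsi: pd.Series


def network_segregation_index(points: pd.DataFrame) -> NetworkEmbedding:
    """NSI per network from a (subject, network)-indexed table of 2D points.

    ``points`` needs a 2-level index (subject, network) and exactly two
    columns.  Every network must have ≥ 2 subjects, and there must be ≥ 2
    networks.  A network whose subject points coincide exactly (AWND 0)
    raises :class:`UndefinedNsiError`.
    """
    if points.shape[1] != 2:
        raise ValueError("embedding must be 2D (exactly two columns)")
    if points.index.nlevels != 2:
        raise ValueError("points need a (subject, network) MultiIndex")
    networks = points.index.get_level_values(1).unique()
    if len(networks) < 2:
        raise ValueError("need at least 2 networks")
    counts = points.groupby(level=1).size()
    if (counts < 2).any():
        few = counts[counts < 2].index.tolist()
        raise ValueError(f"networks with a single subject point: {few}")

    centers = points.groupby(level=1).mean().loc[networks]
    awnd, abnd, nsi = {}, {}, {}
    cm = centers.to_numpy(dtype=float)
    for i, net in enumerate(networks):
        pts = points.xs(net, level=1).to_numpy(dtype=float)
        d_within = np.linalg.norm(pts - cm[i], axis=1)
        awnd[net] = float(d_within.mean())
        others = np.delete(cm, i, axis=0)
        abnd[net] = float(np.linalg.norm(others - cm[i], axis=1).mean())
        if awnd[net] == 0.0:
            raise UndefinedNsiError(
                f"network {net!r}: all subject points coincide (AWND = 0)"
            )
        nsi[net] = abnd[net] / awnd[net]
    return NetworkEmbedding(points, centers,
                            pd.Series(awnd, name="AWND"),
                            pd.Series(abnd, name="ABND"),
                            pd.Series(nsi, name="NSI"))


def embed_cohort(subject_maps: list[tuple[ScalarMap, ScalarMap]],
                 atlas: NetworkAtlas) -> pd.DataFrame:
    """Build the (subject, network) 2D point table from per-subject map pairs.

    Each subject contributes, per network, the pair of that network's mean
    values in the two maps (e.g. mean rPWR, mean rCST).
    """
    rows = []
    for s, (mx, my) in enumerate(subject_maps):
        xm = network_means(mx, atlas)
        ym = network_means(my, atlas)
        for net in xm.index:
            rows.append((s, net, xm[net], ym[net]))
    df = pd.DataFrame(rows, columns=["subject", "network", "x", "y"])
    return df.set_index(["subject", "network"])


def compare_nsi(nsi_a: pd.Series, nsi_b: pd.Series):
    """Wilcoxon signed-rank test of paired per-network NSI values between two
    embedding spaces.  Routine statistics, exposed as a convenience."""
    a, b = nsi_a.align(nsi_b, join="inner")
    return stats.wilcoxon(a.to_numpy(), b.to_numpy())
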