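"""ROI bookkeeping: label volumes, ROI-mean time series, centroids, link lengths.

A parcellation assigns every voxel to at most one ROI (integer labels,
0 = background).  Network nodes are ROIs; a node's signal is the
unweighted mean of its in-mask member voxel series.  Link lengths are
Euclidean mm distances between ROI centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import distance_matrix as _distance_matrix

from .core import BrainVolume4D, VolumeGrid

__all__ = [
    "Parcellation",
    "roi_time_series",
    "roi_centroids",
    "link_lengths",
    "make_fixed_size_rois",
]


@dataclass
class Parcellation:
    """Nonoverlapping integer ROI labels on a grid (0 = background, 1..R ROIs)."""

    grid: VolumeGrid
    labels: np.ndarray
    names: list[str] | None = None
    system: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.shape != self.grid.dims:
            raise ValueError(f"label shape {self.labels.shape} != grid dims {self.grid.dims}")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        r = int(self.labels.max())
        if r < 1:
            raise ValueError("parcellation has no ROIs")
        present = np.unique(self.labels)
        missing = sorted(set(range(1, r + 1)) - set(int(v) for v in present))
        if missing:
            raise ValueError(f"ROI ids with no voxels: {missing}")
        for attr in ("names", "system"):
            vals = getattr(self, attr)
            if vals is not None and len(vals) != r:
                raise ValueError(f"{attr} must have length {r}")

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())

    def roi_voxel_indices(self, roi: int) -> np.ndarray:
        return np.argwhere(self.labels == roi)


def roi_time_series(volume: BrainVolume4D, parc: Parcellation) -> np.ndarray:
    """Average in-mask voxel series within each ROI → (R, T) array."""
    if parc.grid.dims != volume.grid.dims:
        raise ValueError(
            f"parcellation grid {parc.grid.dims} does not match volume grid {volume.grid.dims}"
        )
    r = parc.n_rois
    out = np.empty((r, volume.n_timepoints), dtype=np.float64)
    for roi in range(1, r + 1):
        members = (parc.labels == roi) & volume.mask
        n = int(members.sum())
        if n == 0:
            raise ValueError(f"ROI {roi} has no in-mask voxels")
        out[roi - 1] = volume.data[members].mean(axis=0)
    return out


def roi_centroids(parc: Parcellation) -> np.ndarray:
    """(R, 3) mm coordinates: mean of member-voxel centers per ROI."""
    r = parc.n_rois
    out = np.empty((r, 3), dtype=np.float64)
    for roi in range(1, r + 1):
        idx = parc.roi_voxel_indices(roi)
        out[roi - 1] = parc.grid.voxel_centers_mm(idx).mean(axis=0)
    return out


def link_lengths(centroids: np.ndarray) -> np.ndarray:
    """Symmetric R×R matrix of Euclidean mm distances between ROI centroids."""
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("centroids must be an (R, 3) array")
    return _distance_matrix(c, c)


_FACE_NEIGHBOURS = np.array(
    [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def make_fixed_size_rois(parc: Parcellation) -> Parcellation:
    """Replace every ROI by a fixed 7-voxel digital sphere at its centroid.

    The sphere is the voxel containing the centroid plus its six
    face-adjacent voxels — the only 7-voxel digital sphere, matching the
    maximum size at which equally sized spheres need not overlap.  A
    sphere clipped by the grid edge or overlapping another is an error
    (the fixed-size contract is never silently violated).
    """
    cents = roi_centroids(parc)
    grid = parc.grid
    dims = np.asarray(grid.dims)
    vox = np.asarray(grid.voxel_size)
    origin = np.asarray(grid.origin)
    # nearest voxel center; exact ties resolved toward the lower index
    u = (cents - origin) / vox
    center_idx = np.ceil(u - 1.0).astype(int)
    labels = np.zeros(grid.dims, dtype=np.int32)
    owner: dict[tuple[int, int, int], int] = {}
    overlaps: set[tuple[int, int]] = set()
    for roi in range(1, parc.n_rois + 1):
        c = center_idx[roi - 1]
        if np.any(c < 0) or np.any(c >= dims):
            raise ValueError(f"centroid of ROI {roi} falls outside the grid")
        for off in _FACE_NEIGHBOURS:
            v = c + off
            if np.any(v < 0) or np.any(v >= dims):
                raise ValueError(
                    f"7-voxel sphere of ROI {roi} is clipped by the grid edge at {tuple(v)}"
                )
            key = (int(v[0]), int(v[1]), int(v[2]))
            if key in owner:
                overlaps.add((owner[key], roi))
            else:
                owner[key] = roi
                labels[key] = roi
    if overlaps:
        pairs = sorted(overlaps)
        raise ValueError(f"fixed-size spheres overlap for ROI pairs: {pairs}")
    return Parcellation(grid, labels, names=parc.names, system=parc.system)
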