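"""Core data containers shared across the pipeline.

A :class:`BrainVolume4D` is a masked voxel time-series block on a regular
3D grid; it is the object spatial smoothing acts on.  A
:class:`SubjectRecord` carries the per-subject phenotype/nuisance fields
(group, scan site, mean framewise displacement, gender) used by the
link-wise confound regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "BrainVolume4D", "SubjectRecord"]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3D voxel grid with a voxel→mm coordinate convention.

    The mm-space center of voxel (i, j, k) is
    ``origin + (index + 0.5) * voxel_size`` per axis, so ROI centroid
    distances (link lengths) are physical distances.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be positive per axis, got {self.voxel_size}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """mm coordinates of the centers of voxels given as an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.voxel_size)


@dataclass
class BrainVolume4D:
    """Masked voxel time series: ``data[i, j, k, t]`` with a boolean brain mask.

    Out-of-mask voxels carry no signal (stored as zeros and never read by
    any operation).  All in-mask series share the same length T >= 2.
    """

    grid: VolumeGrid
    mask: np.ndarray
    data: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.mask.shape != self.grid.dims:
            raise ValueError(f"mask shape {self.mask.shape} != grid dims {self.grid.dims}")
        if self.data.ndim != 4 or self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("time series must have length T >= 2")
        if self.tr <= 0:
            raise ValueError("TR must be positive (seconds)")
        if not self.mask.any():
            raise ValueError("mask is empty: no in-brain voxels")
        # enforce the "no series outside the mask" contract
        self.data[~self.mask] = 0.0

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "BrainVolume4D":
        return BrainVolume4D(self.grid, self.mask.copy(), self.data.copy(), self.tr)


@dataclass(frozen=True)
class SubjectRecord:
    """Phenotype row for one subject: diagnosis group plus nuisance covariates."""

    id: str
    group: str  # "patient" or "control"
    site: str = "site0"
    mean_fd: float = 0.0  # mean framewise displacement, mm
    gender: str = "F"

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        if self.mean_fd < 0:
            raise ValueError("mean FD must be nonnegative")
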