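"""Synthetic two-group resting-state cohorts with a planted group-difference
subnetwork.

The generator emulates the ingredients the downstream pipeline is
sensitive to: band-limited (default 0.01–0.08 Hz at TR = 2 s) ROI-level
signals with a prescribed correlation structure; a connected set of
links whose correlation is raised by ``delta`` in the patient group;
within-ROI voxel noise with configurable intrinsic spatial smoothness;
and nuisance structure (per-site link offsets and motion-correlated
shifts) injected at the Fisher-z link level — exactly the level at which
the confound regression removes it.  Every quantity is reproducible from
the cohort seed, and the ground truth (achieved post-repair contrast,
nuisance contributions) is kept for acceptance checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import BrainVolume4D, SubjectRecord, VolumeGrid
from .parcellation import Parcellation
from .smoothing import SmoothingKernel, smooth_array

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "make_group_covariances",
    "generate_roi_series",
    "generate_subject_volume",
    "make_block_parcellation",
    "generate_cohort",
]

DEFAULT_PLANTED_LINKS: tuple[tuple[int, int], ...] = ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5))


def _links_connected(links) -> bool:
    links = [tuple(l) for l in links]
    if not links:
        return True
    nodes = set()
    for a, b in links:
        nodes.update((a, b))
    seen = {links[0][0]}
    frontier = [links[0][0]]
    adj: dict[int, list[int]] = {n: [] for n in nodes}
    for a, b in links:
        adj[a].append(b)
        adj[b].append(a)
    while frontier:
        cur = frontier.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return seen == nodes


@dataclass(frozen=True)
class CohortSpec:
    """Study-design knobs for a synthetic two-group cohort.

    Defaults describe a small but fully powered comparison: 20 subjects
    per group, 12 ROIs of 8 voxels on a 2 mm grid, T = 512 samples at
    TR = 2 s band-limited to 0.01–0.08 Hz, a 5-link connected chain whose
    correlation is 0.4 higher in patients over an r0 = 0.1 background,
    unit-variance voxel noise with 4 mm intrinsic smoothness, two scan
    sites and a weak motion effect.
    """

    n_per_group: int = 20
    n_rois: int = 12
    roi_voxels: int = 8
    T: int = 512
    tr: float = 2.0
    band: tuple[float, float] = (0.01, 0.08)
    r0: float = 0.1
    planted_links: tuple[tuple[int, int], ...] = DEFAULT_PLANTED_LINKS
    delta: float = 0.4
    voxel_noise_sd: float = 1.0
    intrinsic_fwhm: float = 4.0
    n_sites: int = 2
    site_effect_sd: float = 0.1
    fd_effect_slope: float = 0.3
    seed: int = 0
    voxel_size_mm: float = 2.0
    gap_voxels: int = 2
    background: str = "all"  # r0 on all off-diagonal links ("all") or none ("none")

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group (F statistic undefined below)")
        if not -1 < self.r0 < 1:
            raise ValueError("r0 must lie in (-1, 1)")
        if abs(self.r0) + abs(self.delta) >= 1:
            raise ValueError(
                f"|r0| + |delta| = {abs(self.r0) + abs(self.delta):.3f} >= 1: "
                "the requested patient correlations cannot form a correlation matrix"
            )
        links = tuple(tuple(sorted((int(a), int(b)))) for a, b in self.planted_links)
        if any(a == b for a, b in links):
            raise ValueError("planted links must join distinct ROIs")
        if any(b >= self.n_rois for _, b in links):
            raise ValueError("planted link indices must be < n_rois")
        if not _links_connected(links):
            raise ValueError("planted links must form a connected set on their incident nodes")
        object.__setattr__(self, "planted_links", links)
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.background not in ("all", "none"):
            raise ValueError("background must be 'all' or 'none'")
        f_lo, f_hi = self.band
        if not (0 <= f_lo < f_hi <= 1.0 / (2.0 * self.tr) + 1e-12):
            raise ValueError("band must satisfy 0 <= f_lo < f_hi <= Nyquist")


@dataclass
class GroundTruth:
    """What was actually planted, after positive-semidefinite repair."""

    planted_links: tuple[tuple[int, int], ...]
    control_cov: np.ndarray
    patient_cov: np.ndarray
    achieved_delta: dict[tuple[int, int], float]
    nuisance_z: dict[str, np.ndarray] = field(default_factory=dict)  # subject id -> (L,) z offsets

    @property
    def mean_achieved_delta(self) -> float:
        return float(np.mean(list(self.achieved_delta.values())))


@dataclass
class Cohort:
    """A generated cohort: subject records plus their data and bookkeeping."""

    spec: CohortSpec
    subjects: list[SubjectRecord]
    ground_truth: GroundTruth
    parcellation: Parcellation | None = None
    volumes: list[BrainVolume4D] | None = None
    roi_series: list[np.ndarray] | None = None

    def __iter__(self):
        data = self.volumes if self.volumes is not None else self.roi_series
        return iter(zip(self.subjects, data))


def _nearest_psd_corr(c: np.ndarray) -> np.ndarray:
    """Eigenvalue-clip to the PSD cone, then re-normalize to unit diagonal."""
    w, v = np.linalg.eigh(c)
    if w.min() >= -1e-12:
        return c
    w = np.clip(w, 0.0, None)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(c2), 1e-12, None))
    c2 = c2 / np.outer(d, d)
    c2 = (c2 + c2.T) / 2.0
    np.fill_diagonal(c2, 1.0)
    return c2


def make_group_covariances(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Control and patient R×R correlation matrices plus the ground truth.

    The control matrix carries ``r0`` on the background links (all
    off-diagonal entries, or none, per ``spec.background``); the patient
    matrix is identical except the planted links carry ``r0 + delta``.
    Both are repaired to the nearest positive-semidefinite correlation
    matrix, and the achieved (post-repair) planted contrast is reported.
    """
    r = spec.n_rois
    base = spec.r0 if spec.background == "all" else 0.0
    control = np.full((r, r), base, dtype=np.float64)
    np.fill_diagonal(control, 1.0)
    patient = control.copy()
    for a, b in spec.planted_links:
        patient[a, b] = patient[b, a] = spec.r0 + spec.delta
    control = _nearest_psd_corr(control)
    patient = _nearest_psd_corr(patient)
    achieved = {
        (a, b): float(patient[a, b] - control[a, b]) for a, b in spec.planted_links
    }
    return control, patient, GroundTruth(spec.planted_links, control, patient, achieved)


def _cov_factor(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        raise ValueError("covariance must be positive-semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_roi_series(
    cov: np.ndarray,
    T: int,
    tr: float,
    band: tuple[float, float] = (0.01, 0.08),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Band-limited Gaussian signals with a prescribed correlation matrix.

    White Gaussian rows are band-limited by frequency-domain masking
    (bins outside [f_lo, f_hi] zeroed), standardized, and mixed through a
    matrix square root of ``cov``; rows are finally re-standardized to
    exactly zero mean, unit variance.  Out-of-band power is therefore
    fully suppressed, and the empirical row correlation converges to
    ``cov`` as T grows.
    """
    cov = np.asarray(cov, dtype=np.float64)
    r = cov.shape[0]
    if T < 8:
        raise ValueError("T must be >= 8")
    f_lo, f_hi = band
    nyq = 1.0 / (2.0 * tr)
    if not (0 <= f_lo < f_hi):
        raise ValueError("band must satisfy 0 <= f_lo < f_hi")
    if f_hi > nyq + 1e-12:
        raise ValueError(f"f_hi = {f_hi} exceeds the Nyquist frequency {nyq}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal((r, T))
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12)
    if keep.sum() < 2:
        raise ValueError("band retains fewer than 2 frequency bins; increase T or widen band")
    spec_ = np.fft.rfft(noise, axis=1)
    spec_[:, ~keep] = 0.0
    x = np.fft.irfft(spec_, n=T, axis=1)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    mixed = _cov_factor(cov) @ x
    mixed -= mixed.mean(axis=1, keepdims=True)
    sd = mixed.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return mixed / sd


def make_block_parcellation(spec: CohortSpec) -> Parcellation:
    """Toy parcellation: R axis-aligned cubic blocks tiled with gaps.

    Blocks of side ceil(roi_voxels^(1/3)) are laid out on a near-cubic
    3D arrangement separated by ``gap_voxels`` background voxels (and a
    border of the same width), so that smoothing mixes neighbouring ROIs
    the way it does in real parcellations.  Each block keeps exactly
    ``roi_voxels`` voxels (raster order within the block).
    """
    r = spec.n_rois
    side = max(1, math.ceil(spec.roi_voxels ** (1.0 / 3.0) - 1e-9))
    gap = spec.gap_voxels
    nx = math.ceil(r ** (1.0 / 3.0) - 1e-9)
    ny = math.ceil((r / nx) ** 0.5 - 1e-9)
    nz = math.ceil(r / (nx * ny) - 1e-9)
    dims = tuple(gap + n * (side + gap) for n in (nx, ny, nz))
    labels = np.zeros(dims, dtype=np.int32)
    roi = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if roi >= r:
                    break
                roi += 1
                o = [gap + i * (side + gap) for i in (ix, iy, iz)]
                count = 0
                for dx in range(side):
                    for dy in range(side):
                        for dz in range(side):
                            if count >= spec.roi_voxels:
                                break
                            labels[o[0] + dx, o[1] + dy, o[2] + dz] = roi
                            count += 1
    grid = VolumeGrid(dims, (spec.voxel_size_mm,) * 3)
    return Parcellation(grid, labels)


def generate_subject_volume(
    parc: Parcellation,
    roi_series: np.ndarray,
    spec: CohortSpec,
    seed: int | np.random.Generator = 0,
) -> BrainVolume4D:
    """Voxel-level stand-in for a preprocessed 4D image.

    Every voxel of ROI r carries ``roi_series[r]`` plus voxel noise of sd
    ``voxel_noise_sd``; when ``intrinsic_fwhm > 0`` the noise field is
    spatially smoothed to that FWHM (then rescaled back to the requested
    sd) so the volume has nonzero intrinsic smoothness.  The mask is the
    union of ROI voxels.
    """
    if parc.n_rois != roi_series.shape[0]:
        raise ValueError("parcellation ROI count must match roi_series rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = roi_series.shape[1]
    dims = parc.grid.dims
    mask = parc.labels > 0
    data = np.zeros(dims + (t,), dtype=np.float64)
    for roi in range(1, parc.n_rois + 1):
        data[parc.labels == roi] = roi_series[roi - 1]
    if spec.voxel_noise_sd > 0:
        noise = rng.standard_normal(dims + (t,))
        if spec.intrinsic_fwhm > 0:
            full = np.ones(dims, dtype=bool)
            noise = smooth_array(
                noise, full, parc.grid.voxel_size, SmoothingKernel(spec.intrinsic_fwhm)
            )
            noise /= noise.std()
        data += spec.voxel_noise_sd * noise
    return BrainVolume4D(parc.grid, mask, data, tr=spec.tr)


def _truncated_lognormal_fd(rng: np.random.Generator, cap: float = 0.5) -> float:
    # log-normal(mu=ln 0.15, sigma=0.5) truncated at the inclusion cap
    for _ in range(1000):
        v = float(rng.lognormal(math.log(0.15), 0.5))
        if v < cap:
            return v
    return cap * 0.99


def generate_cohort(spec: CohortSpec, mode: str = "volume") -> Cohort:
    """Generate a reproducible two-group cohort.

    ``mode="volume"`` produces full 4D volumes on the toy block
    parcellation; ``mode="roi"`` skips the voxel stage and returns ROI
    series directly (fast path for statistical simulations).  Site labels
    are assigned round-robin within each group; mean FD is drawn from a
    truncated log-normal; per-site and motion-correlated nuisance offsets
    for the Fisher-z link weights are stored in the ground truth so the
    connectivity stage can inject them.
    """
    if mode not in ("volume", "roi"):
        raise ValueError("mode must be 'volume' or 'roi'")
    control, patient, gt = make_group_covariances(spec)
    r = spec.n_rois
    n_links = r * (r - 1) // 2
    master = np.random.default_rng(np.random.SeedSequence([2**16, spec.seed]))
    # cohort-level nuisance patterns
    site_offsets = {
        f"site{i}": master.normal(0.0, spec.site_effect_sd, n_links) if spec.site_effect_sd > 0
        else np.zeros(n_links)
        for i in range(spec.n_sites)
    }
    fd_pattern = master.standard_normal(n_links) if spec.fd_effect_slope != 0 else np.zeros(n_links)

    subjects: list[SubjectRecord] = []
    series_list: list[np.ndarray] = []
    volumes: list[BrainVolume4D] = []
    parc = make_block_parcellation(spec) if mode == "volume" else None
    idx = 0
    for group, cov in (("patient", patient), ("control", control)):
        for i in range(spec.n_per_group):
            site = f"site{i % spec.n_sites}"
            mean_fd = _truncated_lognormal_fd(master)
            gender = "F" if master.random() < 0.5 else "M"
            sub = SubjectRecord(
                id=f"sub-{idx:03d}", group=group, site=site, mean_fd=mean_fd, gender=gender
            )
            subjects.append(sub)
            sub_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
            series = generate_roi_series(cov, spec.T, spec.tr, spec.band, sub_rng)
            gt.nuisance_z[sub.id] = (
                site_offsets[site] + spec.fd_effect_slope * mean_fd * fd_pattern
            )
            if mode == "volume":
                volumes.append(generate_subject_volume(parc, series, spec, sub_rng))
            else:
                series_list.append(series)
            idx += 1
    return Cohort(
        spec=spec,
        subjects=subjects,
        ground_truth=gt,
        parcellation=parc,
        volumes=volumes if mode == "volume" else None,
        roi_series=series_list if mode == "roi" else None,
    )
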