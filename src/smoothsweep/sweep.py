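"""Kernel-sweep orchestration and the sweep-level comparison quantities.

For every FWHM in the sweep the ORIGINAL volumes are smoothed, ROI series
extracted, connectivity matrices built and cleaned, and the network-based
statistic run with a kernel-specific sub-seed.  The per-kernel primary
subnetworks are then compared across kernels through:

* link counts per kernel and link persistence (at which kernels each
  ever-significant link is detected),
* a signed Cohen's d grid (|d| = sqrt(F (1/n1 + 1/n2)), df = 1; sign from
  the patient-minus-control mean difference) over the union of
  ever-significant links, evaluated at EVERY kernel,
* the Hamming distance matrix between subnetwork link masks (a metric on
  binary masks), and
* per-kernel Spearman rank correlation between physical link length (mm
  between ROI centroids) and the link F statistic, over ALL links.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .connectivity import (
    ConnectivityMatrix,
    MatrixStack,
    fisher_inverse,
    fisher_z,
    from_upper_triangle,
    pearson_matrix,
    regress_confounds,
    upper_triangle,
)
from .nbs import NBSConfig, NBSResult, Subnetwork, nbs_test, select_primary_subnetwork
from .parcellation import link_lengths, roi_centroids, roi_time_series
from .smoothing import KernelSweep, gaussian_smooth
from .synthetic import Cohort

__all__ = [
    "SweepConfig",
    "KernelSweepResult",
    "cohens_d_from_f",
    "hamming_distance",
    "spearman_rho",
    "link_persistence",
    "build_matrix_stack",
    "run_sweep",
]


def cohens_d_from_f(f: float, n1: int, n2: int, mean_difference: float = 1.0) -> float:
    """Cohen's d recovered from a df = 1 F statistic.

    |d| = sqrt(F * (1/n1 + 1/n2)); the sign is that of the
    patient-minus-control mean difference of the link weight.
    """
    if f < 0:
        raise ValueError("F must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    mag = math.sqrt(f * (1.0 / n1 + 1.0 / n2))
    return math.copysign(mag, mean_difference) if mag > 0 else 0.0


def _as_mask(a, r: int | None = None) -> np.ndarray:
    if a is None:
        if r is None:
            raise ValueError("need R to build an empty mask")
        return np.zeros((r, r), dtype=bool)
    if isinstance(a, Subnetwork):
        return a.link_mask
    return np.asarray(a, dtype=bool)


def hamming_distance(a, b, n_rois: int | None = None) -> int:
    """Number of upper-triangle link positions at which two masks differ.

    0 iff the subnetworks are identical; an absent subnetwork counts as
    the empty mask.
    """
    if a is None and b is None:
        if n_rois is None:
            raise ValueError("need n_rois when both subnetworks are absent")
        return 0
    r = n_rois
    for x in (a, b):
        if x is not None:
            r = _as_mask(x).shape[0]
    ma, mb = _as_mask(a, r), _as_mask(b, r)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    iu = np.triu_indices(r, k=1)
    return int((ma[iu] != mb[iu]).sum())


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    return float(_sstats.spearmanr(x, y).statistic)


def link_persistence(
    subnetworks: list[Subnetwork | None], fwhms: list[float], n_rois: int
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Which kernels detect each ever-significant link.

    Returns a table with one row per link significant at >= 1 kernel
    (columns: roi_a, roi_b, first_fwhm, n_kernels, fwhms), ordered by
    (smallest detecting kernel, then descending kernel count), plus a
    summary with the number of links significant at ALL kernels and at
    >= ceil(0.75 K) kernels.
    """
    k = len(fwhms)
    if len(subnetworks) != k:
        raise ValueError("one subnetwork (or None) per kernel required")
    per_link: dict[tuple[int, int], list[float]] = {}
    for f, sn in zip(fwhms, subnetworks):
        if sn is None:
            continue
        for link in sn.links():
            per_link.setdefault(link, []).append(f)
    rows = [
        {
            "roi_a": a,
            "roi_b": b,
            "first_fwhm": kernels[0],
            "n_kernels": len(kernels),
            "fwhms": ",".join(f"{v:g}" for v in kernels),
        }
        for (a, b), kernels in per_link.items()
    ]
    df = pd.DataFrame(rows, columns=["roi_a", "roi_b", "first_fwhm", "n_kernels", "fwhms"])
    if len(df):
        df = df.sort_values(
            ["first_fwhm", "n_kernels", "roi_a", "roi_b"],
            ascending=[True, False, True, True],
        ).reset_index(drop=True)
    summary = {
        "n_links_any": len(per_link),
        "n_links_all_kernels": sum(1 for v in per_link.values() if len(v) == k),
        "n_links_75pct": sum(
            1 for v in per_link.values() if len(v) >= math.ceil(0.75 * k)
        ),
    }
    return df, summary


@dataclass(frozen=True)
class SweepConfig:
    """Everything run_sweep needs beyond the cohort and the kernel list."""

    nbs: NBSConfig = NBSConfig()
    confound_model: tuple[str, ...] = ("site", "mean_fd")
    apply_nuisance: bool = True  # inject the cohort's ground-truth z offsets
    seed: int = 0


@dataclass
class KernelSweepResult:
    fwhms: list[float]
    subnetworks: list[Subnetwork | None]
    n_links: list[int]
    nbs_results: list[NBSResult]
    d_grid: pd.DataFrame  # rows: ever-significant links; columns: FWHMs
    persistence: pd.DataFrame
    persistence_summary: dict[str, int]
    hamming: np.ndarray  # K x K
    rho: list[float]  # per-kernel Spearman(length, F) over all links
    length_distributions: list[np.ndarray]  # detected-link lengths (mm) per kernel
    link_length_matrix: np.ndarray
    seeds: dict[float, int] = field(default_factory=dict)


def build_matrix_stack(
    cohort: Cohort,
    fwhm: float = 0.0,
    confound_model: tuple[str, ...] = ("site", "mean_fd"),
    apply_nuisance: bool = True,
) -> MatrixStack:
    """Cleaned connectivity matrices for one smoothing level of a cohort.

    Volumes (if present) are smoothed at ``fwhm`` from the original data
    and reduced to ROI series; ROI-mode cohorts require fwhm = 0.  Then:
    Pearson → Fisher z → ground-truth nuisance injection (site/motion
    offsets, if enabled) → link-wise confound regression → inverse
    Fisher.
    """
    series = []
    if cohort.volumes is not None:
        for vol in cohort.volumes:
            sm = gaussian_smooth(vol, fwhm) if fwhm > 0 else vol
            series.append(roi_time_series(sm, cohort.parcellation))
    else:
        if fwhm != 0:
            raise ValueError("ROI-mode cohorts carry no volumes; smoothing requires mode='volume'")
        series = list(cohort.roi_series)
    z_mats = []
    for sub, s in zip(cohort.subjects, series):
        m = pearson_matrix(s, subject_id=sub.id, fwhm=fwhm)
        zm = fisher_z(m)
        if apply_nuisance and sub.id in cohort.ground_truth.nuisance_z:
            off = cohort.ground_truth.nuisance_z[sub.id]
            zm = ConnectivityMatrix(
                zm.weights + from_upper_triangle(off, zm.n_rois),
                subject_id=sub.id,
                fwhm=fwhm,
                space="z",
            )
        z_mats.append(zm)
    stack = MatrixStack(list(cohort.subjects), z_mats)
    if confound_model:
        stack = regress_confounds(stack, confound_model)
    return MatrixStack(stack.subjects, [fisher_inverse(m) for m in stack.matrices])


def _kernel_seed(master_seed: int, kernel_index: int) -> int:
    """Deterministic per-kernel NBS seed: child of (master, kernel counter)."""
    return int(np.random.SeedSequence([master_seed, kernel_index]).generate_state(1)[0] % (2**31))


def run_sweep(cohort: Cohort, sweep: KernelSweep, cfg: SweepConfig) -> KernelSweepResult:
    """Full kernel sweep: per-kernel NBS plus the cross-kernel comparisons."""
    if cohort.volumes is None:
        raise ValueError("run_sweep needs a volume-mode cohort (smoothing acts on voxels)")
    fwhms = list(sweep.fwhms)
    n1 = sum(1 for s in cohort.subjects if s.group == "patient")
    n2 = sum(1 for s in cohort.subjects if s.group == "control")
    lengths = link_lengths(roi_centroids(cohort.parcellation))
    r = cohort.parcellation.n_rois
    iu = np.triu_indices(r, k=1)

    subnets: list[Subnetwork | None] = []
    results: list[NBSResult] = []
    rho: list[float] = []
    length_dists: list[np.ndarray] = []
    seeds: dict[float, int] = {}
    for k_idx, fwhm in enumerate(fwhms):
        try:
            stack = build_matrix_stack(cohort, fwhm, cfg.confound_model, cfg.apply_nuisance)
            sub_seed = _kernel_seed(cfg.seed, k_idx)
            seeds[fwhm] = sub_seed
            res = nbs_test(
                stack,
                NBSConfig(cfg.nbs.suprathreshold, cfg.nbs.n_perm, cfg.nbs.alpha, sub_seed),
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"sweep failed at FWHM {fwhm} mm: {exc}") from exc
        sn = select_primary_subnetwork(res)
        subnets.append(sn)
        results.append(res)
        rho.append(spearman_rho(lengths[iu], res.f_matrix[iu]))
        if sn is None:
            length_dists.append(np.zeros(0))
        else:
            mask = sn.link_mask[iu]
            length_dists.append(lengths[iu][mask])

    persistence, summary = link_persistence(subnets, fwhms, r)
    ever = [(int(a), int(b)) for a, b in zip(persistence["roi_a"], persistence["roi_b"])]
    d_rows = {}
    for a, b in ever:
        row = []
        for res in results:
            row.append(
                cohens_d_from_f(
                    float(res.f_matrix[a, b]), n1, n2, float(res.mean_difference[a, b])
                )
            )
        d_rows[f"{a}-{b}"] = row
    d_grid = pd.DataFrame.from_dict(d_rows, orient="index", columns=[f"{f:g}" for f in fwhms])

    k = len(fwhms)
    ham = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            ham[i, j] = ham[j, i] = hamming_distance(subnets[i], subnets[j], n_rois=r)

    return KernelSweepResult(
        fwhms=fwhms,
        subnetworks=subnets,
        n_links=[0 if s is None else s.n_links for s in subnets],
        nbs_results=results,
        d_grid=d_grid,
        persistence=persistence,
        persistence_summary=summary,
        hamming=ham,
        rho=rho,
        length_distributions=length_dists,
        link_length_matrix=lengths,
        seeds=seeds,
    )
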