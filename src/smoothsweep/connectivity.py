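"""Per-subject connectivity matrices and their preparation for group tests.

The pipeline is: Pearson correlation between ROI-mean series → Fisher
z-transform (variance stabilization) → link-wise ordinary-least-squares
removal of nuisance covariates (scan site, mean framewise displacement,
optionally gender; never the diagnosis group) → inverse Fisher transform
back to the correlation scale.  Density thresholding (keep the top
fraction of links) with optional binarization supports the
thresholded-network analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import SubjectRecord

__all__ = [
    "ConnectivityMatrix",
    "MatrixStack",
    "pearson_matrix",
    "fisher_z",
    "fisher_inverse",
    "regress_confounds",
    "threshold_density",
    "upper_triangle",
    "from_upper_triangle",
]

_FISHER_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI×ROI link weights for one subject; diagonal fixed at 0.

    ``space`` records whether weights are correlations ("r", |w| <= 1) or
    Fisher z values ("z", unbounded).  ``fwhm`` is a provenance tag: the
    smoothing kernel the source volume was processed with.
    """

    weights: np.ndarray
    subject_id: str = ""
    fwhm: float | None = None
    space: str = "r"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        if self.space == "r" and np.any(np.abs(w) > 1.0 + 1e-12):
            raise ValueError("correlation weights must satisfy |w| <= 1")
        if self.space not in ("r", "z"):
            raise ValueError("space must be 'r' or 'z'")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return int(self.weights.shape[0])


@dataclass
class MatrixStack:
    """Per-subject connectivity matrices sharing R and smoothing kernel."""

    subjects: list[SubjectRecord]
    matrices: list[ConnectivityMatrix]

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.matrices):
            raise ValueError("one matrix per subject required")
        if not self.subjects:
            raise ValueError("empty stack")
        r = self.matrices[0].n_rois
        if any(m.n_rois != r for m in self.matrices):
            raise ValueError("inconsistent ROI counts in stack")
        spaces = {m.space for m in self.matrices}
        if len(spaces) != 1:
            raise ValueError("mixed r/z spaces in stack")

    @property
    def n_rois(self) -> int:
        return self.matrices[0].n_rois

    @property
    def space(self) -> str:
        return self.matrices[0].space

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.subjects) if s.group == group], dtype=int)

    def weights_array(self) -> np.ndarray:
        """(n_subjects, R, R) stacked weights."""
        return np.stack([m.weights for m in self.matrices])


def upper_triangle(w: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a square matrix."""
    iu = np.triu_indices(w.shape[-1], k=1)
    return w[..., iu[0], iu[1]]


def from_upper_triangle(vec: np.ndarray, r: int) -> np.ndarray:
    """Rebuild a symmetric zero-diagonal matrix from its strict upper triangle."""
    out = np.zeros((r, r), dtype=np.float64)
    iu = np.triu_indices(r, k=1)
    out[iu] = vec
    return out + out.T


def pearson_matrix(
    series: np.ndarray, subject_id: str = "", fwhm: float | None = None
) -> ConnectivityMatrix:
    """Pearson correlations between ROI-mean series; diagonal set to 0."""
    s = np.asarray(series, dtype=np.float64)
    if s.ndim != 2 or s.shape[1] < 3:
        raise ValueError("series must be (R, T) with T >= 3")
    sd = s.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant ROI series (zero variance) for ROI index {bad[0]}")
    w = np.corrcoef(s)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(np.clip(w, -1.0, 1.0), subject_id=subject_id, fwhm=fwhm, space="r")


def fisher_z(w):
    """Fisher z = artanh(r), elementwise; |r| clipped at 1 - 1e-7 first.

    Accepts an array or a ConnectivityMatrix (returns the same kind).
    """
    if isinstance(w, ConnectivityMatrix):
        if w.space != "r":
            raise ValueError("matrix is already in z space")
        return replace(w, weights=fisher_z(w.weights), space="z")
    arr = np.asarray(w, dtype=np.float64)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("Fisher transform requires |w| <= 1")
    return np.arctanh(np.clip(arr, -_FISHER_CLIP, _FISHER_CLIP))


def fisher_inverse(z):
    """Inverse Fisher transform, tanh(z)."""
    if isinstance(z, ConnectivityMatrix):
        if z.space != "z":
            raise ValueError("matrix is not in z space")
        return replace(z, weights=np.tanh(z.weights), space="r")
    return np.tanh(np.asarray(z, dtype=np.float64))


def _design_matrix(subjects: list[SubjectRecord], model: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    df = pd.DataFrame(
        {
            "site": [s.site for s in subjects],
            "mean_fd": [s.mean_fd for s in subjects],
            "gender": [s.gender for s in subjects],
        }
    )
    cols: list[np.ndarray] = [np.ones(len(subjects))]
    names = ["intercept"]
    for cov in model:
        if cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}; choose from {list(df.columns)}")
        if cov == "mean_fd":
            col = df[cov].to_numpy(dtype=float)
            if col.std() > 0:  # a constant covariate has nothing to remove
                cols.append(col)
                names.append(cov)
        else:
            levels = sorted(df[cov].unique())  # reference level = first alphabetically
            for lev in levels[1:]:
                cols.append((df[cov] == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


def regress_confounds(stack: MatrixStack, model: tuple[str, ...] = ("site", "mean_fd")) -> MatrixStack:
    """Remove nuisance covariates from every link by OLS, in z space.

    For each link independently, the Fisher-z weights are regressed on an
    intercept plus the model covariates (categoricals dummy-coded against
    the alphabetically first level).  The cleaned value is the residual
    plus the fitted intercept, so the mean level survives and the inverse
    Fisher transform returns weights on the original scale.  Group
    membership is never part of the model: the group signal must survive
    cleaning.
    """
    if stack.space != "z":
        raise ValueError("regress_confounds operates on Fisher-z matrices")
    x, names = _design_matrix(stack.subjects, tuple(model))
    n, p = x.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} subjects for {p} design columns, have {n}")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError(f"rank-deficient design; check collinearity among columns {names}")
    r = stack.n_rois
    z = np.stack([upper_triangle(m.weights) for m in stack.matrices])  # (n, L)
    beta, *_ = np.linalg.lstsq(x, z, rcond=None)
    cleaned = z - x @ beta + beta[0]  # residual + fitted intercept
    mats = [
        replace(m, weights=from_upper_triangle(cleaned[i], r))
        for i, m in enumerate(stack.matrices)
    ]
    return MatrixStack(list(stack.subjects), mats)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_density(
    m: ConnectivityMatrix,
    density: float,
    binarize: bool = False,
    mode: str = "signed",
) -> ConnectivityMatrix:
    """Keep the k = round(density * R(R-1)/2) strongest links, zero the rest.

    ``mode="signed"`` ranks links by signed weight (the default for
    binarized resting-state graphs); ``mode="absolute"`` ranks by |w|.
    Ties at the cutoff break deterministically toward the lower
    (row, col) index.  ``binarize`` maps survivors to 1.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    r = m.n_rois
    n_links = r * (r - 1) // 2
    k = _round_half_up(density * n_links)
    if k == 0:
        raise ValueError(f"density {density} too small for R = {r} (keeps zero links)")
    iu = np.triu_indices(r, k=1)
    vals = m.weights[iu]
    rank_vals = vals if mode == "signed" else np.abs(vals)
    # primary: value desc; ties: lower (row, col) first
    order = np.lexsort((iu[1], iu[0], -rank_vals))
    keep = order[:k]
    out_vals = np.zeros_like(vals)
    out_vals[keep] = 1.0 if binarize else vals[keep]
    return replace(m, weights=from_upper_triangle(out_vals, r))
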