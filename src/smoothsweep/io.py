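"""Readers/writers for the pipeline's standard formats.

Volumes and parcellations travel as NIfTI-1 (via nibabel); subject
tables, connectivity matrices, manifests and ground-truth edge lists as
TSV; run configuration as TOML.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BrainVolume4D, SubjectRecord, VolumeGrid
from .parcellation import Parcellation

__all__ = [
    "write_volume",
    "read_volume",
    "write_parcellation",
    "read_parcellation",
    "write_subject_table",
    "read_subject_table",
    "write_matrix",
    "read_matrix",
    "write_matrix_stack",
    "read_matrix_stack",
    "write_ground_truth",
    "load_toml_config",
]

_MATRIX_FMT = "%.12g"


def _affine(grid: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.voxel_size)
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.voxel_size)
    return aff


def _grid_from_img(img) -> VolumeGrid:
    aff = img.affine
    voxel_size = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(aff[i, 3] - 0.5 * voxel_size[i]) for i in range(3))
    return VolumeGrid(tuple(int(d) for d in img.shape[:3]), voxel_size, origin)


def write_volume(volume: BrainVolume4D, path: str | Path, mask_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(volume.data, _affine(volume.grid))
    img.header.set_zooms(volume.grid.voxel_size + (volume.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if mask_path is not None:
        m = nib.Nifti1Image(volume.mask.astype(np.uint8), _affine(volume.grid))
        nib.save(m, str(mask_path))


def read_volume(path: str | Path, mask_path: str | Path | None = None) -> BrainVolume4D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    grid = _grid_from_img(img)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if tuple(mimg.shape[:3]) != grid.dims:
            raise ValueError(
                f"mask shape {tuple(mimg.shape[:3])} does not match volume grid {grid.dims}"
            )
        mask = np.asarray(mimg.dataobj) > 0
    else:
        mask = np.any(data != 0, axis=3)
    return BrainVolume4D(grid, mask, data, tr=tr)


def write_parcellation(parc: Parcellation, path: str | Path, table_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), _affine(parc.grid))
    nib.save(img, str(path))
    if table_path is not None:
        r = parc.n_rois
        df = pd.DataFrame(
            {
                "roi_id": np.arange(1, r + 1),
                "name": parc.names or [f"roi{i}" for i in range(1, r + 1)],
                "system": parc.system or ["unassigned"] * r,
            }
        )
        df.to_csv(table_path, sep="\t", index=False)


def read_parcellation(path: str | Path, volume_grid: VolumeGrid | None = None) -> Parcellation:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parcellation not found: {path}")
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    grid = _grid_from_img(img)
    if volume_grid is not None and grid.dims != volume_grid.dims:
        raise ValueError(
            f"parcellation grid {grid.dims} does not match volume grid {volume_grid.dims}"
        )
    return Parcellation(grid, labels)


def write_subject_table(subjects: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "site": [s.site for s in subjects],
            "mean_fd": [s.mean_fd for s in subjects],
            "gender": [s.gender for s in subjects],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"subject table not found: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype={"id": str, "group": str, "site": str, "gender": str},
        float_precision="round_trip",
    )
    return [
        SubjectRecord(
            id=row.id, group=row.group, site=row.site, mean_fd=float(row.mean_fd), gender=row.gender
        )
        for row in df.itertuples()
    ]


def write_matrix(weights: np.ndarray, path: str | Path) -> None:
    r = weights.shape[0]
    ids = [f"roi{i}" for i in range(1, r + 1)]
    df = pd.DataFrame(weights, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format=_MATRIX_FMT)


def read_matrix(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    w = df.to_numpy(dtype=np.float64)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"matrix in {path} is not square: {w.shape}")
    if not np.allclose(w, w.T, atol=1e-8):
        raise ValueError(f"matrix in {path} is asymmetric beyond 1e-8")
    return w


def write_matrix_stack(stack, out_dir: str | Path, space_suffix: str = "") -> Path:
    """One TSV per subject plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub, mat in zip(stack.subjects, stack.matrices):
        fname = f"{sub.id}{space_suffix}.tsv"
        write_matrix(mat.weights, out / fname)
        rows.append(
            {
                "id": sub.id,
                "group": sub.group,
                "site": sub.site,
                "mean_fd": sub.mean_fd,
                "gender": sub.gender,
                "file": fname,
                "fwhm": "" if mat.fwhm is None else mat.fwhm,
                "space": mat.space,
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_matrix_stack(manifest_path: str | Path):
    from .connectivity import ConnectivityMatrix, MatrixStack

    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, sep="\t", dtype={"id": str})
    subjects, matrices = [], []
    for row in df.itertuples():
        mpath = manifest_path.parent / row.file
        if not mpath.exists():
            raise FileNotFoundError(f"manifest subject {row.id} is missing matrix file {mpath}")
        w = read_matrix(mpath)
        fwhm = None if pd.isna(row.fwhm) or row.fwhm == "" else float(row.fwhm)
        space = getattr(row, "space", "r")
        subjects.append(
            SubjectRecord(
                id=row.id,
                group=row.group,
                site=row.site,
                mean_fd=float(row.mean_fd),
                gender=row.gender,
            )
        )
        matrices.append(
            ConnectivityMatrix(w, subject_id=row.id, fwhm=fwhm, space=space if isinstance(space, str) else "r")
        )
    return MatrixStack(subjects, matrices)


def write_ground_truth(gt, path: str | Path) -> None:
    pd.DataFrame(
        {
            "roi_a": [a for a, _ in gt.planted_links],
            "roi_b": [b for _, b in gt.planted_links],
            "delta_achieved": [gt.achieved_delta[l] for l in gt.planted_links],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_toml_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_hash(cfg: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
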