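"""NIfTI and feature-matrix I/O."""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix, MetabolicVolume

__all__ = [
    "save_nifti",
    "load_nifti",
    "load_volume",
    "load_mask",
    "find_subject_volumes",
    "save_features",
    "load_features",
]

_SUBJECT_RE = re.compile(r"(sub-[A-Za-z0-9]+)\.nii(\.gz)?$")


def _affine(voxel_size_mm) -> np.ndarray:
    """RAS-oriented affine from the voxel size (origin at the grid corner)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(data: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), voxel


def load_volume(path: str | Path, subject_id: str | None = None) -> MetabolicVolume:
    data, voxel = load_nifti(path)
    if subject_id is None:
        m = _SUBJECT_RE.search(Path(path).name)
        subject_id = m.group(1) if m else Path(path).stem
    return MetabolicVolume(data=data, voxel_size_mm=voxel, subject_id=subject_id)


def load_mask(path: str | Path) -> np.ndarray:
    data, _ = load_nifti(path)
    return data > 0.5


def find_subject_volumes(volumes_dir: str | Path) -> dict[str, Path]:
    """Map subject_id -> volume path for files named sub-<ID>.nii[.gz].

    Fails loudly when no volume matches the convention; matching against
    the score table happens in the pipeline.
    """
    volumes_dir = Path(volumes_dir)
    found = {}
    for p in sorted(volumes_dir.iterdir()):
        m = _SUBJECT_RE.search(p.name)
        if m:
            found[m.group(1)] = p
    if not found:
        raise FileNotFoundError(
            f"no sub-<ID>.nii[.gz] volumes found in {volumes_dir}"
        )
    return found


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Persist a FeatureMatrix as .npz with a JSON sidecar for metadata."""
    path = Path(path)
    np.savez_compressed(path, values=fm.values, voxel_index=fm.voxel_index)
    sidecar = {
        "subject_ids": fm.subject_ids,
        "grid_dims": list(fm.grid_dims),
        "voxel_size_mm": list(fm.voxel_size_mm),
        "stage": fm.stage,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FeatureMatrix(
        values=arrays["values"],
        voxel_index=arrays["voxel_index"],
        subject_ids=list(meta["subject_ids"]),
        grid_dims=tuple(meta["grid_dims"]),
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        stage=meta["stage"],
    )
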