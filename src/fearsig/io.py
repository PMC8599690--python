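"""NIfTI / TSV / JSON serialization with provenance sidecars.

All images are written as NIfTI-1 with the lattice's diagonal affine; every
read checks grid shape and affine against the expected space and refuses to
resample.  Masked vectors follow the package-wide flat order (boolean
C-order indexing of the mask volume).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datasets import BetaImageSet
from .signature import SignatureModel
from .space import LatticeSpace


def space_affine(space: LatticeSpace) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = space.voxel_size
    return aff


def _check_grid(img: nib.Nifti1Image, space: LatticeSpace, path) -> None:
    if tuple(img.shape[:3]) != tuple(space.dims):
        raise ValueError(f"{path}: grid {img.shape[:3]} does not match lattice "
                         f"{space.dims} (no resampling)")
    if not np.allclose(img.affine, space_affine(space), atol=1e-6):
        raise ValueError(f"{path}: affine does not match the lattice affine "
                         "(no resampling)")


def save_map(path, values: np.ndarray, space: LatticeSpace,
             sidecar: dict | None = None) -> Path:
    """Write an in-mask vector as a 3-D NIfTI (+ optional JSON sidecar)."""
    path = Path(path)
    img = nib.Nifti1Image(
        space.unflatten(np.asarray(values, float)).astype(np.float32),
        space_affine(space),
    )
    nib.save(img, path)
    if sidecar is not None:
        meta = dict(sidecar)
        meta.setdefault("space_fingerprint", space.fingerprint())
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(meta, indent=2, default=str)
        )
    return path


def load_map(path, space: LatticeSpace) -> np.ndarray:
    """Read a 3-D NIfTI back to the in-mask vector; NaNs in mask are errors."""
    img = nib.load(str(path))
    _check_grid(img, space, path)
    values = space.flatten(np.asarray(img.get_fdata(), dtype=float))
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(
            f"{path}: non-finite values inside the mask at flat voxels "
            f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
        )
    return values


def save_mask(path, space: LatticeSpace) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(space.mask.astype(np.uint8), space_affine(space)),
             path)
    return path


def save_atlas(path, space: LatticeSpace) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(space.atlas.astype(np.int16), space_affine(space)),
             path)
    return path


def save_series(path, Y: np.ndarray, space: LatticeSpace) -> Path:
    """Write a (scans × in-mask voxels) matrix as a 4-D NIfTI."""
    Y = np.asarray(Y, float)
    vol = np.zeros(tuple(space.dims) + (Y.shape[0],), dtype=np.float32)
    vol[space.mask, :] = Y.T
    path = Path(path)
    nib.save(nib.Nifti1Image(vol, space_affine(space)), path)
    return path


def load_series(path, space: LatticeSpace) -> np.ndarray:
    img = nib.load(str(path))
    _check_grid(img, space, path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series")
    return data[space.mask, :].T


def read_masked_images(paths, space: LatticeSpace,
                       subject_ids=None, ratings=None,
                       level: str = "condition") -> BetaImageSet:
    """Stack 3-D beta images into a BetaImageSet (grid-checked, no NaNs)."""
    paths = list(paths)
    if space.n_voxels == 0:
        raise ValueError("mask contains no voxels")
    data = np.vstack([load_map(p, space) for p in paths])
    if subject_ids is None:
        subject_ids = np.array([f"sub-{i + 1:03d}" for i in range(len(paths))])
    return BetaImageSet(
        data=data,
        subject_ids=np.asarray(subject_ids),
        ratings=None if ratings is None else np.asarray(ratings, float),
        level=level,
        space_fingerprint=space.fingerprint(),
    )


def save_events(path, events: pd.DataFrame) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def load_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_model(path_stem, model: SignatureModel, space: LatticeSpace) -> Path:
    """Persist a signature as weight NIfTI + JSON sidecar."""
    stem = Path(path_stem)
    save_map(stem.with_suffix(".nii.gz"), model.weights, space)
    stem.with_suffix(".json").write_text(
        json.dumps(
            {
                "intercept": model.intercept,
                "config": model.config,
                "space_fingerprint": model.space_fingerprint,
            },
            indent=2,
        )
    )
    return stem


def load_model(path_stem, space: LatticeSpace) -> SignatureModel:
    stem = Path(path_stem)
    weights = load_map(stem.with_suffix(".nii.gz"), space)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return SignatureModel(
        weights=weights,
        intercept=meta["intercept"],
        config=meta.get("config", {}),
        space_fingerprint=meta.get("space_fingerprint"),
    )
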