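"""Standard-format I/O: TSV tables, NIfTI volumes, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthetic import ROIMask


def write_tsv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a TSV; an optional seed is recorded as a comment header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_matrix_tsv(matrix: np.ndarray, path, columns=None, seed: int | None = None) -> None:
    cols = columns or [f"c{i}" for i in range(matrix.shape[1])]
    write_tsv(pd.DataFrame(matrix, columns=cols), path, seed=seed)


def read_matrix_tsv(path) -> np.ndarray:
    return read_tsv(path).to_numpy(float)


def write_mask_nifti(mask: ROIMask, path, values: np.ndarray | None = None) -> None:
    """Write a mask (or per-voxel integer labels) as a NIfTI label volume."""
    vals = np.ones(mask.n_voxels, dtype=np.int16) if values is None else np.asarray(values, np.int16)
    img = nib.Nifti1Image(mask.volume(vals).astype(np.int16), mask.affine)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_label_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(int), img.affine


def mask_from_nifti(path, hemisphere: str) -> tuple[ROIMask, np.ndarray]:
    """Load an arbitrary integer label volume as (ROIMask, per-voxel labels)."""
    vol, affine = read_label_nifti(path)
    coords = np.argwhere(vol > 0)
    labels = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
    mask = ROIMask(coords=coords, shape=vol.shape, affine=affine, hemisphere=hemisphere)
    return mask, labels


def write_yaml(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
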