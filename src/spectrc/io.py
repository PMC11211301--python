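"""NIfTI / CSV / JSON serialization helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import VoxelGrid


def grid_affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_volume(path, values: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid_affine(grid))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    aff = img.affine
    voxel_size = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    grid = VoxelGrid(
        tuple(int(n) for n in img.shape[:3]),
        voxel_size,
        tuple(float(v) for v in aff[:3, 3]),
    )
    return np.asarray(img.dataobj, dtype=np.float64), grid


def save_rc_table(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def load_rc_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_report(path, report) -> None:
    from . import __version__

    if isinstance(report, dict):
        report = {"spectrc_version": __version__, **report}
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
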