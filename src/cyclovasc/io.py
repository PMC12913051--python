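"""Shared readers/writers: NIfTI volumes, CSV tables, binary mask images.

Conventions: voxel indices are 0-based and physical coordinates flow
through the NIfTI affine; 2-D images use a top-left origin with y
increasing downwards.  Mask images load as binary with the explicit rule
"value > 0 means vessel".  Result tables written by pipeline stages
carry provenance columns (stage name, seed, configuration hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_volume", "write_volume", "read_table", "write_table",
    "read_image", "write_image", "add_provenance", "config_hash",
]


def write_volume(data: np.ndarray, path: str | Path,
                 affine: np.ndarray | None = None) -> Path:
    """Write an array as NIfTI; identity affine by default."""
    path = Path(path)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns ``(data, affine)``."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path,
               key_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally rejecting duplicated key rows."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot read table {path}: {exc}") from exc
    if key_columns:
        dup = df.duplicated(subset=key_columns)
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValueError(
                f"{path}: duplicated key rows {rows} on {key_columns}")
    return df


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF mask as binary uint8 (any value > 0 is vessel)."""
    try:
        arr = iio.imread(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:            # collapse colour/alpha channels
        arr = arr[..., :3].max(axis=-1)
    return (arr > 0).astype(np.uint8)


def write_image(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG/TIFF (vessel = 255)."""
    path = Path(path)
    iio.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)
    return path


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration dictionary."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def add_provenance(df: pd.DataFrame, stage: str, seed: int,
                   cfg_hash: str) -> pd.DataFrame:
    df = df.copy()
    df["stage"] = stage
    df["seed"] = seed
    df["config_hash"] = cfg_hash
    return df
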