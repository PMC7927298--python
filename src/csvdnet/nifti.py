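"""Thin NIfTI and value-vector I/O helpers (nibabel-backed).

Masks and scalar maps are exchanged as NIfTI volumes (gzip accepted by
nibabel transparently); voxel dimensions come from the header zooms.
Skeletonised MD values may alternatively be supplied as one-column
delimited text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from .exceptions import FormatError

__all__ = ["load_volume", "load_mask", "save_volume", "load_value_vector", "save_value_vector"]


def load_volume(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read a 3-D scalar volume and its voxel dimensions (mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def load_mask(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read a binary mask (any nonzero voxel is True)."""
    data, zooms = load_volume(path)
    return data > 0, zooms


def save_volume(data: np.ndarray, voxel_dims, path) -> None:
    """Write a 3-D volume with a diagonal affine built from voxel sizes."""
    affine = np.diag(list(voxel_dims) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(voxel_dims))
    nib.save(img, str(path))


def load_value_vector(path) -> np.ndarray:
    """Read a one-column text file of scalar values."""
    values = np.loadtxt(str(path), ndmin=1)
    if values.ndim != 1:
        raise FormatError(f"{path}: expected a single column of values")
    return values


def save_value_vector(values: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(values, dtype=float), fmt="%.10g")
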