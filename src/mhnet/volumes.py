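"""Domain types (volumes, displacement fields, label maps) and NIfTI I/O.

Volumes are kept in the array index space of the file as stored: no
reorientation is performed, and inputs to registration are assumed to be
affinely pre-aligned already.  Displacements are expressed in voxel units
throughout the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "DisplacementField",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
    "crop_center",
    "normalize",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains NaN or Inf")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors, shape (3, X, Y, Z), in voxel units."""

    u: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float32)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(
                f"DisplacementField must have shape (3, X, Y, Z), got {self.u.shape}"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("DisplacementField contains NaN or Inf")

    @property
    def shape(self):
        return self.u.shape[1:]


@dataclass
class LabelMap:
    """Integer segmentation aligned to a Volume; label 0 is background."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("LabelMap values must be integers")
            arr = np.round(arr).astype(np.int32)
        if arr.ndim != 3:
            raise ValueError(f"LabelMap must be 3D, got {arr.ndim}D")
        if arr.min() < 0:
            raise ValueError("LabelMap values must be non-negative")
        self.labels = arr.astype(np.int32)

    @property
    def shape(self):
        return self.labels.shape

    def label_values(self):
        """Sorted non-background label values present in the map."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _load_nifti(path, expected_ndim):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != expected_ndim:
        raise ValueError(
            f"{path}: expected a {expected_ndim}D image, got {data.ndim}D "
            f"with shape {data.shape}"
        )
    return img, data


def read_volume(path) -> Volume:
    """Read a 3D NIfTI volume; spacing is taken from the header zooms."""
    img, data = _load_nifti(path, 3)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.nan_to_num(data.astype(np.float32)), spacing)


def write_volume(v: Volume, path) -> None:
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))


def read_labels(path) -> LabelMap:
    _, data = _load_nifti(path, 3)
    return LabelMap(np.round(data).astype(np.int32))


def write_labels(l: LabelMap, path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(l.labels.astype(np.int16), affine), str(path))


def read_field(path) -> DisplacementField:
    """Read a displacement field stored as 4D NIfTI with last dimension 3."""
    _, data = _load_nifti(path, 4)
    if data.shape[-1] != 3:
        raise ValueError(f"{path}: displacement NIfTI must have last dim 3")
    return DisplacementField(np.moveaxis(data.astype(np.float32), -1, 0))


def write_field(phi: DisplacementField, path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    data = np.moveaxis(phi.u.astype(np.float32), 0, -1)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def crop_center(v: Volume, target_shape) -> Volume:
    """Centered crop; the left margin per axis is floor((in - out) / 2)."""
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3:
        raise ValueError("target_shape must have three entries")
    for axis, (n, t) in enumerate(zip(v.shape, target_shape)):
        if t > n:
            raise ValueError(
                f"crop target {target_shape} exceeds input shape {v.shape} "
                f"on axis {axis}"
            )
        if t < 1:
            raise ValueError("crop target dimensions must be >= 1")
    off = [(n - t) // 2 for n, t in zip(v.shape, target_shape)]
    sl = tuple(slice(o, o + t) for o, t in zip(off, target_shape))
    return Volume(v.data[sl].copy(), v.spacing)


def normalize(v: Volume, method: str = "minmax") -> Volume:
    """Intensity normalization.

    ``minmax`` rescales to [0, 1] (a constant volume maps to zeros);
    ``zscore`` subtracts the mean and divides by the standard deviation.
    """
    data = v.data.astype(np.float64)
    if method == "minmax":
        lo, hi = data.min(), data.max()
        out = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    elif method == "zscore":
        sd = data.std()
        out = np.zeros_like(data) if sd == 0 else (data - data.mean()) / sd
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return Volume(out.astype(np.float32), v.spacing)
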