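"""Raster carriers and physical-unit bookkeeping.

A :class:`VoxelGrid` is a 3D scalar field with per-axis voxel spacing in
micrometres; a :class:`BinaryMask` is its boolean counterpart.  Axis order is
``(z, y, x)``, indices are 0-based, and the physical coordinate of voxel
``(i, j, k)`` is ``index * spacing + origin`` (μm).  All physical volumes are
reported in mm³ (1 mm³ = 1e9 μm³).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import tifffile

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "load_grid",
    "save_grid",
    "load_mask",
    "save_mask",
    "downsample_grid",
    "mask_volume_mm3",
    "MetadataError",
    "ShapeError",
]

UM3_PER_MM3 = 1e9

#: default dataset name for flat HDF5 volumes
HDF5_DATASET = "volume"
HDF5_SPACING_ATTR = "spacing_um"


class MetadataError(ValueError):
    """Spacing (or other required metadata) is missing."""


class ShapeError(ValueError):
    """Array does not have exactly three axes with at least one voxel each."""


def _check_geometry(values: np.ndarray, spacing: Sequence[float]) -> tuple[float, float, float]:
    if values.ndim != 3 or min(values.shape) < 1:
        raise ShapeError(f"expected a 3D array with >=1 voxel per axis, got shape {values.shape}")
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing must be three positive values in um, got {spacing}")
    return sp


@dataclass
class VoxelGrid:
    """3D scalar field with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Intensities in arbitrary units.
    spacing : (float, float, float)
        Voxel edge lengths in μm, ordered (z, y, x).
    channel : str
        Label, conventionally "vessel", "extravasation" or "hypoxia".
    origin : (float, float, float)
        Physical offset of voxel (0, 0, 0) in μm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = _check_geometry(self.values, self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """Boolean raster sharing a VoxelGrid's geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = ""
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing = _check_geometry(self.values, self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def like(self, values: np.ndarray, channel: Optional[str] = None) -> "BinaryMask":
        return BinaryMask(values, self.spacing, channel if channel is not None else self.channel, self.origin)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sitk():
    import SimpleITK as sitk  # deferred: only needed for NRRD

    return sitk


def load_grid(
    path: str | os.PathLike,
    spacing_override: Optional[Sequence[float]] = None,
    channel: str = "",
    dataset: str = HDF5_DATASET,
) -> VoxelGrid:
    """Read a 3D volume from TIFF / NRRD / HDF5.

    Spacing is taken from file metadata when present (NRRD always carries it;
    HDF5 via the ``spacing_um`` dataset attribute), otherwise from
    ``spacing_override``.  Raises :class:`MetadataError` when neither is
    available and :class:`ShapeError` for non-3D data.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    spacing: Optional[tuple[float, float, float]] = None
    if suffix in (".tif", ".tiff"):
        values = np.asarray(tifffile.imread(str(path)))
    elif suffix == ".nrrd":
        sitk = _sitk()
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img)  # (z, y, x)
        sx, sy, sz = img.GetSpacing()
        spacing = (float(sz), float(sy), float(sx))
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise IOError(f"dataset {dataset!r} not found in {path}")
            ds = f[dataset]
            values = ds[()]
            if HDF5_SPACING_ATTR in ds.attrs:
                spacing = tuple(float(s) for s in ds.attrs[HDF5_SPACING_ATTR])
    else:
        raise IOError(f"unrecognized raster format: {path}")
    if values.ndim != 3:
        raise ShapeError(f"{path}: expected 3D data, got shape {values.shape}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise MetadataError(f"{path}: no spacing metadata; pass spacing_override")
    return VoxelGrid(values, spacing, channel=channel)


def save_grid(grid: VoxelGrid, path: str | os.PathLike, dataset: str = HDF5_DATASET) -> None:
    """Write a VoxelGrid to TIFF, NRRD or HDF5 (spacing preserved for the latter two)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), grid.values)
    elif suffix == ".nrrd":
        sitk = _sitk()
        img = sitk.GetImageFromArray(grid.values)
        sz, sy, sx = grid.spacing
        img.SetSpacing((float(sx), float(sy), float(sz)))
        sitk.WriteImage(img, str(path))
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=grid.values)
            ds.attrs[HDF5_SPACING_ATTR] = np.asarray(grid.spacing, dtype=float)
    else:
        raise IOError(f"unrecognized raster format: {path}")


def save_mask(mask: BinaryMask, path: str | os.PathLike, dataset: str = HDF5_DATASET) -> None:
    """Write a mask as uint8 (NRRD or HDF5)."""
    save_grid(VoxelGrid(mask.values.astype(np.uint8), mask.spacing, mask.channel, mask.origin), path, dataset)


def load_mask(path: str | os.PathLike, spacing_override: Optional[Sequence[float]] = None,
              channel: str = "", dataset: str = HDF5_DATASET) -> BinaryMask:
    g = load_grid(path, spacing_override, channel, dataset)
    return BinaryMask(g.values > 0, g.spacing, g.channel, g.origin)


# ---------------------------------------------------------------------------
# Resampling and volumes
# ---------------------------------------------------------------------------

def downsample_grid(grid: VoxelGrid, factor: int) -> VoxelGrid:
    """Block-mean downsampling by an integer factor per axis.

    Trailing partial blocks are averaged over the voxels actually present, so
    tissue at the volume border is not discarded.  Output spacing is the input
    spacing multiplied by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(grid, values=grid.values.copy())
    out = np.asarray(grid.values, dtype=np.float64)
    for ax in range(3):
        n = out.shape[ax]
        starts = np.arange(0, n, factor)
        sums = np.add.reduceat(out, starts, axis=ax)
        counts = np.minimum(starts + factor, n) - starts
        shape = [1, 1, 1]
        shape[ax] = len(starts)
        out = sums / counts.reshape(shape)
    spacing = tuple(s * factor for s in grid.spacing)
    return VoxelGrid(out, spacing, grid.channel, grid.origin)


def mask_volume_mm3(mask: BinaryMask) -> float:
    """Physical volume of the true voxels: count × voxel volume, in mm³."""
    return mask.count() * float(np.prod(mask.spacing)) / UM3_PER_MM3
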