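"""Lesion segmentation by mirrored-hemisphere subtraction.

The contusion cavity in a controlled-cortical-impact brain is a unilateral
loss of tissue.  Because the uninjured hemisphere is a close mirror image of
the injured one, the cavity can be delineated without an atlas: segment the
tissue, solidify the outer surface so the cavity mouth is bridged, split the
brain at the centre-of-mass sagittal plane, mirror the contralateral half
onto the ipsilateral half, register by translation and subtract.  What the
mirror covers but the injured hemisphere lacks is the lesion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, signal as scipy_signal
from skimage.filters import threshold_otsu

from .grids import BinaryMask, VoxelGrid, mask_volume_mm3

__all__ = [
    "MidsagittalPlane",
    "LesionModel",
    "segment_tissue",
    "solidify_surface",
    "find_midsagittal",
    "mirror_subtract_lesion",
    "lesion_boundary",
    "build_lesion_model",
    "remove_small_components",
    "EmptyTissueError",
]


class EmptyTissueError(ValueError):
    """Thresholding produced no tissue voxels."""


@dataclass
class MidsagittalPlane:
    """The left-right splitting plane: an axis index and a fractional position."""

    axis: int
    plane_position: float


@dataclass
class LesionModel:
    solid_mask: BinaryMask
    plane: MidsagittalPlane
    lesion_mask: BinaryMask
    lesion_volume_mm3: float


def _spherical_dilate(mask: np.ndarray, radius_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Dilation by a Euclidean ball of physical radius (EDT formulation)."""
    return ndimage.distance_transform_edt(~mask, sampling=spacing) <= radius_um


def _spherical_erode(mask: np.ndarray, radius_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Erosion by a Euclidean ball of physical radius (EDT formulation)."""
    return ndimage.distance_transform_edt(mask, sampling=spacing) > radius_um


def segment_tissue(grid: VoxelGrid, threshold: float | str = "auto") -> BinaryMask:
    """Threshold the autofluorescence channel and keep the largest component.

    ``threshold="auto"`` selects Otsu's threshold on the intensity histogram;
    voxels strictly above the threshold are tissue.  Raises
    :class:`EmptyTissueError` when nothing survives.
    """
    if threshold == "auto":
        thr = float(threshold_otsu(np.asarray(grid.values)))
    else:
        thr = float(threshold)
    raw = grid.values > thr
    if not raw.any():
        raise EmptyTissueError(f"no voxels above threshold {thr}")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        raw = labels == (int(np.argmax(sizes)) + 1)
    return BinaryMask(raw, grid.spacing, channel="tissue", origin=grid.origin)


def solidify_surface(tissue: BinaryMask, closing_radius_um: float = 300.0) -> BinaryMask:
    """Bridge surface cavities and fill internal holes.

    Morphological closing with a spherical structuring element of the given
    physical radius, followed by hole filling.  The output is a superset of
    the input; a surface cavity whose mouth half-width is below the closing
    radius becomes part of the solid.  This is the raster analogue of
    shrink-wrap surface solidification.
    """
    if not tissue.values.any():
        raise ValueError("empty tissue mask")
    if closing_radius_um < max(tissue.spacing):
        raise ValueError(f"closing radius {closing_radius_um} um is below one voxel")
    # pad with background so the dilated surface never touches the border
    pad = [int(np.ceil(closing_radius_um / s)) + 1 for s in tissue.spacing]
    padded = np.pad(tissue.values, [(p, p) for p in pad])
    dilated = _spherical_dilate(padded, closing_radius_um, tissue.spacing)
    closed = _spherical_erode(dilated, closing_radius_um, tissue.spacing)
    sl = tuple(slice(p, n - p) for p, n in zip(pad, closed.shape))
    out = ndimage.binary_fill_holes(closed[sl] | tissue.values)
    return tissue.like(out)


def find_midsagittal(solid: BinaryMask, lr_axis: int = 2) -> MidsagittalPlane:
    """Centre of mass of the solid mask along the left-right axis."""
    if not solid.values.any():
        raise ValueError("empty solid mask")
    com = ndimage.center_of_mass(solid.values)
    return MidsagittalPlane(axis=lr_axis, plane_position=float(com[lr_axis]))


def _reflect_about(mask: np.ndarray, axis: int, position: float) -> np.ndarray:
    """Reflect a boolean volume about the plane ``index = position`` on ``axis``.

    Implemented as a flip plus a subvoxel linear-interpolation shift so the
    reflection axis sits exactly at the fractional plane position.
    """
    flipped = np.flip(mask, axis=axis).astype(float)
    n = mask.shape[axis]
    shift = [0.0, 0.0, 0.0]
    shift[axis] = 2.0 * position - (n - 1)
    out = ndimage.shift(flipped, shift, order=1, mode="constant", cval=0.0)
    return out >= 0.5


def _best_translation(fixed: np.ndarray, moving: np.ndarray, search: int) -> tuple[int, int, int]:
    """Integer translation of ``moving`` maximizing overlap with ``fixed``.

    FFT cross-correlation evaluated over all lags, restricted to the
    ±``search`` voxel window (equivalent to exhaustive search).
    """
    corr = scipy_signal.fftconvolve(fixed.astype(np.float32), moving[::-1, ::-1, ::-1].astype(np.float32), mode="full")
    center = np.asarray(moving.shape) - 1
    window = []
    for a in range(3):
        lo = max(center[a] - search, 0)
        hi = min(center[a] + search + 1, corr.shape[a])
        window.append(slice(lo, hi))
    sub = corr[tuple(window)]
    best = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return tuple(int(best[a] + window[a].start - center[a]) for a in range(3))


def _translate(mask: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    out = mask
    for a, o in enumerate(offset):
        out = np.roll(out, o, axis=a)
        idx = [slice(None)] * 3
        if o > 0:
            idx[a] = slice(0, o)
        elif o < 0:
            idx[a] = slice(o, None)
        else:
            continue
        out = out.copy()
        out[tuple(idx)] = False
    return out


def remove_small_components(mask: np.ndarray, spacing: tuple[float, float, float],
                            min_mm3: float) -> np.ndarray:
    """Drop connected components whose physical volume is below ``min_mm3``."""
    if min_mm3 <= 0 or not mask.any():
        return mask
    voxel_mm3 = float(np.prod(spacing)) / 1e9
    min_vox = min_mm3 / voxel_mm3
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_vox) + 1
    return np.isin(labels, keep)


def mirror_subtract_lesion(
    solid: BinaryMask,
    plane: MidsagittalPlane,
    ipsilateral_side: int = +1,
    search_radius: int = 10,
    min_component_mm3: float = 1e-3,
) -> BinaryMask:
    """Derive the lesion mask by mirrored-hemisphere subtraction.

    The contralateral half of the solidified brain is reflected across the
    midsagittal plane (with subvoxel shift so the reflection axis is exactly
    the plane position), rigidly aligned to the ipsilateral half by the
    translation (±``search_radius`` voxels per axis) maximizing mask overlap,
    and subtracted: lesion = mirrored contralateral AND NOT ipsilateral
    solid, restricted to the ipsilateral side.  Components smaller than
    ``min_component_mm3`` are removed.
    """
    ax = plane.axis
    n = solid.shape[ax]
    p = plane.plane_position
    if not (0 <= p <= n):
        raise ValueError(f"plane position {p} outside axis of length {n}")
    if ipsilateral_side not in (+1, -1):
        raise ValueError("ipsilateral_side must be +1 or -1")

    idx = np.arange(n).reshape([-1 if a == ax else 1 for a in range(3)])
    ipsi_region = idx > p if ipsilateral_side > 0 else idx < p
    ipsi_region = np.broadcast_to(ipsi_region, solid.shape)

    mirrored = _reflect_about(solid.values, ax, p)
    mirrored_ipsi = mirrored & ipsi_region
    ipsi_solid = solid.values & ipsi_region

    offset = _best_translation(ipsi_solid, mirrored_ipsi, search_radius)
    mirrored_reg = _translate(mirrored_ipsi, offset)

    lesion = mirrored_reg & ~solid.values & ipsi_region
    lesion = remove_small_components(lesion, solid.spacing, min_component_mm3)
    return solid.like(lesion, channel="lesion")


_FACES = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def lesion_boundary(
    lesion: BinaryMask,
    solid: BinaryMask,
    surface_window: Optional[BinaryMask] = None,
) -> BinaryMask:
    """Tissue voxels 6-adjacent to the lesion: the seed surface for layering.

    When the lesion mask is empty (sham-like brains) and a craniotomy
    ``surface_window`` is supplied, the boundary falls back to the tissue
    surface under that window; with neither, the boundary is empty.
    """
    tissue = solid.values & ~lesion.values
    if lesion.values.any():
        dil = ndimage.binary_dilation(lesion.values, structure=_STRUCT6)
        boundary = tissue & dil
    elif surface_window is not None:
        exterior = ~solid.values & surface_window.values
        dil = ndimage.binary_dilation(exterior, structure=_STRUCT6)
        boundary = tissue & dil
    else:
        boundary = np.zeros_like(tissue)
    return solid.like(boundary, channel="lesion_boundary")


def build_lesion_model(
    grid: VoxelGrid,
    threshold: float | str = "auto",
    closing_radius_um: float = 300.0,
    ipsilateral_side: int = +1,
    lr_axis: int = 2,
    search_radius: int = 10,
    min_component_mm3: float = 1e-3,
) -> LesionModel:
    """Full lesion pipeline on one autofluorescence/extravasation channel."""
    tissue = segment_tissue(grid, threshold)
    solid = solidify_surface(tissue, closing_radius_um)
    plane = find_midsagittal(solid, lr_axis)
    lesion = mirror_subtract_lesion(solid, plane, ipsilateral_side, search_radius, min_component_mm3)
    return LesionModel(solid, plane, lesion, mask_volume_mm3(lesion))
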