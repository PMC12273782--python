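"""Ground-truthed synthetic brain phantoms.

The phantom emulates the statistical structure the quantification pipeline
assumes in a cleared, light-sheet-imaged mouse brain: a bilaterally
near-symmetric solid tissue ellipsoid with autofluorescent background, a
branched bright-tube vascular tree, an optional unilateral lesion cavity
opening to the dorsal surface, perilesional hypoxia/extravasation signal
decaying exponentially with distance from the lesion surface, and additive
Gaussian noise.  Every geometric quantity the pipeline later estimates
(lesion volume, per-depth vessel length/volume, supra-background signal
volume) is also computed analytically from the generating primitives and
returned as a :class:`PhantomTruth`.

Physical frame: the brain ellipsoid is centred at the physical origin
``(0, 0, 0)`` μm; axis order is ``(z, y, x)`` with +z dorsal and x the
left-right axis, so the midsagittal plane is ``x = 0`` and the lesioned
(ipsilateral) hemisphere is ``x > 0``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .grids import BinaryMask, VoxelGrid, UM3_PER_MM3

__all__ = [
    "PhantomSpec",
    "TubeSegment",
    "PhantomTruth",
    "generate_vessel_tree",
    "rasterize_phantom",
    "PhantomConfigurationError",
]

#: z-score of the 99.9th percentile of a standard normal; used as the default
#: floor defining "true" supra-background signal, so truth matches what a
#: 99.9th-percentile background threshold can recover from noise-free signal.
Z_999 = 3.0902


class PhantomConfigurationError(ValueError):
    """The phantom specification is geometrically inconsistent."""


@dataclass
class TubeSegment:
    """One straight cylindrical vessel piece in physical μm coordinates."""

    start: np.ndarray
    end: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.radius = float(self.radius)

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def volume_um3(self) -> float:
        return math.pi * self.radius**2 * self.length_um


@dataclass
class PhantomSpec:
    """Parameters of the synthetic brain.

    Lengths in μm, intensities in arbitrary units matching the imaging
    channels.  ``lesion_center`` is relative to the brain centre and must lie
    strictly in the ipsilateral (x > 0) hemisphere.
    """

    brain_semi_axes: tuple[float, float, float] = (600.0, 800.0, 1000.0)
    spacing: tuple[float, float, float] = (20.0, 20.0, 20.0)
    root_radius: float = 30.0
    radius_decay: float = 0.75
    branch_angle_range: tuple[float, float] = (20.0, 60.0)
    min_radius: Optional[float] = None  # default 1.5 x min spacing
    segments_per_branch: int = 4
    branching_depth: int = 4
    branch_length_um: Optional[float] = None  # default 0.5 x min semi-axis
    n_roots: int = 2
    lesion_center: Optional[tuple[float, float, float]] = None
    lesion_semi_axes: Optional[tuple[float, float, float]] = None
    signal_decay_length: float = 150.0
    vessel_intensity: float = 800.0
    signal_peak_intensity: float = 400.0
    autofluorescence_level: float = 100.0
    noise_sd: float = 10.0
    truth_bin_um: float = 100.0
    signal_truth_floor: Optional[float] = None  # default Z_999 * noise_sd
    seed: int = 0
    tree_seed: Optional[int] = None  # separate vessel-tree seed (default: seed)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.brain_semi_axes) or any(s <= 0 for s in self.spacing):
            raise ValueError("brain semi-axes and spacings must be positive")
        if not (0 < self.radius_decay <= 1):
            raise ValueError("radius_decay must lie in (0, 1]")
        if self.lesion_center is not None:
            if self.lesion_semi_axes is None:
                raise ValueError("lesion_center given without lesion_semi_axes")
            if self.lesion_center[2] <= 0:
                raise ValueError("lesion_center must lie strictly in the ipsilateral (x > 0) hemisphere")

    @property
    def effective_min_radius(self) -> float:
        if self.min_radius is not None:
            return float(self.min_radius)
        return 1.5 * min(self.spacing)

    @property
    def effective_branch_length(self) -> float:
        if self.branch_length_um is not None:
            return float(self.branch_length_um)
        return 0.5 * min(self.brain_semi_axes)

    @property
    def effective_signal_floor(self) -> float:
        if self.signal_truth_floor is not None:
            return float(self.signal_truth_floor)
        return Z_999 * self.noise_sd


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a rasterized phantom.

    Per-depth-bin vessel quantities are keyed by bin index ``k`` covering the
    interval ``[k*bin_width_um, (k+1)*bin_width_um)`` of distance from the
    lesion surface (segment-midpoint binning); they are empty when the
    phantom has no lesion.  Segments whose midpoint falls inside the lesion
    cavity are excluded from both totals and bins (the cavity erases them
    from the raster).
    """

    lesion_volume_mm3: float
    total_vessel_length_mm: float
    total_vessel_volume_mm3: float
    vessel_length_mm_by_bin: dict[int, float]
    vessel_volume_mm3_by_bin: dict[int, float]
    signal_volume_mm3: dict[str, float]
    bin_width_um: float


# ---------------------------------------------------------------------------
# Vessel tree generation
# ---------------------------------------------------------------------------

def _inside_ellipsoid(p: np.ndarray, semi: Sequence[float]) -> bool:
    return float(np.sum((p / np.asarray(semi)) ** 2)) <= 1.0


def _clip_to_ellipsoid(p: np.ndarray, q: np.ndarray, semi: Sequence[float]) -> np.ndarray:
    """Point on segment p→q where it crosses the ellipsoid surface (p inside)."""
    semi = np.asarray(semi, dtype=float)
    d = q - p
    a = np.sum((d / semi) ** 2)
    b = 2 * np.sum(p * d / semi**2)
    c = np.sum((p / semi) ** 2) - 1.0
    disc = b * b - 4 * a * c
    if disc < 0 or a == 0:
        return q
    t = (-b + math.sqrt(disc)) / (2 * a)
    t = min(max(t, 0.0), 1.0)
    return p + t * d


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d (deterministic)."""
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    v /= np.linalg.norm(v)
    return u, v


def generate_vessel_tree(spec: PhantomSpec, seed: Optional[int] = None) -> list[TubeSegment]:
    """Grow a recursive bifurcating tube tree inside the brain ellipsoid.

    Roots sit on the ventral (−z) surface pointing dorsally.  Each branch is
    a straight run of ``segments_per_branch`` collinear segments of total
    length ``branch_length_um``; at every bifurcation the radius shrinks by
    ``radius_decay`` and each child deflects from the parent direction by an
    angle drawn uniformly from ``branch_angle_range`` (degrees), the two
    children at opposite azimuths.  Branches stop when the radius would fall
    below the minimum or on exiting the tissue ellipsoid (the final segment
    is clipped to the surface).  Fully deterministic for a fixed seed.
    """
    if seed is None:
        seed = spec.tree_seed if spec.tree_seed is not None else spec.seed
    rng = np.random.default_rng(seed)
    min_r = spec.effective_min_radius
    if min_r > spec.root_radius:
        warnings.warn("min_radius exceeds root_radius: no tree generated", stacklevel=2)
        return []
    semi = np.asarray(spec.brain_semi_axes, dtype=float)
    az, ay, ax = semi
    L = spec.effective_branch_length
    seg_len = L / spec.segments_per_branch
    lo, hi = (math.radians(a) for a in spec.branch_angle_range)
    segments: list[TubeSegment] = []

    def grow(p: np.ndarray, d: np.ndarray, r: float, depth: int) -> None:
        for _ in range(spec.segments_per_branch):
            q = p + d * seg_len
            if not _inside_ellipsoid(q, semi):
                q = _clip_to_ellipsoid(p, q, semi)
                if np.linalg.norm(q - p) > 1e-9:
                    segments.append(TubeSegment(p, q, r))
                return
            segments.append(TubeSegment(p, q, r))
            p = q
        if depth <= 0 or r * spec.radius_decay < min_r:
            return
        u, v = _orthonormal_frame(d)
        theta = rng.uniform(lo, hi)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        for branch_phi in (phi, phi + math.pi):
            child = math.cos(theta) * d + math.sin(theta) * (math.cos(branch_phi) * u + math.sin(branch_phi) * v)
            child /= np.linalg.norm(child)
            grow(p, child, r * spec.radius_decay, depth - 1)

    for i in range(spec.n_roots):
        # roots spread along y, alternating hemispheres, on the ventral surface
        xfrac = 0.45 if i % 2 == 0 else -0.45
        yfrac = -0.4 + 0.8 * (i // 2 + 0.5) / max(1, (spec.n_roots + 1) // 2)
        x0, y0 = xfrac * ax, yfrac * ay
        inside = 1.0 - (y0 / ay) ** 2 - (x0 / ax) ** 2
        z0 = -az * math.sqrt(max(inside, 0.0)) * 0.999
        p0 = np.array([z0, y0, x0])
        d0 = np.array([1.0, 0.0, 0.0])  # dorsal
        grow(p0, d0, spec.root_radius, spec.branching_depth)
    return segments


# ---------------------------------------------------------------------------
# Distance to an ellipsoid surface (for analytic depth binning)
# ---------------------------------------------------------------------------

def distance_to_ellipsoid(p: np.ndarray, center: Sequence[float], semi: Sequence[float]) -> float:
    """Euclidean distance from point ``p`` to the surface of an ellipsoid.

    Returns 0 for points inside.  Solves the Lagrange condition
    ``sum(a_i^2 y_i^2 / (a_i^2 + t)^2) = 1`` for the exterior foot point by
    bracketed root finding; exact closed form is used for spheres.
    """
    y = np.abs(np.asarray(p, dtype=float) - np.asarray(center, dtype=float))
    a = np.asarray(semi, dtype=float)
    if float(np.sum((y / a) ** 2)) <= 1.0:
        return 0.0
    if np.allclose(a, a[0]):
        return float(np.linalg.norm(y) - a[0])

    def f(t: float) -> float:
        return float(np.sum((a * y) ** 2 / (a**2 + t) ** 2)) - 1.0

    t_hi = float(np.linalg.norm(a * y) + np.max(a) ** 2)
    t = optimize.brentq(f, 0.0, t_hi, xtol=1e-9)
    foot = a**2 * y / (a**2 + t)
    return float(np.linalg.norm(y - foot))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _grid_axes(spec: PhantomSpec, margin_voxels: int = 3) -> tuple[list[np.ndarray], tuple[int, int, int], tuple[float, float, float]]:
    """Per-axis physical voxel-centre coordinates, symmetric about the origin."""
    coords, shape, origin = [], [], []
    for semi, sp in zip(spec.brain_semi_axes, spec.spacing):
        n = int(math.ceil(2 * semi / sp)) + 2 * margin_voxels
        o = -(n - 1) / 2.0 * sp
        coords.append(o + sp * np.arange(n))
        shape.append(n)
        origin.append(o)
    return coords, tuple(shape), tuple(origin)


def _rasterize_tubes(segments: list[TubeSegment], coords: list[np.ndarray],
                     shape: tuple[int, int, int], spacing: Sequence[float]) -> np.ndarray:
    """Boolean tube mask: voxel centres within radius of any segment."""
    mask = np.zeros(shape, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    origins = np.array([c[0] for c in coords])
    for seg in segments:
        pad = seg.radius + float(spacing.max())
        lo_phys = np.minimum(seg.start, seg.end) - pad
        hi_phys = np.maximum(seg.start, seg.end) + pad
        lo = np.maximum(np.floor((lo_phys - origins) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((hi_phys - origins) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        local = np.meshgrid(*(coords[a][lo[a]:hi[a]] for a in range(3)), indexing="ij")
        pts = np.stack(local, axis=-1)
        d = seg.end - seg.start
        ll = float(d @ d)
        if ll == 0:
            dist2 = np.sum((pts - seg.start) ** 2, axis=-1)
        else:
            t = np.clip(((pts - seg.start) @ d) / ll, 0.0, 1.0)
            proj = seg.start + t[..., None] * d
            dist2 = np.sum((pts - proj) ** 2, axis=-1)
        hit = dist2 <= seg.radius**2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= hit
    return mask


def _supersampled_cavity_volume(spec: PhantomSpec, coords: list[np.ndarray],
                                factor: int = 2) -> float:
    """Lesion ∩ brain ellipsoid volume by midpoint integration at finer resolution (mm³)."""
    lc = np.asarray(spec.lesion_center, dtype=float)
    ls = np.asarray(spec.lesion_semi_axes, dtype=float)
    semi = np.asarray(spec.brain_semi_axes, dtype=float)
    axes = []
    for a in range(3):
        sp = spec.spacing[a] / factor
        lo = lc[a] - ls[a] - sp
        hi = lc[a] + ls[a] + sp
        axes.append(np.arange(lo + sp / 2, hi, sp))
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    in_lesion = np.sum(((pts - lc) / ls) ** 2, axis=-1) <= 1.0
    in_brain = np.sum((pts / semi) ** 2, axis=-1) <= 1.0
    subvol = float(np.prod([spec.spacing[a] / factor for a in range(3)]))
    return float(np.count_nonzero(in_lesion & in_brain)) * subvol / UM3_PER_MM3


def rasterize_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, VoxelGrid, VoxelGrid, BinaryMask, PhantomTruth]:
    """Render the phantom to voxel grids and compute its analytic truth.

    Returns ``(vessel, extravasation, hypoxia, tissue_mask, truth)``.  The
    vessel channel carries tubes at ``vessel_intensity`` on autofluorescent
    tissue; the signal channels carry
    ``signal_peak_intensity * exp(-d / signal_decay_length)`` added to the
    autofluorescence, where ``d`` is the distance to the lesion surface,
    zeroed in the contralateral hemisphere beyond three decay lengths; the
    lesion cavity is background in every channel; Gaussian noise of sd
    ``noise_sd`` is added everywhere.  Deterministic for a fixed spec seed.
    """
    coords, shape, origin = _grid_axes(spec)
    semi = np.asarray(spec.brain_semi_axes, dtype=float)
    zz = (coords[0] / semi[0]) ** 2
    yy = (coords[1] / semi[1]) ** 2
    xx = (coords[2] / semi[2]) ** 2
    brain = zz[:, None, None] + yy[None, :, None] + xx[None, None, :] <= 1.0

    cavity = np.zeros(shape, dtype=bool)
    if spec.lesion_center is not None:
        lc = np.asarray(spec.lesion_center, dtype=float)
        ls = np.asarray(spec.lesion_semi_axes, dtype=float)
        lz = ((coords[0] - lc[0]) / ls[0]) ** 2
        ly = ((coords[1] - lc[1]) / ls[1]) ** 2
        lx = ((coords[2] - lc[2]) / ls[2]) ** 2
        cavity = (lz[:, None, None] + ly[None, :, None] + lx[None, None, :] <= 1.0) & brain
        if not cavity.any():
            raise PhantomConfigurationError("lesion ellipsoid does not intersect the tissue")
    tissue = brain & ~cavity

    segments = generate_vessel_tree(spec)
    tube_mask = _rasterize_tubes(segments, coords, shape, spec.spacing) if segments else np.zeros(shape, bool)

    af = spec.autofluorescence_level
    vessel = np.where(tissue, af, 0.0)
    vessel[tube_mask & tissue] = spec.vessel_intensity

    signal = np.zeros(shape, dtype=float)
    if cavity.any():
        d_um = ndimage.distance_transform_edt(~cavity, sampling=spec.spacing)
        signal = spec.signal_peak_intensity * np.exp(-d_um / spec.signal_decay_length)
        contra = coords[2][None, None, :] < 0
        far = d_um > 3.0 * spec.signal_decay_length
        signal[np.broadcast_to(contra, shape) & far] = 0.0
        signal[~tissue] = 0.0
    extrav = np.where(tissue, af, 0.0) + signal
    hypoxia = np.where(tissue, af, 0.0) + signal

    rng = np.random.default_rng(spec.seed)
    noisy = []
    for arr in (vessel, extrav, hypoxia):
        noisy.append(arr + (rng.standard_normal(shape) * spec.noise_sd if spec.noise_sd > 0 else 0.0))
    vessel, extrav, hypoxia = noisy

    truth = _compute_truth(spec, segments, coords, tissue, signal)

    sp = spec.spacing
    mk = lambda arr, ch: VoxelGrid(arr, sp, channel=ch, origin=origin)
    return (
        mk(vessel, "vessel"),
        mk(extrav, "extravasation"),
        mk(hypoxia, "hypoxia"),
        BinaryMask(tissue, sp, channel="tissue", origin=origin),
        truth,
    )


def _compute_truth(spec: PhantomSpec, segments: list[TubeSegment], coords: list[np.ndarray],
                   tissue: np.ndarray, signal: np.ndarray) -> PhantomTruth:
    has_lesion = spec.lesion_center is not None
    lesion_vol = _supersampled_cavity_volume(spec, coords) if has_lesion else 0.0

    length_by_bin: dict[int, float] = {}
    volume_by_bin: dict[int, float] = {}
    total_len_um = 0.0
    total_vol_um3 = 0.0
    for seg in segments:
        if has_lesion:
            mid = seg.midpoint
            inside = float(np.sum(((mid - np.asarray(spec.lesion_center)) / np.asarray(spec.lesion_semi_axes)) ** 2)) <= 1.0
            if inside:
                continue  # erased by the cavity
            d = distance_to_ellipsoid(mid, spec.lesion_center, spec.lesion_semi_axes)
            k = int(d // spec.truth_bin_um)
            length_by_bin[k] = length_by_bin.get(k, 0.0) + seg.length_um / 1000.0
            volume_by_bin[k] = volume_by_bin.get(k, 0.0) + seg.volume_um3 / UM3_PER_MM3
        total_len_um += seg.length_um
        total_vol_um3 += seg.volume_um3

    floor = spec.effective_signal_floor
    voxel_mm3 = float(np.prod(spec.spacing)) / UM3_PER_MM3
    sig_vol = float(np.count_nonzero((signal > floor) & tissue)) * voxel_mm3
    return PhantomTruth(
        lesion_volume_mm3=lesion_vol,
        total_vessel_length_mm=total_len_um / 1000.0,
        total_vessel_volume_mm3=total_vol_um3 / UM3_PER_MM3,
        vessel_length_mm_by_bin=length_by_bin,
        vessel_volume_mm3_by_bin=volume_by_bin,
        signal_volume_mm3={"extravasation": sig_vol, "hypoxia": sig_vol},
        bin_width_um=spec.truth_bin_um,
    )
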