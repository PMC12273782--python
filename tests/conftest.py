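"""Shared fixtures: small deterministic phantoms and raster helpers."""

from __future__ import annotations

import numpy as np
import pytest

from tbi3d.grids import BinaryMask, VoxelGrid
from tbi3d.phantom import PhantomSpec, rasterize_phantom


def make_cylinder_mask(shape, axis, radius_vox, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Axis-aligned solid cylinder spanning the full extent of ``axis``."""
    centers = [(n - 1) / 2.0 for n in shape]
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    other = [a for a in range(3) if a != axis]
    r2 = sum((grids[a] - centers[a]) ** 2 for a in other)
    return BinaryMask(r2 <= radius_vox**2, spacing)


@pytest.fixture(scope="session")
def lesioned_phantom():
    """Small brain with an open dorsal cavity, vessels and signal; shared
    across tests (read-only)."""
    spec = PhantomSpec(
        brain_semi_axes=(500.0, 600.0, 800.0),
        spacing=(15.0, 15.0, 15.0),
        root_radius=25.0,
        min_radius=10.0,
        branching_depth=3,
        branch_length_um=350.0,
        lesion_center=(450.0, 0.0, 350.0),
        lesion_semi_axes=(250.0, 250.0, 250.0),
        signal_decay_length=150.0,
        noise_sd=10.0,
        seed=7,
    )
    return spec, rasterize_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, lesion-free, vessel-free symmetric brain."""
    spec = PhantomSpec(
        brain_semi_axes=(400.0, 450.0, 600.0),
        spacing=(20.0, 20.0, 20.0),
        root_radius=0.1,  # degenerate tree -> no vessels
        min_radius=50.0,
        noise_sd=0.0,
        seed=1,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = rasterize_phantom(spec)
    return spec, out
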