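"""Tissue segmentation, surface solidification and mirror-subtract lesion masking."""

import numpy as np
import pytest
from scipy import ndimage

from tbi3d.grids import BinaryMask, VoxelGrid, mask_volume_mm3
from tbi3d.lesion import (
    EmptyTissueError,
    MidsagittalPlane,
    build_lesion_model,
    find_midsagittal,
    lesion_boundary,
    mirror_subtract_lesion,
    segment_tissue,
    solidify_surface,
)


def ellipsoid_mask(shape, semi_vox, spacing=(1.0, 1.0, 1.0), center=None):
    if center is None:
        center = [(n - 1) / 2.0 for n in shape]
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    s = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_vox))
    return BinaryMask(s <= 1.0, spacing)


class TestSegmentTissue:
    def test_all_zero_raises(self):
        with pytest.raises(EmptyTissueError):
            segment_tissue(VoxelGrid(np.zeros((8, 8, 8)), (1, 1, 1)), threshold=10)

    def test_perfect_separation_recovers_exact_mask(self, clean_phantom):
        spec, (_, extrav, _, tissue, _) = clean_phantom
        rec = segment_tissue(extrav, threshold=50)
        np.testing.assert_array_equal(rec.values, tissue.values)

    def test_noisy_phantom_volume_within_2pct(self):
        from tbi3d.phantom import PhantomSpec, rasterize_phantom

        spec = PhantomSpec(
            brain_semi_axes=(400.0, 450.0, 600.0), spacing=(20.0, 20.0, 20.0),
            root_radius=0.1, min_radius=50.0, noise_sd=10.0, seed=2,
        )
        with pytest.warns(UserWarning):
            _, extrav, _, tissue, _ = rasterize_phantom(spec)[:5]
        rec = segment_tissue(extrav, threshold="auto")
        assert mask_volume_mm3(rec) == pytest.approx(mask_volume_mm3(tissue), rel=0.02)

    def test_keeps_largest_component_only(self):
        vals = np.zeros((10, 10, 20))
        vals[2:8, 2:8, 2:8] = 100.0  # big blob
        vals[4:6, 4:6, 15:17] = 100.0  # small distant blob
        mask = segment_tissue(VoxelGrid(vals, (1, 1, 1)), threshold=50)
        assert mask.count() == 6 * 6 * 6


class TestSolidify:
    def test_convex_ellipsoid_nearly_unchanged(self):
        ell = ellipsoid_mask((40, 44, 48), (14, 16, 18), spacing=(10.0, 10.0, 10.0))
        out = solidify_surface(ell, closing_radius_um=80.0)
        inter = np.count_nonzero(out.values & ell.values)
        union = np.count_nonzero(out.values | ell.values)
        assert inter / union >= 0.999

    def test_superset_of_input(self):
        ell = ellipsoid_mask((30, 30, 30), (10, 10, 10), spacing=(10.0, 10.0, 10.0))
        out = solidify_surface(ell, closing_radius_um=50.0)
        assert np.all(out.values[ell.values])

    def test_bridges_surface_cavity(self):
        # 500-um-wide cylindrical pocket in a flat surface, 400-um closing
        # radius: the ball cannot enter the mouth, so the pocket solidifies
        # except for the shallow sag cap at the rim (~88 um deep).
        sp = (25.0, 25.0, 25.0)
        vals = np.zeros((44, 40, 40), bool)
        vals[10:, :, :] = True  # slab with flat top at z=10
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        pocket2d = (yy - 19.5) ** 2 + (xx - 19.5) ** 2 <= 10.0**2
        cavity = np.zeros_like(vals)
        cavity[10:30, pocket2d] = True  # 500 um deep pocket
        open_tissue = BinaryMask(vals & ~cavity, sp)
        out = solidify_surface(open_tissue, closing_radius_um=400.0)
        covered = np.count_nonzero(out.values & cavity) / cavity.sum()
        assert covered > 0.7
        deep_half = cavity.copy()
        deep_half[:20] = False
        assert np.all(out.values[deep_half])

    def test_no_internal_cavities_remain(self):
        ell = ellipsoid_mask((32, 32, 32), (12, 12, 12), spacing=(10.0, 10.0, 10.0))
        holey = ell.values.copy()
        holey[14:18, 14:18, 14:18] = False
        out = solidify_surface(BinaryMask(holey, ell.spacing), closing_radius_um=20.0)
        # complement must be a single connected component (the exterior)
        _, n = ndimage.label(~out.values)
        assert n == 1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            solidify_surface(BinaryMask(np.zeros((8, 8, 8), bool), (1, 1, 1)), 5.0)

    def test_subvoxel_radius_raises(self):
        ell = ellipsoid_mask((16, 16, 16), (5, 5, 5), spacing=(10.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            solidify_surface(ell, closing_radius_um=5.0)


class TestMidsagittal:
    def test_symmetric_mask(self):
        vals = np.zeros((5, 5, 101), bool)
        vals[2, 2, 40:61] = True  # symmetric about index 50
        assert find_midsagittal(BinaryMask(vals, (1, 1, 1)), 2).plane_position == pytest.approx(50.0)

    def test_single_voxel(self):
        vals = np.zeros((5, 5, 11), bool)
        vals[1, 2, 7] = True
        assert find_midsagittal(BinaryMask(vals, (1, 1, 1)), 2).plane_position == pytest.approx(7.0)

    def test_two_blob_weighted_mean_oracle(self):
        vals = np.zeros((4, 4, 30), bool)
        vals[1, 1, 2:5] = True
        vals[2, 2, 20:28] = True
        plane = find_midsagittal(BinaryMask(vals, (1, 1, 1)), 2)
        idx = np.nonzero(vals)[2]
        assert plane.plane_position == pytest.approx(idx.mean())

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            find_midsagittal(BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1)))


class TestMirrorSubtract:
    def test_symmetric_solid_gives_empty_lesion(self):
        ell = ellipsoid_mask((30, 34, 41), (12, 14, 17), spacing=(10.0, 10.0, 10.0))
        plane = find_midsagittal(ell, 2)
        lesion = mirror_subtract_lesion(ell, plane, min_component_mm3=0.0)
        assert lesion.count() == 0

    def test_recovers_cavity_within_10pct(self, lesioned_phantom):
        spec, (_, extrav, _, tissue, truth) = lesioned_phantom
        model = build_lesion_model(extrav, closing_radius_um=150.0)
        assert model.lesion_volume_mm3 == pytest.approx(truth.lesion_volume_mm3, rel=0.10)

    def test_contralateral_cavity_not_reported(self):
        # carve a notch on the LEFT (x<plane) side but look for lesions on the right
        ell = ellipsoid_mask((30, 30, 41), (12, 12, 17), spacing=(10.0, 10.0, 10.0))
        notch = ellipsoid_mask((30, 30, 41), (4, 4, 4), spacing=(10.0, 10.0, 10.0),
                               center=(5.0, 14.5, 8.0))
        carved = BinaryMask(ell.values & ~notch.values, ell.spacing)
        plane = find_midsagittal(ell, 2)
        lesion = mirror_subtract_lesion(carved, plane, ipsilateral_side=+1, min_component_mm3=0.0)
        # the true cavity is contralateral; nothing should appear ipsilaterally
        assert mask_volume_mm3(lesion) <= 0.1 * mask_volume_mm3(notch)

    def test_plane_outside_grid_raises(self):
        ell = ellipsoid_mask((10, 10, 10), (4, 4, 4))
        with pytest.raises(ValueError):
            mirror_subtract_lesion(ell, MidsagittalPlane(2, 99.0))

    def test_translation_invariance_of_lesion_volume(self, lesioned_phantom):
        spec, (_, extrav, _, _, truth) = lesioned_phantom
        base = build_lesion_model(extrav, closing_radius_um=150.0).lesion_volume_mm3
        shifted = VoxelGrid(np.roll(extrav.values, (2, -3, 1), axis=(0, 1, 2)), extrav.spacing)
        moved = build_lesion_model(shifted, closing_radius_um=150.0).lesion_volume_mm3
        assert moved == pytest.approx(base, rel=0.02)


class TestLesionBoundary:
    def test_cubic_lesion_boundary_matches_adjacency_scan(self):
        solid = BinaryMask(np.ones((20, 20, 20), bool), (1, 1, 1))
        lesion = BinaryMask(np.zeros((20, 20, 20), bool), (1, 1, 1))
        lesion.values[8:12, 8:12, 8:12] = True
        boundary = lesion_boundary(lesion, solid)
        # independent 6-neighbourhood scan
        expected = np.zeros_like(solid.values)
        tissue = solid.values & ~lesion.values
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        for i, j, k in np.argwhere(tissue):
            for dz, dy, dx in offs:
                z, y, x = i + dz, j + dy, k + dx
                if 0 <= z < 20 and 0 <= y < 20 and 0 <= x < 20 and lesion.values[z, y, x]:
                    expected[i, j, k] = True
                    break
        np.testing.assert_array_equal(boundary.values, expected)

    def test_empty_lesion_no_window_gives_empty_boundary(self):
        solid = BinaryMask(np.ones((8, 8, 8), bool), (1, 1, 1))
        lesion = BinaryMask(np.zeros((8, 8, 8), bool), (1, 1, 1))
        assert lesion_boundary(lesion, solid).count() == 0

    def test_lesion_equals_solid_gives_empty_boundary(self):
        solid = BinaryMask(np.ones((8, 8, 8), bool), (1, 1, 1))
        assert lesion_boundary(solid, solid).count() == 0

    def test_craniotomy_window_fallback_for_sham(self):
        solid = ellipsoid_mask((24, 24, 24), (9, 9, 9), spacing=(10.0, 10.0, 10.0))
        lesion = BinaryMask(np.zeros((24, 24, 24), bool), solid.spacing)
        window = BinaryMask(np.zeros((24, 24, 24), bool), solid.spacing)
        window.values[:6, 8:16, 8:16] = True  # dorsal window
        boundary = lesion_boundary(lesion, solid, surface_window=window)
        assert boundary.count() > 0
        assert np.all(solid.values[boundary.values])
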