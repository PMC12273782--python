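"""Frangi vesselness, skeletonization, radius recovery and per-layer metrics."""

import math

import numpy as np
import pytest

from tbi3d.grids import BinaryMask, VoxelGrid
from tbi3d.layers import LayerSpec, build_layers
from tbi3d.vessels import (
    VesselnessParams,
    frangi_vesselness,
    segment_vessels,
    skeleton_totals,
    skeletonize_vessels,
    vessel_metrics_per_layer,
)
from conftest import make_cylinder_mask


def cylinder_image(shape=(40, 40, 40), radius_vox=4.0, intensity=100.0, axis=0,
                   spacing=(1.0, 1.0, 1.0)) -> VoxelGrid:
    mask = make_cylinder_mask(shape, axis, radius_vox, spacing)
    return VoxelGrid(mask.values * intensity, spacing, channel="vessel")


def sphere_image(shape=(40, 40, 40), radius_vox=4.0, intensity=100.0) -> VoxelGrid:
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    r2 = sum((g - (n - 1) / 2.0) ** 2 for g, n in zip(grids, shape))
    return VoxelGrid((r2 <= radius_vox**2) * intensity, (1.0, 1.0, 1.0))


class TestFrangi:
    def test_constant_field_zero_response(self):
        g = VoxelGrid(np.full((20, 20, 20), 57.0), (1, 1, 1))
        v = frangi_vesselness(g, VesselnessParams(scales_um=(2.0,)))
        assert float(v.values.max()) == 0.0

    def test_tube_response_dominates_background(self):
        g = cylinder_image(radius_vox=4.0)
        v = frangi_vesselness(g, VesselnessParams(scales_um=(2.0, 4.0)))
        axis_mean = v.values[:, 19, 19].mean()
        bg_mean = v.values[:, :8, :8].mean()
        assert axis_mean > 10 * max(bg_mean, 1e-12)

    def test_sphere_suppressed_relative_to_tube(self):
        params = VesselnessParams(scales_um=(2.0, 4.0))
        tube = frangi_vesselness(cylinder_image(radius_vox=4.0), params)
        ball = frangi_vesselness(sphere_image(radius_vox=4.0), params)
        assert ball.values[19, 19, 19] < tube.values[19, 19, 19]
        assert ball.values.max() < tube.values.max()

    def test_contrast_monotonicity_with_fixed_c(self):
        params = VesselnessParams(scales_um=(2.0, 4.0), c=50.0)
        v1 = frangi_vesselness(cylinder_image(intensity=100.0), params)
        v2 = frangi_vesselness(cylinder_image(intensity=300.0), params)
        assert v2.values[20, 19, 19] >= v1.values[20, 19, 19]

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            frangi_vesselness(VoxelGrid(np.ones((1, 1, 1)), (1, 1, 1)))


class TestSegmentVessels:
    def test_zero_vesselness_gives_empty_mask(self):
        v = VoxelGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        assert segment_vessels(v, 0.5).count() == 0

    def test_threshold_out_of_range_rejected(self):
        v = VoxelGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(ValueError):
            segment_vessels(v, 1.5)

    def test_tube_volume_within_25pct_of_analytic(self):
        # scales matched to the tube radius (sigma ~ r/sqrt(2)) and a mid
        # threshold: the multi-scale response has a soft halo outside the
        # wall, so a permissive threshold would systematically overcount
        g = cylinder_image(shape=(60, 40, 40), radius_vox=4.0)
        v = frangi_vesselness(g, VesselnessParams(scales_um=(2.0, 3.0)))
        mask = segment_vessels(v, 0.5)
        analytic = math.pi * 4.0**2 * 60
        assert mask.count() == pytest.approx(analytic, rel=0.25)

    def test_small_component_filter(self):
        v = np.zeros((30, 20, 20))
        v[5:25, 9:12, 9:12] = 0.9  # big tube-ish blob
        v[2:3, 2:3, 2:3] = 0.9  # single spurious voxel
        vg = VoxelGrid(v, (10.0, 10.0, 10.0))
        from scipy import ndimage

        mask = segment_vessels(vg, 0.5, min_component_mm3=5e-6)
        _, n = ndimage.label(mask.values)
        assert n == 1


class TestSkeleton:
    def test_straight_tube_single_path_length_and_radius(self):
        sp = (2.68, 2.68, 2.68)
        mask = make_cylinder_mask((100, 21, 21), axis=0, radius_vox=4.0, spacing=sp)
        skel = skeletonize_vessels(mask)
        endpoints = skel.endpoints()
        assert len(endpoints) == 2
        assert len(skel.branch_points()) == 0
        total = skel.total_length_um()
        assert abs(total - 99 * 2.68) <= 2 * 2.68
        radii = [skel.graph.nodes[n]["radius_um"] for n in skel.graph.nodes]
        median_r_vox = np.median(radii) / 2.68
        assert abs(median_r_vox - 4.0) <= 0.5

    def test_single_voxel_mask(self):
        m = BinaryMask(np.zeros((5, 5, 5), bool), (1, 1, 1))
        m.values[2, 2, 2] = True
        skel = skeletonize_vessels(m)
        assert skel.n_nodes == 1
        assert skel.n_edges == 0

    def test_empty_mask_empty_graph(self):
        skel = skeletonize_vessels(BinaryMask(np.zeros((5, 5, 5), bool), (1, 1, 1)))
        assert skel.n_nodes == 0

    def test_y_shape_has_one_branch_three_endpoints(self):
        vals = np.zeros((40, 40, 40), bool)
        vals[5:25, 20, 20] = True  # stem
        for t in range(14):
            vals[24 + t, 20 + t, 20] = True  # arm 1
            vals[24 + t, 20 - t, 20] = True  # arm 2
        skel = skeletonize_vessels(BinaryMask(vals, (1, 1, 1)))
        assert len(skel.branch_points()) == 1
        assert len(skel.endpoints()) == 3

    @pytest.mark.parametrize("radius", [2, 4, 8])
    def test_radius_recovery_interior(self, radius):
        mask = make_cylinder_mask((60, 41, 41), axis=0, radius_vox=radius, spacing=(1.0, 1.0, 1.0))
        skel = skeletonize_vessels(mask)
        interior = [
            skel.graph.nodes[n]["radius_um"]
            for n in skel.graph.nodes
            if 2 <= n[0] <= 57
        ]
        assert abs(np.median(interior) - radius) <= 0.5

    def test_rotation_robustness(self):
        sp = (1.0, 1.0, 1.0)
        a = make_cylinder_mask((80, 31, 31), axis=0, radius_vox=3.0, spacing=sp)
        b = BinaryMask(np.transpose(a.values, (2, 1, 0)), sp)  # 90 deg rotation
        la = skeletonize_vessels(a).total_length_um()
        lb = skeletonize_vessels(b).total_length_um()
        assert lb == pytest.approx(la, rel=0.01)


class TestPerLayerMetrics:
    def _layers_full_block(self, shape, sp, thickness, n):
        seed = BinaryMask(np.zeros(shape, bool), sp)
        seed.values[:, :, 0] = True
        tissue = BinaryMask(np.ones(shape, bool), sp)
        lesion = BinaryMask(np.zeros(shape, bool), sp)
        return build_layers(seed, tissue, lesion, LayerSpec(thickness, n, "edt"))

    def test_empty_skeleton_all_zero(self):
        sp = (5.0, 5.0, 5.0)
        layers = self._layers_full_block((10, 10, 10), sp, 25.0, 2)
        skel = skeletonize_vessels(BinaryMask(np.zeros((10, 10, 10), bool), sp))
        metrics = vessel_metrics_per_layer(skel, layers)
        assert all(m.length_density_mm_per_mm3 == 0.0 for m in metrics)
        assert all(m.volume_fraction == 0.0 for m in metrics)

    def test_single_cylinder_analytic_density(self):
        # tube along z in a single 1-layer block of known volume
        sp = (5.0, 5.0, 5.0)
        shape = (40, 21, 21)
        mask = make_cylinder_mask(shape, axis=0, radius_vox=3.0, spacing=sp)
        skel = skeletonize_vessels(mask)
        layers = self._layers_full_block(shape, sp, 1000.0, 1)
        m = vessel_metrics_per_layer(skel, layers)[0]
        V = layers.tissue_volumes_mm3[0]
        L_mm = 39 * 5.0 / 1000.0
        r_um = 3.0 * 5.0
        assert m.length_density_mm_per_mm3 == pytest.approx(L_mm / V, rel=0.10)
        assert m.volume_fraction == pytest.approx(math.pi * r_um**2 * (L_mm * 1000) / 1e9 / V, rel=0.15)

    def test_partition_conserves_totals(self):
        sp = (5.0, 5.0, 5.0)
        shape = (60, 31, 31)
        mask = make_cylinder_mask(shape, axis=0, radius_vox=3.0, spacing=sp)
        skel = skeletonize_vessels(mask)
        layers = self._layers_full_block(shape, sp, 40.0, 10)
        metrics = vessel_metrics_per_layer(skel, layers)
        total_len, total_vol = skeleton_totals(skel)
        assert sum(m.length_mm for m in metrics) == pytest.approx(total_len, rel=1e-6)
        assert sum(m.volume_mm3 for m in metrics) == pytest.approx(total_vol, rel=1e-6)

    def test_zero_tissue_layer_reports_nan_with_warning(self):
        sp = (5.0, 5.0, 5.0)
        shape = (20, 11, 11)
        mask = make_cylinder_mask(shape, axis=0, radius_vox=2.0, spacing=sp)
        skel = skeletonize_vessels(mask)
        layers = self._layers_full_block(shape, sp, 1000.0, 1)
        layers.tissue_volumes_mm3[0] = 0.0
        with pytest.warns(UserWarning):
            m = vessel_metrics_per_layer(skel, layers)[0]
        assert math.isnan(m.length_density_mm_per_mm3)
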