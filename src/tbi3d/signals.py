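"""Hypoxia / extravasation quantification against contralateral background.

Exogenous fluorophores (hypoxia dye, 70-kDa dextran) sit on top of tissue
autofluorescence.  Because the contralateral hemisphere is distal to the
injury, its intensity distribution defines a per-brain background: the
threshold is its 99.9th percentile, and the metric per depth layer is the
supra-threshold volume divided by the layer's tissue volume (mm³/mm³).
Thresholds are per brain and per channel, never shared across brains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask, VoxelGrid, UM3_PER_MM3
from .layers import DepthLayerSet
from .lesion import remove_small_components

__all__ = [
    "ThresholdRule",
    "SignalLayerMetrics",
    "background_threshold",
    "segment_signal",
    "signal_fraction_per_layer",
]


@dataclass
class ThresholdRule:
    """Background percentile rule: linear-interpolation quantile of the
    intensities under the contralateral reference mask."""

    percentile: float = 99.9
    reference: BinaryMask = None

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ValueError("percentile must be in (0, 100)")
        if self.reference is None or not self.reference.values.any():
            raise ValueError("reference mask must be nonempty")


@dataclass
class SignalLayerMetrics:
    interval_um: tuple[float, float]
    signal_fraction: float
    signal_volume_mm3: float
    tissue_volume_mm3: float


def background_threshold(grid: VoxelGrid, rule: ThresholdRule) -> float:
    """Linear-interpolation quantile of intensities under the reference mask.

    Downstream comparison is strictly greater-than, so a constant background
    yields zero supra-threshold signal.
    """
    vals = np.asarray(grid.values)[rule.reference.values]
    if vals.size == 0:
        raise ValueError("reference mask selects no voxels")
    return float(np.quantile(vals.astype(np.float64), rule.percentile / 100.0, method="linear"))


def segment_signal(
    grid: VoxelGrid,
    threshold: float,
    tissue: BinaryMask,
    min_component_mm3: float = 1e-4,
) -> BinaryMask:
    """Supra-threshold tissue voxels, small components removed (denoising)."""
    mask = (np.asarray(grid.values) > threshold) & tissue.values
    mask = remove_small_components(mask, grid.spacing, min_component_mm3)
    return BinaryMask(mask, grid.spacing, channel=f"{grid.channel}_signal", origin=grid.origin)


def signal_fraction_per_layer(signal: BinaryMask, layers: DepthLayerSet) -> list[SignalLayerMetrics]:
    """Per layer: supra-threshold volume / layer tissue volume."""
    voxel_mm3 = float(np.prod(signal.spacing)) / UM3_PER_MM3
    out = []
    for k, layer in enumerate(layers.layers):
        vol = float(np.count_nonzero(signal.values & layer.values)) * voxel_mm3
        tv = layers.tissue_volumes_mm3[k]
        if tv <= 0:
            if vol > 0:
                warnings.warn(f"layer {k} has signal but zero tissue volume", stacklevel=2)
            frac = math.nan if vol > 0 else 0.0
        else:
            frac = vol / tv
        out.append(SignalLayerMetrics(layers.intervals_um[k], frac, vol, tv))
    return out
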