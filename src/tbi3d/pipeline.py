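"""Per-brain and cohort orchestration.

One brain runs: tissue segmentation → surface solidification → midsagittal
split → mirror-subtract lesion → lesion boundary → conformal depth layers →
vessel metrics (Frangi → mask → skeleton) and signal fractions (contralateral
99.9th-percentile threshold) per layer.  Each analysis runs at its own
resolution (coarse for the lesion, medium for the biomarker signals, fine
for the vessels), mirroring how whole-brain light-sheet volumes are handled
in practice; all three downsample factors are configurable so desk-scale
phantoms can run at factor 1.

A cohort run aggregates per-brain, per-layer metric rows, removes 1.5×IQR
outliers within each group, and tests each metric in each layer with one-way
ANOVA plus Fisher's LSD.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import __version__
from .grids import BinaryMask, VoxelGrid, downsample_grid, load_grid, mask_volume_mm3, save_mask
from .layers import DepthLayerSet, LayerSpec, build_layers
from .lesion import (
    LesionModel,
    build_lesion_model,
    lesion_boundary,
)
from .signals import ThresholdRule, background_threshold, segment_signal, signal_fraction_per_layer
from .stats import fisher_lsd, oneway_anova, remove_outliers_iqr
from .vessels import (
    VesselnessParams,
    frangi_vesselness,
    segment_vessels,
    skeletonize_vessels,
    vessel_metrics_per_layer,
)

__all__ = ["PipelineConfig", "BrainInput", "BrainResult", "run_brain", "analyze_brain", "run_cohort", "cohort_stats"]


@dataclass
class BrainInput:
    brain_id: str
    vessel_path: str
    extravasation_path: str
    hypoxia_path: str
    group: str = ""
    spacing_um: Optional[tuple[float, float, float]] = None


@dataclass
class PipelineConfig:
    """Everything needed to process a cohort reproducibly."""

    brains: list[BrainInput] = field(default_factory=list)
    lesion_factor: int = 32
    signal_factor: int = 4
    vessel_factor: int = 2
    tissue_threshold: float | str = "auto"
    closing_radius_um: float = 300.0
    ipsilateral_side: int = +1
    lr_axis: int = 2
    registration_search_voxels: int = 10
    lesion_min_component_mm3: float = 1e-3
    layer_thickness_um: float = 100.0
    n_layers: int = 10
    layer_method: str = "edt"
    vessel_scales_um: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0)
    vessel_threshold: float = 0.2
    vessel_min_component_mm3: float = 0.0
    signal_percentile: float = 99.9
    signal_min_component_mm3: float = 1e-4
    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.lesion_factor, self.signal_factor, self.vessel_factor) < 1:
            raise ValueError("downsample factors must be >= 1")
        for b in self.brains:
            for p in (b.vessel_path, b.extravasation_path, b.hypoxia_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"brain {b.brain_id}: missing input {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        brains = [BrainInput(**b) for b in raw.pop("brains", [])]
        cfg = cls(brains=brains, **raw)
        if isinstance(cfg.vessel_scales_um, list):
            cfg.vessel_scales_um = tuple(cfg.vessel_scales_um)
        cfg.validate()
        return cfg


@dataclass
class BrainResult:
    brain_id: str
    metrics: pd.DataFrame  # tidy: brain_id, metric, layer, layer_min_um, layer_max_um, value
    lesion: LesionModel
    layers: DepthLayerSet
    thresholds: dict[str, float]
    manifest: dict


def _resample_mask(mask: BinaryMask, like: VoxelGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a mask onto another grid's raster."""
    if mask.shape == like.shape:
        return BinaryMask(mask.values, like.spacing, mask.channel, like.origin)
    zoom = [t / s for t, s in zip(like.shape, mask.shape)]
    out = ndimage.zoom(mask.values.astype(np.uint8), zoom, order=0, grid_mode=True, mode="nearest")
    # guard against off-by-one rounding in the zoomed shape
    fixed = np.zeros(like.shape, dtype=bool)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(like.shape, out.shape))
    fixed[sl] = out[sl] > 0
    return BinaryMask(fixed, like.spacing, mask.channel, like.origin)


def _contralateral_reference(solid: BinaryMask, lesion: BinaryMask, plane_pos: float,
                             lr_axis: int, ipsilateral_side: int) -> BinaryMask:
    idx = np.arange(solid.shape[lr_axis]).reshape([-1 if a == lr_axis else 1 for a in range(3)])
    contra = idx < plane_pos if ipsilateral_side > 0 else idx > plane_pos
    ref = solid.values & ~lesion.values & np.broadcast_to(contra, solid.shape)
    return solid.like(ref, channel="contralateral_reference")


def analyze_brain(
    vessel: VoxelGrid,
    extravasation: VoxelGrid,
    hypoxia: VoxelGrid,
    config: Optional[PipelineConfig] = None,
    brain_id: str = "brain",
) -> BrainResult:
    """Run the full single-brain workflow on in-memory channels."""
    cfg = config or PipelineConfig()

    # --- lesion geometry at coarse resolution -----------------------------
    lesion_grid = downsample_grid(extravasation, cfg.lesion_factor)
    model = build_lesion_model(
        lesion_grid,
        threshold=cfg.tissue_threshold,
        closing_radius_um=cfg.closing_radius_um,
        ipsilateral_side=cfg.ipsilateral_side,
        lr_axis=cfg.lr_axis,
        search_radius=cfg.registration_search_voxels,
        min_component_mm3=cfg.lesion_min_component_mm3,
    )

    layer_spec = LayerSpec(cfg.layer_thickness_um, cfg.n_layers, cfg.layer_method)

    def layered(level_grid: VoxelGrid) -> tuple[DepthLayerSet, BinaryMask, BinaryMask]:
        solid = _resample_mask(model.solid_mask, level_grid)
        lesion = _resample_mask(model.lesion_mask, level_grid)
        boundary = lesion_boundary(lesion, solid)
        layers = build_layers(boundary, solid, lesion, layer_spec)
        return layers, solid, lesion

    rows: list[dict] = []
    thresholds: dict[str, float] = {}

    # --- signal channels at medium resolution ------------------------------
    sig_any = downsample_grid(extravasation, cfg.signal_factor)
    sig_layers, sig_solid, sig_lesion = layered(sig_any)
    # fractional plane index rescaled to this resolution (voxel-centre aligned)
    ratio = sig_solid.shape[cfg.lr_axis] / model.solid_mask.shape[cfg.lr_axis]
    plane_pos = (model.plane.plane_position + 0.5) * ratio - 0.5
    reference = _contralateral_reference(sig_solid, sig_lesion, plane_pos, cfg.lr_axis, cfg.ipsilateral_side)
    tissue_no_lesion = sig_solid.like(sig_solid.values & ~sig_lesion.values, channel="tissue")
    for channel_grid, name in ((hypoxia, "hypoxia"), (extravasation, "extravasation")):
        g = downsample_grid(channel_grid, cfg.signal_factor)
        thr = background_threshold(g, ThresholdRule(cfg.signal_percentile, reference))
        thresholds[name] = thr
        sig = segment_signal(g, thr, tissue_no_lesion, cfg.signal_min_component_mm3)
        for m in signal_fraction_per_layer(sig, sig_layers):
            rows.append(dict(brain_id=brain_id, metric=f"{name}_fraction",
                             layer_min_um=m.interval_um[0], layer_max_um=m.interval_um[1],
                             value=m.signal_fraction))

    # --- vessels at fine resolution ----------------------------------------
    ves_grid = downsample_grid(vessel, cfg.vessel_factor)
    ves_layers, ves_solid, ves_lesion = layered(ves_grid)
    vness = frangi_vesselness(ves_grid, VesselnessParams(scales_um=cfg.vessel_scales_um))
    vmask = segment_vessels(vness, cfg.vessel_threshold, cfg.vessel_min_component_mm3)
    vmask = vmask.like(vmask.values & ves_solid.values & ~ves_lesion.values)
    skel = skeletonize_vessels(vmask)
    for m in vessel_metrics_per_layer(skel, ves_layers):
        rows.append(dict(brain_id=brain_id, metric="vessel_length_density",
                         layer_min_um=m.interval_um[0], layer_max_um=m.interval_um[1],
                         value=m.length_density_mm_per_mm3))
        rows.append(dict(brain_id=brain_id, metric="vessel_volume_fraction",
                         layer_min_um=m.interval_um[0], layer_max_um=m.interval_um[1],
                         value=m.volume_fraction))
    for k, tv in enumerate(sig_layers.tissue_volumes_mm3):
        rows.append(dict(brain_id=brain_id, metric="tissue_volume_mm3",
                         layer_min_um=sig_layers.intervals_um[k][0],
                         layer_max_um=sig_layers.intervals_um[k][1], value=tv))
    rows.append(dict(brain_id=brain_id, metric="lesion_volume_mm3",
                     layer_min_um=np.nan, layer_max_um=np.nan, value=model.lesion_volume_mm3))

    metrics = pd.DataFrame(rows)
    manifest = {
        "brain_id": brain_id,
        "tbi3d_version": __version__,
        "python": platform.python_version(),
        "parameters": {k: v for k, v in asdict(cfg).items() if k != "brains"},
        "thresholds": thresholds,
        "lesion_volume_mm3": model.lesion_volume_mm3,
        "midsagittal_plane": {"axis": model.plane.axis, "position": model.plane.plane_position},
    }
    return BrainResult(brain_id, metrics, model, sig_layers, thresholds, manifest)


def run_brain(config: PipelineConfig, brain: BrainInput) -> BrainResult:
    """File-based single-brain run; writes metrics CSV, lesion report and
    manifest under ``config.out_dir`` when set."""
    grids = {}
    for name, path in (("vessel", brain.vessel_path),
                       ("extravasation", brain.extravasation_path),
                       ("hypoxia", brain.hypoxia_path)):
        grids[name] = load_grid(path, spacing_override=brain.spacing_um, channel=name)
    result = analyze_brain(grids["vessel"], grids["extravasation"], grids["hypoxia"],
                           config, brain_id=brain.brain_id)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.metrics.to_csv(out / f"{brain.brain_id}_metrics.csv", index=False)
        (out / f"{brain.brain_id}_manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
        save_mask(result.lesion.lesion_mask, out / f"{brain.brain_id}_lesion.h5")
    return result


def run_cohort(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every brain, then test group differences per metric per layer.

    Returns ``(metrics, stats)``.  A brain whose processing fails is recorded
    and skipped; remaining brains proceed.
    """
    all_metrics = []
    failures = []
    for brain in config.brains:
        try:
            res = run_brain(config, brain)
        except Exception as exc:  # keep the cohort going
            failures.append({"brain_id": brain.brain_id, "error": repr(exc)})
            warnings.warn(f"brain {brain.brain_id} failed: {exc!r}", stacklevel=2)
            continue
        m = res.metrics.copy()
        m["group"] = brain.group
        all_metrics.append(m)
    if not all_metrics:
        raise RuntimeError(f"no brain processed successfully: {failures}")
    metrics = pd.concat(all_metrics, ignore_index=True)
    stats = cohort_stats(metrics)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "cohort_metrics.csv", index=False)
        stats.to_csv(out / "cohort_stats.csv", index=False)
        if failures:
            (out / "failures.json").write_text(json.dumps(failures, indent=2))
    return metrics, stats


#: bookkeeping quantities never hypothesis-tested by default: the per-layer
#: tissue volume is the normalizing denominator, and the whole-brain lesion
#: volume has no layer structure; both are nearly deterministic given the
#: geometry, so quantization differences would masquerade as significance
BOOKKEEPING_METRICS = frozenset({"tissue_volume_mm3", "lesion_volume_mm3"})


def cohort_stats(metrics: pd.DataFrame, group_col: str = "group",
                 test_metrics: Optional[list[str]] = None) -> pd.DataFrame:
    """Per metric per layer: IQR outlier removal per group, ANOVA + LSD.

    ``test_metrics`` selects the metrics to test (default: every metric
    present except the bookkeeping volumes).  Groups with fewer than two
    brains are excluded with a warning; a layer with fewer than two usable
    groups is skipped.
    """
    groups_present = metrics[group_col].dropna().unique()
    if len(groups_present) < 2:
        raise ValueError("cohort statistics need at least two groups")
    if test_metrics is None:
        selected = metrics[~metrics["metric"].isin(BOOKKEEPING_METRICS)]
    else:
        selected = metrics[metrics["metric"].isin(test_metrics)]
    rows = []
    for (metric, lo, hi), sub in selected.dropna(subset=["value"]).groupby(
        ["metric", "layer_min_um", "layer_max_um"], dropna=False
    ):
        groups = {}
        for g, gsub in sub.groupby(group_col):
            vals = remove_outliers_iqr(gsub["value"].tolist())
            if len(vals) < 2:
                warnings.warn(f"group {g} excluded for {metric} [{lo},{hi}): <2 observations", stacklevel=2)
                continue
            groups[g] = vals
        if len(groups) < 2:
            continue
        try:
            report = oneway_anova(groups)
        except ValueError:
            continue
        lsd = fisher_lsd(groups, report)
        for (gi, gj), (diff, p) in lsd.items():
            rows.append(dict(metric=metric, layer_min_um=lo, layer_max_um=hi,
                             F=report.F, anova_p=report.p,
                             df_between=report.df_between, df_within=report.df_within,
                             group_a=gi, group_b=gj, mean_diff=diff, lsd_p=p))
    return pd.DataFrame(rows)
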