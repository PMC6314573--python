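"""End-to-end pipeline: raw stack → segmented network → metrics.

Stages: 2D vesselness filtering → hysteresis segmentation → lacuna
segmentation (on the raw image) → optional lacuna masking → small-object
removal → 3D skeletonization → skeleton graph → network metrics →
orientation descriptor. Every stage parameter lives in one structured
config (YAML round-trip), a fixed seed makes runs reproducible, and a run
manifest records the resolved configuration and stage timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import VoxelGrid, Spacing, DEFAULT_SPACING, read_stack, write_stack
from .vesselness import VesselnessParams, HysteresisParams, frangi_stack, hysteresis_threshold
from .lacunae import LacunaParams, segment_lacunae, lacuna_density, apply_lacuna_mask
from .skeleton import (NetworkMetrics, build_skeleton_graph, network_metrics,
                       skeletonize_3d, SkeletonGraph)
from .orientation import MorphologyThresholds, orientation_descriptor, AngularSpectrum


@dataclass
class SkeletonParams:
    diameter_um: float = 0.2            # assumed canaliculus diameter for Ca.V/TV
    min_component_voxels: int = 8       # drop isolated specks (<= this size) before thinning
    min_branch_um: float = 0.8          # prune terminal twigs below the lateral resolution scale
    junction_merge_radius_um: float = 1.5  # cluster junctions below the axial resolution
    apply_lacuna_mask: bool = True

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")


@dataclass
class OrientationParams:
    n_bins: int = 36
    radial_band: tuple[float, float] = (0.1, 0.8)
    mode: str = "slice_mean"
    thresholds: MorphologyThresholds = field(default_factory=MorphologyThresholds)


@dataclass
class PipelineConfig:
    spacing_um: Spacing = DEFAULT_SPACING
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    hysteresis: HysteresisParams = field(default_factory=HysteresisParams)
    lacunae: LacunaParams = field(default_factory=LacunaParams)
    skeleton: SkeletonParams = field(default_factory=SkeletonParams)
    orientation: OrientationParams = field(default_factory=OrientationParams)
    seed: int = 0
    save_intermediates: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in raw.items():
            if key == "spacing_um":
                kwargs[key] = tuple(value)
            elif key == "vesselness":
                kwargs[key] = VesselnessParams(**value)
            elif key == "hysteresis":
                kwargs[key] = HysteresisParams(**value)
            elif key == "lacunae":
                kwargs[key] = LacunaParams(**value)
            elif key == "skeleton":
                kwargs[key] = SkeletonParams(**value)
            elif key == "orientation":
                value = dict(value)
                if "radial_band" in value:
                    value["radial_band"] = tuple(value["radial_band"])
                if "thresholds" in value:
                    value["thresholds"] = MorphologyThresholds(**value["thresholds"])
                kwargs[key] = OrientationParams(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    metrics: NetworkMetrics                  # with lacuna masking (if enabled)
    metrics_unmasked: NetworkMetrics
    graph: SkeletonGraph
    spectrum: AngularSpectrum
    lacuna_count: int
    nlc_tv_mm3: float
    manifest: dict

    def metrics_row(self) -> dict:
        row = self.metrics.to_row()
        row["orientation_label"] = self.spectrum.label
        row["anisotropy_index"] = self.spectrum.anisotropy
        return row


def _remove_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels < 1:
        return mask
    from skimage import morphology

    return morphology.remove_small_objects(mask, max_size=min_voxels)


def run_pipeline(source, config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline on a stack (path or :class:`VoxelGrid`).

    Returns metrics for the lacuna-masked network (the default analysis
    variant) alongside the unmasked variant; when ``outdir`` is given, all
    intermediate grids, CSV tables and a JSON run manifest are written.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)

        return _T()

    if isinstance(source, VoxelGrid):
        grid = source
        source_name = "<in-memory>"
    else:
        grid = read_stack(source, spacing=config.spacing_um)
        source_name = str(source)

    with stage("vesselness"):
        response = frangi_stack(grid, config.vesselness)
    with stage("hysteresis"):
        segmented = hysteresis_threshold(response, config.hysteresis)
    with stage("lacunae"):
        lacuna_mask, lacuna_set = segment_lacunae(grid, config.lacunae)
        nlc = lacuna_density(lacuna_set)

    variants: dict[str, VoxelGrid] = {"unmasked": segmented}
    if config.skeleton.apply_lacuna_mask:
        variants["masked"] = apply_lacuna_mask(segmented, lacuna_mask)

    tv = grid.volume_um3
    results: dict[str, tuple[NetworkMetrics, SkeletonGraph, VoxelGrid]] = {}
    with stage("skeleton"):
        for name, seg in variants.items():
            cleaned = seg.like(_remove_small(seg.values.astype(bool),
                                             config.skeleton.min_component_voxels))
            skel = skeletonize_3d(cleaned)
            graph = build_skeleton_graph(
                skel, min_branch_um=config.skeleton.min_branch_um,
                junction_merge_radius_um=config.skeleton.junction_merge_radius_um)
            m = network_metrics(graph, tv, diameter_um=config.skeleton.diameter_um,
                                n_lacunae=lacuna_set.count,
                                grid_voxel_count=grid.values.size)
            results[name] = (m, graph, skel)

    with stage("orientation"):
        spectrum = orientation_descriptor(
            response, n_bins=config.orientation.n_bins,
            radial_band=config.orientation.radial_band,
            mode=config.orientation.mode,
            thresholds=config.orientation.thresholds,
        )

    primary = "masked" if config.skeleton.apply_lacuna_mask else "unmasked"
    metrics, graph, skel = results[primary]
    metrics_unmasked = results["unmasked"][0]

    manifest = {
        "source": source_name,
        "config": asdict(config),
        "seed": config.seed,
        "timings_s": timings,
        "shape": list(grid.shape),
        "tv_um3": tv,
        "lacuna_count": lacuna_set.count,
    }
    result = PipelineResult(metrics, metrics_unmasked, graph, spectrum,
                            lacuna_set.count, nlc, manifest)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if config.save_intermediates:
            write_stack(outdir / "vesselness.tif", response, dtype=np.float32)
            write_stack(outdir / "segmented.tif", variants[primary])
            write_stack(outdir / "lacuna_mask.tif", lacuna_mask)
            write_stack(outdir / "skeleton.tif", skel)
        lacuna_set.to_frame().to_csv(outdir / "lacunae.csv", index=False)
        spectrum.to_frame().to_csv(outdir / "angular_spectrum.csv", index=False)
        rows = []
        for name, (m, _, _) in results.items():
            row = {"variant": name, **m.to_row()}
            row["orientation_label"] = spectrum.label
            row["anisotropy_index"] = spectrum.anisotropy
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False)
        _write_graph(outdir, graph)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return result


def _write_graph(outdir: Path, graph: SkeletonGraph) -> None:
    nodes = pd.DataFrame(
        [
            {"id": n.id, "kind": n.kind,
             "z_um": n.position_um[0], "y_um": n.position_um[1], "x_um": n.position_um[2]}
            for n in graph.nodes
        ],
        columns=["id", "kind", "z_um", "y_um", "x_um"],
    )
    branches = pd.DataFrame(
        [
            {"id": b.id, "node_a": b.node_ids[0], "node_b": b.node_ids[1],
             "length_um": b.length_um, "n_voxels": len(b.path)}
            for b in graph.branches
        ],
        columns=["id", "node_a", "node_b", "length_um", "n_voxels"],
    )
    nodes.to_csv(outdir / "skeleton_nodes.csv", index=False)
    branches.to_csv(outdir / "skeleton_branches.csv", index=False)
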