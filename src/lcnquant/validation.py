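"""Ground-truth validation of the pipeline on synthetic phantoms.

A phantom provides three kinds of reference: the analytic ground truth
(total centerline length, hence Ca.V/TV, and the generated lacuna count),
the clean voxelized network (the optical support mask with lacunae
removed, skeletonized noise-free — the reference for connectivity, since
canaliculi that physically touch are genuinely connected in the porosity
network), and the generative junction list. The pipeline runs on the
rendered noisy image and is scored against these references.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import phantom as ph
from .grid import VoxelGrid, read_stack
from .lacunae import apply_lacuna_mask
from .pipeline import PipelineConfig, run_pipeline
from .skeleton import build_skeleton_graph, network_metrics, skeletonize_3d
from .stats import compare_skeletons, relative_error


def reference_metrics(gt: ph.GroundTruth, lacuna: VoxelGrid,
                      diameter_um: float = 0.2,
                      min_branch_um: float = 0.8,
                      junction_merge_radius_um: float = 1.5):
    """Reference network metrics from the clean rasterized phantom.

    The clean optical support mask (lacunae excluded) is skeletonized and
    measured with the same graph machinery — including the same cleanup
    conventions — as the pipeline output, but the total length is taken
    from the analytic ground truth: connectivity is a property of the
    voxelized network, length of the generative one.
    """
    support = ph.canal_support_mask(gt)
    clean = apply_lacuna_mask(support, lacuna)
    graph = build_skeleton_graph(skeletonize_3d(clean),
                                 min_branch_um=min_branch_um,
                                 junction_merge_radius_um=junction_merge_radius_um)
    m = network_metrics(graph, support.volume_um3, diameter_um=diameter_um,
                        n_lacunae=len(gt.lacunae), grid_voxel_count=support.values.size)
    # override length-derived fields with the exact generative values
    m.total_length_um = gt.total_length_um
    m.cav_tv_pct = gt.realized_canal_fraction_pct
    return m, graph


def evaluate_phantom(params: ph.GenerationParams,
                     iparams: ph.ImagingParams | None = None,
                     config: PipelineConfig | None = None) -> dict:
    """Simulate one phantom, run the full pipeline, score the recovery.

    Returns truth and recovered values with signed relative errors (%) for
    Ca.V/TV, junction count and lacuna count.
    """
    image, _, lacuna, _, gt = ph.simulate(params, iparams)
    config = config or PipelineConfig(spacing_um=params.spacing_um, seed=params.seed)
    ref, _ = reference_metrics(gt, lacuna, config.skeleton.diameter_um,
                               config.skeleton.min_branch_um,
                               config.skeleton.junction_merge_radius_um)
    result = run_pipeline(image, config)
    rec = result.metrics
    return {
        "seed": params.seed,
        "target_cav_tv_pct": params.canal_fraction_pct,
        "truth_cav_tv_pct": ref.cav_tv_pct,
        "recovered_cav_tv_pct": rec.cav_tv_pct,
        "cav_tv_error_pct": relative_error(rec.cav_tv_pct, ref.cav_tv_pct),
        "truth_n_connections": ref.n_connections,
        "recovered_n_connections": rec.n_connections,
        "connections_error_pct": relative_error(rec.n_connections, ref.n_connections)
        if ref.n_connections else 0,
        "truth_n_lacunae": len(gt.lacunae),
        "recovered_n_lacunae": result.lacuna_count,
        "recovered_nlc_tv_mm3": result.nlc_tv_mm3,
        "truth_n_canaliculi": ref.n_canaliculi,
        "recovered_n_canaliculi": rec.n_canaliculi,
        "recovered_total_length_um": rec.total_length_um,
        "truth_total_length_um": ref.total_length_um,
    }


def phantom_error_report(phantom_dir: Path,
                         config: PipelineConfig | None = None) -> pd.DataFrame:
    """Uncertainty report for a phantom written by ``lcnquant simulate``.

    Mirrors the reference-skeleton comparison: pipeline metrics with and
    without the lacuna mask, each against the clean-phantom reference.
    """
    phantom_dir = Path(phantom_dir)
    gt = ph.load_truth(phantom_dir / "truth.json")
    spacing = gt.params.spacing_um
    image = read_stack(phantom_dir / "image.tif", spacing=spacing)
    lacuna = read_stack(phantom_dir / "lacuna_mask.tif", spacing=spacing)
    lacuna = lacuna.like(lacuna.values > 0)
    config = config or PipelineConfig(spacing_um=spacing, seed=gt.seed)
    ref, _ = reference_metrics(gt, lacuna, config.skeleton.diameter_um,
                               config.skeleton.min_branch_um,
                               config.skeleton.junction_merge_radius_um)
    result = run_pipeline(image, config)
    parts = [
        compare_skeletons(result.metrics_unmasked, ref, variant="vesselness"),
        compare_skeletons(result.metrics, ref, variant="vesselness+lacuna-mask"),
    ]
    return pd.concat(parts, ignore_index=True)
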