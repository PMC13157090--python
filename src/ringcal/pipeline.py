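"""End-to-end orchestration: scene cloud in, metric transform out.

This is the library-level composition the CLI wraps: optional cleaning,
red segmentation, ring-cluster selection, PCA plane frame, plane
projection, two-stage circle fit, and transform assembly. Each stage's
diagnostics are collected so a batch run can be audited offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    CircleFitResult,
    MetricTransform,
    PlaneFrame,
    apply_transform,
    build_metric_transform,
    fit_circle,
    pca_frame,
    project_to_plane,
)
from .cloud import ColoredPointCloud, remove_statistical_outliers, statistical_outlier_mask
from .config import PipelineConfig
from .detection import RingCandidate, segment_red, select_ring_cluster
from .phenotypes import PhenotypeReport, extract_report


@dataclass
class CalibrationResult:
    """Transform plus everything needed to audit how it was obtained.

    ``ring.indices`` and ``plant_index`` are expressed in the numbering
    of the *input* cloud, regardless of any internal cleaning.
    """

    transform: MetricTransform
    ring: RingCandidate
    frame: PlaneFrame
    circle: CircleFitResult
    plant_index: np.ndarray  # input-cloud indices of the non-ring remainder
    diagnostics: dict


def calibrate_scene(
    cloud: ColoredPointCloud, config: PipelineConfig | None = None
) -> CalibrationResult:
    """Detect the ring in a scene cloud and recover the metric transform.

    Statistical-outlier cleaning (when enabled) only feeds the ring
    detection and fit; it assumes roughly uniform sampling density, and
    a scene mixes densities (marker sheet vs foliage), so the non-ring
    remainder is reported uncleaned and cleaned separately downstream.

    The "plant" used for the normal-sign disambiguation is the non-ring
    remainder of the scene (everything that grows above the ring plane).
    """
    cfg = config or PipelineConfig()
    work = cloud
    kept = np.arange(cloud.n)
    if cfg.clean and work.n > cfg.clean_k:
        kept = np.flatnonzero(statistical_outlier_mask(cloud, cfg.clean_k, cfg.clean_sigma))
        work = cloud.select(kept)

    red = segment_red(work, cfg.thresholds())
    ring = select_ring_cluster(
        work, red, eps=cfg.eps, min_cluster=cfg.min_cluster,
        planarity_max=cfg.planarity_max, annularity_max=cfg.annularity_max,
    )

    ring_cloud = work.select(ring.indices)
    ring.indices = kept[ring.indices]  # back to input-cloud numbering
    plant_mask = np.ones(cloud.n, dtype=bool)
    plant_mask[ring.indices] = False
    plant_index = np.flatnonzero(plant_mask)
    plant_cloud = cloud.select(plant_index)

    frame = pca_frame(ring_cloud.points)
    pts2d = project_to_plane(ring_cloud.points, frame)
    circle = fit_circle(
        pts2d, n_iter=cfg.n_iter, inlier_tol=cfg.inlier_tol,
        min_inlier_frac=cfg.min_inlier_frac, seed=cfg.seed,
    )
    transform = build_metric_transform(
        frame, circle, plant_cloud, d_true=cfg.d_true, center_origin=cfg.center_origin
    )
    diagnostics = {
        "n_input": cloud.n,
        "n_after_cleaning": work.n,
        "n_red": int(len(red)),
        "ring_n_points": ring.n_points,
        "ring_planarity": ring.planarity,
        "ring_annularity": ring.annularity,
        "inlier_frac": float(circle.inlier_mask.mean()),
        "d_fitted": circle.d_fitted,
        "rms_residual": circle.rms_residual,
        "scale": transform.s,
        "config": cfg.to_dict(),
    }
    return CalibrationResult(transform, ring, frame, circle, plant_index, diagnostics)


def run_scene(
    cloud: ColoredPointCloud, config: PipelineConfig | None = None
) -> tuple[CalibrationResult, ColoredPointCloud, PhenotypeReport]:
    """Calibrate, transform the plant remainder to mm, extract traits.

    The remainder is cleaned against its own density statistics (not
    the scene's, which the dense marker sheet dominates).
    """
    cfg = config or PipelineConfig()
    cal = calibrate_scene(cloud, cfg)
    plant = cloud.select(cal.plant_index)
    if cfg.clean and plant.n > cfg.clean_k:
        plant = remove_statistical_outliers(plant, cfg.clean_k, cfg.clean_sigma)
    metric = apply_transform(plant, cal.transform)
    report = extract_report(metric, cfg.trait_params())
    return cal, metric, report
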