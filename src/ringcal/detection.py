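"""Locate the red-ring fiducial inside a colored scene cloud.

Detection is purely 3D: points are classified as "red" by HSV
thresholding of their per-point colors (red needs two hue intervals
because it wraps the hue circle), the red subset is partitioned by
single-linkage Euclidean clustering, and each cluster is scored by two
scale-free shape statistics:

* **planarity** — ratio of the smallest to largest PCA eigenvalue of the
  cluster; near 0 for anything flat, ~1 for spheres and cubes.
* **annularity** — coefficient of variation of in-plane radial distances
  about the cluster's algebraic circle-fit center; near 0 for a thin
  ring (at any arc occlusion), ~0.5 for a filled disk.

The largest cluster passing both thresholds is the ring. Measuring
annularity about the fitted circle center, not the cluster centroid,
is what keeps the statistic occlusion-invariant: the centroid of a half
arc sits far off the circle center, and radial spread about it would
reject exactly the occluded rings the fiducial is designed to survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import rgb_to_hsv as _mpl_rgb_to_hsv
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud
from .errors import NoRingFoundError, ParameterError


@dataclass
class ColorThresholds:
    """HSV gate for "red" points. Hue in degrees [0, 360); red wraps zero."""

    hue_low_1: float = 0.0
    hue_high_1: float = 20.0
    hue_low_2: float = 340.0
    hue_high_2: float = 360.0
    sat_min: float = 0.4
    val_min: float = 0.2

    def __post_init__(self):
        for lo, hi in ((self.hue_low_1, self.hue_high_1), (self.hue_low_2, self.hue_high_2)):
            if not (0 <= lo < hi <= 360):
                raise ParameterError(f"degenerate hue interval [{lo}, {hi})")
        if not (0 <= self.sat_min <= 1 and 0 <= self.val_min <= 1):
            raise ParameterError("sat_min and val_min must lie in [0, 1]")


@dataclass
class RingCandidate:
    """A red cluster with its shape scores (indices refer to the scene cloud)."""

    indices: np.ndarray
    planarity: float
    annularity: float
    n_points: int


def rgb_to_hsv(colors: np.ndarray) -> np.ndarray:
    """Vectorized RGB→HSV; hue in degrees [0, 360), sat/val in [0, 1].

    Gray points (undefined hue) get hue 0 with saturation 0.
    """
    colors = np.asarray(colors, dtype=np.float64)
    if colors.size and (colors.min() < 0 or colors.max() > 1):
        raise ParameterError("colors must lie in [0, 1]")
    hsv = _mpl_rgb_to_hsv(colors.reshape(-1, 3))
    hsv[:, 0] = (hsv[:, 0] * 360.0) % 360.0
    return hsv


def segment_red(cloud: ColoredPointCloud, thr: ColorThresholds | None = None) -> np.ndarray:
    """Indices of points whose color falls in the red HSV gate."""
    thr = thr or ColorThresholds()
    hsv = rgb_to_hsv(cloud.colors)
    h, s, v = hsv[:, 0], hsv[:, 1], hsv[:, 2]
    in_hue = ((h >= thr.hue_low_1) & (h < thr.hue_high_1)) | (
        (h >= thr.hue_low_2) & (h < thr.hue_high_2)
    )
    return np.flatnonzero(in_hue & (s >= thr.sat_min) & (v >= thr.val_min))


def _cluster_labels(points: np.ndarray, eps: float) -> np.ndarray:
    """Single-linkage clustering at radius eps via the eps-neighborhood graph."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    n = len(points)
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        graph = coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def _kasa_center(pts2d: np.ndarray) -> np.ndarray:
    """Algebraic (Kåsa) circle-fit center; falls back to the centroid."""
    x, y = pts2d[:, 0], pts2d[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.isfinite(sol[:2]).all():
            return sol[:2]
    except np.linalg.LinAlgError:
        pass
    return pts2d.mean(axis=0)


def _shape_scores(points: np.ndarray) -> tuple[float, float]:
    """(planarity, annularity) of one cluster."""
    centered = points - points.mean(axis=0)
    # eigenvalues of the covariance, descending
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    ev = svals**2
    planarity = float(ev[2] / ev[0]) if ev[0] > 0 else 0.0
    proj = centered @ vt[:2].T  # in-plane coordinates
    center = _kasa_center(proj)
    radial = np.linalg.norm(proj - center, axis=1)
    mean_r = radial.mean()
    annularity = float(radial.std() / mean_r) if mean_r > 0 else np.inf
    return planarity, annularity


def select_ring_cluster(
    cloud: ColoredPointCloud,
    red_indices: np.ndarray,
    eps: float | None = None,
    min_cluster: int = 100,
    planarity_max: float = 0.05,
    annularity_max: float = 0.25,
) -> RingCandidate:
    """Pick the ring among red clusters by planarity and annularity.

    ``eps`` defaults to five times the median nearest-neighbor distance
    of the red subset — scale-free, since the cloud's units are unknown
    before calibration, and generous enough that a noisy ring percolates
    into one cluster while staying far below the separation of any
    distinct red object. The largest passing cluster wins; ties break by lower
    annularity, then lower planarity (deterministic).

    Raises :class:`NoRingFoundError` with per-cluster diagnostics when
    nothing passes.
    """
    red_indices = np.asarray(red_indices)
    if len(red_indices) < min_cluster:
        raise NoRingFoundError(
            f"only {len(red_indices)} red points; need at least min_cluster={min_cluster}"
        )
    red_pts = cloud.points[red_indices]
    if eps is None:
        tree = cKDTree(red_pts)
        nn_dist, _ = tree.query(red_pts, k=2)
        eps = 5.0 * float(np.median(nn_dist[:, 1]))
        if eps <= 0:
            raise ParameterError("degenerate red subset: zero nearest-neighbor distance")

    labels = _cluster_labels(red_pts, eps)
    diagnostics = []
    candidates: list[RingCandidate] = []
    for lab in np.unique(labels):
        member = labels == lab
        n = int(member.sum())
        if n < min_cluster:
            continue
        planarity, annularity = _shape_scores(red_pts[member])
        diagnostics.append(
            {"n_points": n, "planarity": planarity, "annularity": annularity,
             "passed": planarity <= planarity_max and annularity <= annularity_max}
        )
        if planarity <= planarity_max and annularity <= annularity_max:
            candidates.append(
                RingCandidate(red_indices[member], planarity, annularity, n)
            )
    if not candidates:
        raise NoRingFoundError(
            f"no red cluster passed planarity<={planarity_max} and "
            f"annularity<={annularity_max} ({len(diagnostics)} clusters scored)",
            diagnostics=diagnostics,
        )
    candidates.sort(key=lambda c: (-c.n_points, c.annularity, c.planarity))
    return candidates[0]
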