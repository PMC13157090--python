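"""Metric-scale and pose recovery from the detected ring cloud.

Monocular multi-view reconstructions are determined only up to a global
similarity, so a plant cloud out of SfM/MVS has arbitrary units and
orientation. A printed ring of known physical diameter fixes both: PCA
of the ring cloud gives the ring plane (the smallest-eigenvalue axis is
the plane normal), a Rodrigues rotation aligns that normal with the
world vertical, and a two-stage circle fit — RANSAC for a robust initial
circle, geometric least squares on its inliers for precision — measures
the ring's diameter in reconstruction units. The scale factor is then

    s = D_true / D_fitted

which converts reconstruction units to millimeters. Combined with a
translation putting the fitted circle center at the origin (ring plane
= ground plane z=0), this yields the full similarity

    p_world = s * (R^T p) + t

applied to the plant cloud. The geometric (orthogonal-distance)
least-squares refinement matters under occlusion: unlike algebraic
fits it is unbiased on partial arcs, so even a ring with most of its
circumference hidden still yields the correct diameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .cloud import ColoredPointCloud
from .errors import (
    AmbiguousOrientationError,
    DegenerateGeometryError,
    FitFailedError,
    ParameterError,
)

WORLD_Z = np.array([0.0, 0.0, 1.0])


# --------------------------------------------------------------------------
# PCA plane frame


@dataclass
class PlaneFrame:
    """Centroid plus orthonormal axes of the ring cloud, by descending variance.

    ``e3`` (smallest eigenvalue) is the plane normal; the triplet is
    right-handed.
    """

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray


def pca_frame(points: np.ndarray) -> PlaneFrame:
    """PCA coordinate frame of a point set: the eigenvectors of its
    covariance are the axes of the new coordinate system.

    Raises :class:`DegenerateGeometryError` for collinear input (no
    unique plane).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 3:
        raise ParameterError(f"need at least 3 points, got {len(points)}")
    origin = points.mean(axis=0)
    centered = points - origin
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= 1e-12 * max(svals[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    e1, e2, e3 = vt[0], vt[1], vt[2]
    if np.linalg.det(np.column_stack([e1, e2, e3])) < 0:
        e3 = -e3
    return PlaneFrame(origin, e1, e2, e3)


# --------------------------------------------------------------------------
# Rodrigues rotation


def _skew(k: np.ndarray) -> np.ndarray:
    return np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0.0]])


def rodrigues(z_old: np.ndarray, z_target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``z_old`` onto ``z_target``.

    Axis-angle form R = I + sinθ·[k]× + (1−cosθ)·[k]×², with
    k = z_old×z_target / ‖z_old×z_target‖ and θ = arccos(z_old·z_target).
    Degenerate cases: parallel inputs return the identity; antiparallel
    inputs (cross product vanishes) rotate 180° about a deterministic
    axis orthogonal to ``z_old``.
    """
    z_old = np.asarray(z_old, dtype=np.float64)
    z_target = np.asarray(z_target, dtype=np.float64)
    for v, name in ((z_old, "z_old"), (z_target, "z_target")):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ParameterError(f"{name} must be unit-norm, got |{name}|={np.linalg.norm(v):g}")
    cross = np.cross(z_old, z_target)
    cross_norm = np.linalg.norm(cross)
    cos_t = float(np.clip(np.dot(z_old, z_target), -1.0, 1.0))
    theta = np.arccos(cos_t)
    if cross_norm < 1e-9:
        if cos_t > 0:  # parallel
            return np.eye(3)
        # antiparallel: 180° about any axis ⟂ z_old; pick deterministically
        cand = [np.cross(z_old, np.array([1.0, 0, 0])), np.cross(z_old, np.array([0, 1.0, 0]))]
        k = max(cand, key=np.linalg.norm)
        k = k / np.linalg.norm(k)
        theta = np.pi
    else:
        k = cross / cross_norm
    K = _skew(k)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


# --------------------------------------------------------------------------
# Plane projection and circle fitting


def project_to_plane(points: np.ndarray, frame: PlaneFrame) -> np.ndarray:
    """In-plane (e1, e2) coordinates of points relative to the frame origin."""
    centered = np.asarray(points, dtype=np.float64) - frame.origin
    return np.column_stack([centered @ frame.e1, centered @ frame.e2])


@dataclass
class CircleFitResult:
    """A fitted 2D circle in plane coordinates."""

    center2d: np.ndarray
    radius: float
    inlier_mask: np.ndarray
    rms_residual: float
    converged: bool = True

    @property
    def d_fitted(self) -> float:
        """Fitted diameter, 2r."""
        return 2.0 * self.radius

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError(f"radius must be positive, got {self.radius}")


def kasa_circle(points2d: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) circle fit: linear least squares on
    x² + y² = 2ax + 2by + c. Fast but biased on partial arcs; used only
    to seed the geometric fit.
    """
    pts = np.asarray(points2d, dtype=np.float64)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    sol, *_ = np.linalg.lstsq(A, x * x + y * y, rcond=None)
    center = sol[:2]
    r2 = sol[2] + center @ center
    return center, float(np.sqrt(max(r2, 0.0)))


def _circumcircles(a, b, c):
    """Vectorized circumcircle of point triples; returns centers, radii, valid."""
    d = 2.0 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1])
               + c[:, 0] * (a[:, 1] - b[:, 1]))
    a2 = (a * a).sum(axis=1)
    b2 = (b * b).sum(axis=1)
    c2 = (c * c).sum(axis=1)
    scale = np.maximum.reduce([np.abs(a).max(axis=1), np.abs(b).max(axis=1),
                               np.abs(c).max(axis=1), np.ones(len(a))])
    valid = np.abs(d) > 1e-12 * scale**2
    d_safe = np.where(valid, d, 1.0)
    ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d_safe
    uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d_safe
    centers = np.column_stack([ux, uy])
    radii = np.linalg.norm(a - centers, axis=1)
    return centers, radii, valid


def ransac_circle(
    points2d: np.ndarray,
    n_iter: int = 2000,
    inlier_tol: float | None = None,
    min_inlier_frac: float = 0.3,
    seed: int = 0,
) -> CircleFitResult:
    """Robust initial circle: best of ``n_iter`` three-point hypotheses.

    Each hypothesis is the circumcircle of a random point triple, scored
    by its inlier count (|distance to circle| ≤ ``inlier_tol``); ties
    break by lower RMS inlier residual. Deterministic given ``seed``.
    Fails with :class:`FitFailedError` when the best hypothesis explains
    less than ``min_inlier_frac`` of the points.

    The default ``inlier_tol`` adapts to the data: three times the
    median absolute radial residual of an algebraic prefit, floored at
    2% of the spread. A printed ring has a finite stroke width, and a
    tolerance narrower than the stroke would lock onto a sub-band of it
    and bias the diameter; the adaptive default covers the full stroke.
    Supply an explicit tolerance when the point set is heavily
    contaminated (the prefit assumes mostly on-circle points).
    """
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    m = len(pts)
    if m < 3:
        raise ParameterError(f"need at least 3 points, got {m}")
    if inlier_tol is None:
        spread = float(np.median(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
        if spread <= 0:
            raise ParameterError("degenerate point set: zero spread")
        c0, r0 = kasa_circle(pts)
        resid = np.abs(np.linalg.norm(pts - c0, axis=1) - r0)
        inlier_tol = max(3.0 * float(np.median(resid)), 0.02 * spread)

    rng = np.random.default_rng(seed)
    triples = np.array([rng.choice(m, 3, replace=False) for _ in range(n_iter)])
    centers, radii, valid = _circumcircles(pts[triples[:, 0]], pts[triples[:, 1]], pts[triples[:, 2]])

    best = None  # (count, -rms) maximized
    chunk = 128
    x, y = pts[:, 0], pts[:, 1]
    for lo in range(0, n_iter, chunk):
        idx = np.arange(lo, min(lo + chunk, n_iter))
        idx = idx[valid[idx] & (radii[idx] > 0)]
        if not len(idx):
            continue
        d2 = (x[None, :] - centers[idx, 0, None]) ** 2 + (y[None, :] - centers[idx, 1, None]) ** 2
        dist = np.abs(np.sqrt(d2) - radii[idx, None])
        inl = dist <= inlier_tol
        counts = inl.sum(axis=1)
        for j in np.flatnonzero(counts == counts.max()):
            cnt = int(counts[j])
            if best is not None and cnt < best[0]:
                continue
            rms = float(np.sqrt(np.mean(dist[j][inl[j]] ** 2))) if cnt else np.inf
            key = (cnt, -rms)
            if best is None or key > best[:2]:
                best = (cnt, -rms, centers[idx[j]], radii[idx[j]], inl[j])

    if best is None:
        raise FitFailedError("all RANSAC hypotheses degenerate", best_inlier_frac=0.0)
    cnt, neg_rms, center, radius, mask = best
    frac = cnt / m
    if frac < min_inlier_frac:
        raise FitFailedError(
            f"best inlier fraction {frac:.3f} < min_inlier_frac={min_inlier_frac}",
            best_inlier_frac=frac,
        )
    return CircleFitResult(center, float(radius), mask, -neg_rms)


def lsq_refine_circle(
    points2d: np.ndarray,
    inlier_mask: np.ndarray | None = None,
    init: CircleFitResult | None = None,
    max_iter: int = 100,
) -> CircleFitResult:
    """Geometric least-squares circle on the inliers.

    Minimizes Σ(‖p−c‖−r)² (orthogonal radial residuals) by
    Levenberg–Marquardt from the RANSAC estimate (Kåsa fit when no init
    is given). Geometric LS is exact on noiseless partial arcs, which is
    what makes the diameter estimate occlusion-proof. Never returns a
    worse objective than the initialization.
    """
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    if inlier_mask is None:
        inlier_mask = np.ones(len(pts), dtype=bool)
    inl = pts[np.asarray(inlier_mask, dtype=bool)]
    if len(inl) < 3:
        raise ParameterError(f"need at least 3 inliers, got {len(inl)}")
    if init is not None:
        x0 = np.array([init.center2d[0], init.center2d[1], init.radius])
    else:
        c0, r0 = kasa_circle(inl)
        x0 = np.array([c0[0], c0[1], max(r0, 1e-12)])

    def resid(x):
        return np.linalg.norm(inl - x[:2], axis=1) - x[2]

    sol = least_squares(resid, x0, method="lm", max_nfev=max_iter * 4)
    converged = bool(sol.status > 0)
    if not converged:
        warnings.warn("circle refinement did not converge; returning best iterate")
    # guarantee: never worse than the initialization
    if np.sum(resid(sol.x) ** 2) <= np.sum(resid(x0) ** 2):
        x = sol.x
    else:
        x, converged = x0, False
    rms = float(np.sqrt(np.mean((np.linalg.norm(inl - x[:2], axis=1) - x[2]) ** 2)))
    return CircleFitResult(x[:2].copy(), float(abs(x[2])), np.asarray(inlier_mask, bool),
                           rms, converged)


def fit_circle(
    points2d: np.ndarray,
    n_iter: int = 2000,
    inlier_tol: float | None = None,
    min_inlier_frac: float = 0.3,
    seed: int = 0,
    reselect_rounds: int = 2,
) -> CircleFitResult:
    """Two-stage fit: RANSAC initial circle, geometric LS refinement,
    plus inlier re-selection rounds so the final inlier set is defined
    by the refined circle rather than the (cruder) RANSAC hypothesis.
    """
    pts = np.asarray(points2d, dtype=np.float64).reshape(-1, 2)
    initial = ransac_circle(pts, n_iter, inlier_tol, min_inlier_frac, seed)
    # re-derive the tolerance actually used, for re-selection
    tol = inlier_tol
    if tol is None:
        dist0 = np.abs(np.linalg.norm(pts - initial.center2d, axis=1) - initial.radius)
        tol = float(np.partition(dist0[initial.inlier_mask], -1)[-1]) if initial.inlier_mask.any() else 0.0
    fit = lsq_refine_circle(pts, initial.inlier_mask, initial)
    for _ in range(reselect_rounds):
        resid = np.abs(np.linalg.norm(pts - fit.center2d, axis=1) - fit.radius)
        mask = resid <= tol
        if mask.sum() < 3 or np.array_equal(mask, fit.inlier_mask):
            break
        fit = lsq_refine_circle(pts, mask, fit)
    return fit


# --------------------------------------------------------------------------
# Scale and the assembled transform


def scale_factor(d_fitted: float, d_true: float) -> float:
    """s = D_true / D_fitted: reconstruction units → millimeters."""
    if d_fitted <= 0 or d_true <= 0:
        raise ParameterError(f"diameters must be positive, got {d_fitted}, {d_true}")
    return d_true / d_fitted


@dataclass
class MetricTransform:
    """Similarity mapping reconstruction coordinates to the metric world
    frame: p_world = s·(Rᵀ p) + t, with t in millimeters.
    """

    R: np.ndarray
    s: float
    t: np.ndarray
    d_true_mm: float | None = None
    d_fitted: float | None = None
    rms_residual: float | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if self.s <= 0:
            raise ParameterError(f"scale must be positive, got {self.s}")
        if np.abs(self.R @ self.R.T - np.eye(3)).max() > 1e-8:
            raise ParameterError("R is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-8:
            raise ParameterError("R is not a proper rotation (det != +1)")

    def to_json(self, path=None) -> str:
        payload = {
            "R": self.R.tolist(),
            "s": self.s,
            "t": self.t.tolist(),
            "d_true_mm": self.d_true_mm,
            "d_fitted": self.d_fitted,
            "rms_residual": self.rms_residual,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MetricTransform":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        missing = {"R", "s", "t"} - payload.keys()
        if missing:
            raise ParameterError(f"transform JSON missing fields: {sorted(missing)}")
        return cls(
            np.array(payload["R"]), payload["s"], np.array(payload["t"]),
            payload.get("d_true_mm"), payload.get("d_fitted"), payload.get("rms_residual"),
        )


def build_metric_transform(
    ring_frame: PlaneFrame,
    circle: CircleFitResult,
    plant_cloud: ColoredPointCloud,
    d_true: float = 200.0,
    center_origin: bool = True,
) -> MetricTransform:
    """Assemble rotation, scale, and translation from the fitted ring.

    The ring normal's sign is ambiguous from PCA alone; it is fixed by
    requiring the plant centroid to lie on the positive side (plants grow
    above the ring plane). The stored R satisfies Rᵀ·(ring normal) =
    world +z, so applying the transform makes the cloud upright. With
    ``center_origin`` the fitted circle center maps to the world origin
    and the ring plane to z=0, giving heights measured from the ground
    plane; without it, t = 0.
    """
    if plant_cloud.n == 0:
        raise ParameterError("plant cloud is empty")
    z_old = ring_frame.e3
    height = float((plant_cloud.points.mean(axis=0) - ring_frame.origin) @ z_old)
    if abs(height) < 1e-9:
        raise AmbiguousOrientationError(
            "plant centroid lies on the ring plane; cannot orient the normal"
        )
    if height < 0:
        z_old = -z_old
    # Rᵀ must map the ring normal onto world +z
    R = rodrigues(WORLD_Z, z_old)
    s = scale_factor(circle.d_fitted, d_true)
    if center_origin:
        center3d = (
            ring_frame.origin
            + circle.center2d[0] * ring_frame.e1
            + circle.center2d[1] * ring_frame.e2
        )
        t = -s * (R.T @ center3d)
    else:
        t = np.zeros(3)
    return MetricTransform(R, s, t, d_true_mm=d_true, d_fitted=circle.d_fitted,
                           rms_residual=circle.rms_residual)


def apply_transform(cloud: ColoredPointCloud, T: MetricTransform) -> ColoredPointCloud:
    """Reorient and rescale: p_world = s·(Rᵀ p) + t; units become mm."""
    if cloud.units == "mm":
        raise ParameterError("cloud is already metric; refusing to apply transform twice")
    pts = T.s * (cloud.points @ T.R) + T.t  # pts @ R == (Rᵀ pᵀ)ᵀ row-wise
    return ColoredPointCloud(pts, cloud.colors.copy(), units="mm")
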