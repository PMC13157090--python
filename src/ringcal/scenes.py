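"""Synthetic colored scenes with exact ground truth.

A scene is a red annular ring of known diameter on the ground plane, a
stylized parametric plant above it, and optional red distractor clutter
— all pushed through a known similarity transform (rotation, uniform
scale, translation) that stands in for the arbitrary coordinate system
of a monocular reconstruction. Because every generation parameter is
recorded, the correct output of the calibration pipeline is known
exactly: the recovered scale factor must equal ``1/s*`` for an applied
similarity scale ``s*``, and the recovered world frame must reproduce
the pre-similarity geometry up to a rotation about the vertical.

Perturbation axes mirror what degrades real captures: additive
coordinate noise, contiguous arc occlusion of the ring (a leaf lying
over one side — the hard case for corner-based markers), ring
inclination, chromatic jitter (print and illumination variation,
modeled as hue-wrapped Gaussian hue noise plus saturation/value
shifts), and red clutter in the background.

Plants are stylized shapes (disk leaf, stem with elliptical leaves,
box) rather than realistic models: the point is analytic ground truth
for heights and areas, not realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.spatial.transform import Rotation

from .cloud import ColoredPointCloud
from .errors import ParameterError

LABEL_RING, LABEL_PLANT, LABEL_CLUTTER = 0, 1, 2

PLANT_KINDS = ("none", "disk_leaf", "stem_and_leaves", "box")

#: Leaf pitch above horizontal for the stem_and_leaves plant (degrees).
LEAF_PITCH_DEG = 30.0
STEM_RADIUS_MM = 3.0
ELLIPSE_ASPECT = 0.6  # minor/major axis ratio of leaves


@dataclass
class SceneSpec:
    """Full parameterization of one synthetic scene.

    Geometry is generated in metric world coordinates (mm, ring plane at
    z=0) and then mapped through the similarity
    ``p -> sim_scale * (R(sim_rotvec) p) + sim_translation``.
    """

    d_true: float = 200.0          # printed ring diameter, mm
    annulus_width: float = 10.0    # radial stroke width of the printed ring, mm
    ring_points: int = 30000       # full-ring count (~5 pts/mm² of stroke, dense MVS)
    plant: str = "disk_leaf"
    plant_height: float = 300.0    # mm
    leaf_radius: float = 50.0      # mm (also half box width for kind="box")
    leaf_count: int = 5
    plant_points: int = 4000
    noise_sigma: float = 0.0       # mm, isotropic Gaussian coordinate noise
    occlusion_frac: float = 0.0    # contiguous arc fraction removed, [0,1)
    inclination_deg: float = 0.0   # ring tilt from horizontal
    clutter: tuple = ()            # dicts: kind, size, position, n_points
    hue_jitter: float = 3.0        # degrees, wrap-aware
    sat_jitter: float = 0.05
    val_jitter: float = 0.05
    sim_scale: float = 1.0         # s* of the applied similarity
    sim_rotvec: tuple = (0.0, 0.0, 0.0)
    sim_translation: tuple = (0.0, 0.0, 0.0)
    seed: int = 0
    plant_seed: int | None = None  # vary the plant while keeping the same ring

    def __post_init__(self):
        if self.d_true <= 0:
            raise ParameterError("d_true must be positive")
        if not 0 <= self.occlusion_frac < 1:
            raise ParameterError("occlusion_frac must lie in [0, 1)")
        if self.sim_scale <= 0:
            raise ParameterError("sim_scale must be positive")
        if self.plant not in PLANT_KINDS:
            raise ParameterError(f"plant must be one of {PLANT_KINDS}, got {self.plant!r}")
        if self.annulus_width < 0 or self.noise_sigma < 0:
            raise ParameterError("annulus_width and noise_sigma must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clutter"] = [dict(c) for c in self.clutter]
        d["sim_rotvec"] = list(self.sim_rotvec)
        d["sim_translation"] = list(self.sim_translation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown SceneSpec fields: {sorted(unknown)}")
        d = dict(d)
        if "clutter" in d:
            d["clutter"] = tuple(dict(c) for c in d["clutter"])
        for key in ("sim_rotvec", "sim_translation"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene, for assertions."""

    ring_center: np.ndarray        # scene (post-similarity) coordinates
    ring_normal: np.ndarray        # scene coordinates, unit
    ring_diameter_mm: float
    labels: np.ndarray             # per-point: 0 ring, 1 plant, 2 clutter
    plant_height_mm: float | None
    leaf_area_mm2: float | None
    projection_area_mm2: float | None
    expected_scale: float          # the scale the pipeline should recover, 1/s*
    sim_scale: float
    sim_rotvec: tuple
    sim_translation: tuple
    world_points: np.ndarray | None = None  # pre-similarity metric coordinates

    def to_json(self, path=None) -> str:
        payload = {
            "ring_center": self.ring_center.tolist(),
            "ring_normal": self.ring_normal.tolist(),
            "ring_diameter_mm": self.ring_diameter_mm,
            "labels": self.labels.tolist(),
            "plant_height_mm": self.plant_height_mm,
            "leaf_area_mm2": self.leaf_area_mm2,
            "projection_area_mm2": self.projection_area_mm2,
            "expected_scale": self.expected_scale,
            "sim_scale": self.sim_scale,
            "sim_rotvec": list(self.sim_rotvec),
            "sim_translation": list(self.sim_translation),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        with open(source) as fh:
            p = json.load(fh)
        return cls(
            np.array(p["ring_center"]), np.array(p["ring_normal"]),
            p["ring_diameter_mm"], np.array(p["labels"], dtype=np.int64),
            p["plant_height_mm"], p["leaf_area_mm2"], p["projection_area_mm2"],
            p["expected_scale"], p["sim_scale"], tuple(p["sim_rotvec"]),
            tuple(p["sim_translation"]),
        )


# --------------------------------------------------------------------------
# Color models


def _jittered_colors(rng, n, base_hue_deg, base_sat, base_val, spec: SceneSpec):
    hue = (base_hue_deg + rng.normal(0.0, spec.hue_jitter, n)) % 360.0
    sat = np.clip(base_sat + rng.normal(0.0, spec.sat_jitter, n), 0.0, 1.0)
    val = np.clip(base_val + rng.normal(0.0, spec.val_jitter, n), 0.0, 1.0)
    return hsv_to_rgb(np.column_stack([hue / 360.0, sat, val]))


def _red(rng, n, spec):
    return _jittered_colors(rng, n, 0.0, 0.95, 0.85, spec)


def _green(rng, n, spec):
    return _jittered_colors(rng, n, 120.0, 0.75, 0.6, spec)


# --------------------------------------------------------------------------
# Primitives (generated in metric world coordinates, ring plane z=0)


def make_ring(spec: SceneSpec, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Sample the red annulus; returns (points, colors) in world mm.

    Radii are uniform in ``[d/2 - w/2, d/2 + w/2]`` (so the mean circle
    of the sample equals the nominal diameter). Occlusion removes the
    points of one contiguous arc — a hidden arc is simply never
    reconstructed, so the point count scales with the visible fraction.
    Inclination tilts the ring about the x-axis through its own center;
    Gaussian noise is added last.

    A zero ``annulus_width`` is the idealized fiducial — a mathematical
    circle — and is sampled at uniform arc density (regular angular grid
    with a random phase), the limit of scanning a continuous curve; a
    positive width is sampled at random, like a reconstructed printed
    stroke.
    """
    rng = np.random.default_rng([spec.seed, 0]) if rng is None else rng
    n = round(spec.ring_points * (1.0 - spec.occlusion_frac))
    r = spec.d_true / 2.0 + spec.annulus_width * (rng.uniform(-0.5, 0.5, n))
    theta0 = rng.uniform(0.0, 2 * np.pi)
    span = 2 * np.pi * (1.0 - spec.occlusion_frac)
    if spec.annulus_width == 0:
        theta = theta0 + span * (np.arange(n) + 0.5) / n
    else:
        theta = theta0 + rng.uniform(0.0, span, n)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n)])
    if spec.inclination_deg:
        pts = pts @ Rotation.from_euler("x", spec.inclination_deg, degrees=True).as_matrix().T
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, pts.shape)
    return pts, _red(rng, n, spec)


def ring_normal_world(spec: SceneSpec) -> np.ndarray:
    """Unit normal of the (possibly tilted) ring before the similarity."""
    return Rotation.from_euler("x", spec.inclination_deg, degrees=True).apply([0.0, 0.0, 1.0])


def _sample_disk(rng, n, radius):
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    t = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def _sample_box_surface(rng, n, w, h):
    """Uniform sample of the surface of a box [-w/2,w/2]² × [0,h]."""
    areas = np.array([w * w, w * w, w * h, w * h, w * h, w * h])
    face = rng.choice(6, n, p=areas / areas.sum())
    u = rng.uniform(-0.5, 0.5, n) * w
    v = rng.uniform(-0.5, 0.5, n) * w
    zz = rng.uniform(0.0, 1.0, n) * h
    pts = np.empty((n, 3))
    pts[face == 0] = np.column_stack([u, v, np.zeros(n)])[face == 0]
    pts[face == 1] = np.column_stack([u, v, np.full(n, h)])[face == 1]
    pts[face == 2] = np.column_stack([np.full(n, -w / 2), u, zz])[face == 2]
    pts[face == 3] = np.column_stack([np.full(n, w / 2), u, zz])[face == 3]
    pts[face == 4] = np.column_stack([u, np.full(n, -w / 2), zz])[face == 4]
    pts[face == 5] = np.column_stack([u, np.full(n, w / 2), zz])[face == 5]
    return pts


def make_plant(spec: SceneSpec, rng=None):
    """Sample the stylized plant; returns (points, colors, truth dict).

    Truth carries the analytic height (exact top of the geometry), leaf
    area (sum of leaf-surface areas), and top-down projection area where
    it is analytic.
    """
    rng = np.random.default_rng([spec.seed, 1, spec.plant_seed or 0]) if rng is None else rng
    n = spec.plant_points
    kind = spec.plant
    if kind == "none":
        return np.empty((0, 3)), np.empty((0, 3)), {
            "height": None, "leaf_area": None, "projection_area": None}

    if kind == "disk_leaf":
        xy = _sample_disk(rng, n, spec.leaf_radius)
        pts = np.column_stack([xy, np.full(n, spec.plant_height)])
        truth = {
            "height": spec.plant_height,
            "leaf_area": np.pi * spec.leaf_radius**2,
            "projection_area": np.pi * spec.leaf_radius**2,
        }
    elif kind == "box":
        w = 2.0 * spec.leaf_radius
        pts = _sample_box_surface(rng, n, w, spec.plant_height)
        truth = {
            "height": spec.plant_height,
            "leaf_area": 2 * w * w + 4 * w * spec.plant_height,  # box surface
            "projection_area": w * w,
        }
    else:  # stem_and_leaves
        a = spec.leaf_radius
        b = ELLIPSE_ASPECT * a
        pitch = np.deg2rad(LEAF_PITCH_DEG)
        n_leaf_pts = int(0.8 * n) // max(spec.leaf_count, 1)
        n_stem = n - n_leaf_pts * spec.leaf_count
        t = rng.uniform(0.0, 2 * np.pi, n_stem)
        stem = np.column_stack([
            STEM_RADIUS_MM * np.cos(t), STEM_RADIUS_MM * np.sin(t),
            rng.uniform(0.0, spec.plant_height, n_stem),
        ])
        parts = [stem]
        for j in range(spec.leaf_count):
            h_j = spec.plant_height * (j + 1) / spec.leaf_count
            phi = 2 * np.pi * j / spec.leaf_count
            radial = np.array([np.cos(phi), np.sin(phi), 0.0])
            major = np.array([np.cos(phi) * np.cos(pitch), np.sin(phi) * np.cos(pitch),
                              np.sin(pitch)])
            minor = np.array([-np.sin(phi), np.cos(phi), 0.0])
            uv = _sample_disk(rng, n_leaf_pts, 1.0)
            center = (STEM_RADIUS_MM + a) * radial * np.array([1, 1, 0]) + np.array([0, 0, h_j])
            parts.append(center + np.outer(a * uv[:, 0], major) + np.outer(b * uv[:, 1], minor))
        pts = np.vstack(parts)
        truth = {
            "height": spec.plant_height + a * np.sin(pitch),  # tip of the top leaf
            "leaf_area": spec.leaf_count * np.pi * a * b,
            "projection_area": None,  # overlapping leaves: not analytic
        }
    return pts, _green(rng, len(pts), spec), truth


def make_clutter(spec: SceneSpec, rng=None):
    """Red distractor primitives (sphere/cube surfaces); (points, colors)."""
    rng = np.random.default_rng([spec.seed, 2]) if rng is None else rng
    pts_parts, col_parts = [], []
    for item in spec.clutter:
        kind = item.get("kind", "sphere")
        size = float(item.get("size", 80.0))
        pos = np.asarray(item.get("position", (400.0, 0.0, 80.0)), dtype=np.float64)
        n = int(item.get("n_points", 2000))
        if kind == "sphere":
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = pos + size * v
        elif kind == "cube":
            pts = pos + _sample_box_surface(rng, n, 2 * size, 2 * size) - [0, 0, size]
        else:
            raise ParameterError(f"unknown clutter kind {kind!r}")
        pts_parts.append(pts)
        col_parts.append(_red(rng, n, spec))
    if not pts_parts:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.vstack(pts_parts), np.vstack(col_parts)


# --------------------------------------------------------------------------
# Assembled scene


def similarity_matrix(spec: SceneSpec) -> np.ndarray:
    return Rotation.from_rotvec(spec.sim_rotvec).as_matrix()


def make_scene(spec: SceneSpec) -> tuple[ColoredPointCloud, GroundTruth]:
    """Generate ring + plant + clutter and obfuscate with the similarity.

    The returned cloud is in "reconstruction" units; the ground truth
    records the pre-similarity metric geometry, per-point labels, and the
    scale ``1/s*`` a correct calibration must recover.
    """
    ring_pts, ring_cols = make_ring(spec)
    plant_pts, plant_cols, plant_truth = make_plant(spec)
    clut_pts, clut_cols = make_clutter(spec)

    pts = np.vstack([ring_pts, plant_pts, clut_pts])
    cols = np.vstack([ring_cols, plant_cols, clut_cols])
    labels = np.concatenate([
        np.full(len(ring_pts), LABEL_RING),
        np.full(len(plant_pts), LABEL_PLANT),
        np.full(len(clut_pts), LABEL_CLUTTER),
    ]).astype(np.int64)

    R = similarity_matrix(spec)
    t = np.asarray(spec.sim_translation, dtype=np.float64)
    scene_pts = spec.sim_scale * (pts @ R.T) + t

    truth = GroundTruth(
        ring_center=t.copy(),  # ring centered at the world origin pre-similarity
        ring_normal=R @ ring_normal_world(spec),
        ring_diameter_mm=spec.d_true,
        labels=labels,
        plant_height_mm=plant_truth["height"],
        leaf_area_mm2=plant_truth["leaf_area"],
        projection_area_mm2=plant_truth["projection_area"],
        expected_scale=1.0 / spec.sim_scale,
        sim_scale=spec.sim_scale,
        sim_rotvec=tuple(spec.sim_rotvec),
        sim_translation=tuple(spec.sim_translation),
        world_points=pts,
    )
    return ColoredPointCloud(scene_pts, cols, "reconstruction"), truth


def random_similarity(rng, scale_lo: float = 0.01, scale_hi: float = 100.0) -> dict:
    """Draw a random similarity: log-uniform scale, uniform rotation,
    bounded translation. Returns SceneSpec field overrides.
    """
    s = float(np.exp(rng.uniform(np.log(scale_lo), np.log(scale_hi))))
    rotvec = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_rotvec()
    t = rng.uniform(-100.0, 100.0, 3)
    return {"sim_scale": s, "sim_rotvec": tuple(rotvec), "sim_translation": tuple(t)}


def growth_sequence(base_spec: SceneSpec, n_steps: int = 6, growth_factors=None):
    """Scenes of the same ring with the plant scaled per step.

    ``growth_factors`` must be monotone nondecreasing (default: linear
    1.0 → 2.0 over ``n_steps``). Each step regenerates the plant with a
    step-specific seed; the ring is identical across steps, as in a real
    time series where the fiducial stays put.
    """
    if growth_factors is None:
        growth_factors = np.linspace(1.0, 2.0, n_steps)
    growth_factors = np.asarray(growth_factors, dtype=np.float64)
    if np.any(np.diff(growth_factors) < 0):
        raise ParameterError("growth_factors must be monotone nondecreasing")
    scenes = []
    for step, f in enumerate(growth_factors):
        spec_i = replace(
            base_spec,
            plant_height=base_spec.plant_height * float(f),
            leaf_radius=base_spec.leaf_radius * float(f),
            plant_seed=step,
        )
        scenes.append(make_scene(spec_i))
    return scenes
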