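"""Colored point clouds: container, PLY I/O, and basic cleaning.

The whole pipeline works on one container, :class:`ColoredPointCloud`:
an ``(N, 3)`` float64 coordinate array plus ``(N, 3)`` RGB colors in
``[0, 1]`` and a ``units`` tag (``"reconstruction"`` before calibration,
``"mm"`` after). PLY is the single supported on-disk format — it is the
de facto output of multi-view-stereo tools. Reading goes through
:mod:`trimesh`; writing uses an in-package emitter because the contract
here requires float64 vertex coordinates (round-trip fidelity of 1e-6 on
millimeter-scale clouds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

UNITS = ("reconstruction", "mm")

#: Fill color used when a PLY carries no color properties.
DEFAULT_GRAY = (0.5, 0.5, 0.5)


@dataclass
class ColoredPointCloud:
    """N points with 3D coordinates, RGB colors in [0,1], and a units tag."""

    points: np.ndarray
    colors: np.ndarray
    units: str = "reconstruction"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        if self.points.shape[0] != self.colors.shape[0]:
            raise ParameterError(
                f"points ({self.points.shape[0]}) and colors "
                f"({self.colors.shape[0]}) must have the same length"
            )
        if self.units not in UNITS:
            raise ParameterError(f"units must be one of {UNITS}, got {self.units!r}")
        if self.colors.size and (self.colors.min() < -1e-9 or self.colors.max() > 1 + 1e-9):
            raise ParameterError("colors must lie in [0, 1]")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def select(self, index) -> "ColoredPointCloud":
        """Subset by integer indices or boolean mask, preserving order."""
        return ColoredPointCloud(self.points[index], self.colors[index], self.units)

    def with_units(self, units: str) -> "ColoredPointCloud":
        return replace(self, units=units)


def _colors_from_raw(raw_vertex: dict, n: int) -> np.ndarray | None:
    """Recover r/g/b-aliased color properties trimesh does not map itself."""
    data = raw_vertex.get("data")
    if data is None:
        return None
    if hasattr(data, "dtype") and data.dtype is not None and data.dtype.names:
        names = data.dtype.names
    elif isinstance(data, dict):
        names = tuple(data.keys())
    else:
        return None
    for triple in (("red", "green", "blue"), ("r", "g", "b")):
        if all(t in names for t in triple):
            cols = np.column_stack(
                [np.asarray(data[t], dtype=np.float64).ravel() for t in triple]
            )
            if len(cols) == n:
                return cols
    return None


def read_ply(path) -> ColoredPointCloud:
    """Load a colored point cloud from an ASCII or binary little-endian PLY.

    Vertex colors may be named ``red/green/blue`` or ``r/g/b``, stored as
    uchar or float. Missing colors are filled with mid-gray and a warning
    is logged. Rows with non-finite coordinates are dropped (with a logged
    count) — dense MVS outputs often contain a few. Faces, if present, are
    ignored; only vertices are read.

    A header line ``comment units=mm`` (written by :func:`write_ply` for
    calibrated clouds) restores the units tag; anything else loads as
    ``"reconstruction"``.
    """
    try:
        obj = trimesh.load(str(path), file_type="ply", process=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise FormatError(f"cannot parse PLY file {path}: {exc}") from exc

    if isinstance(obj, trimesh.Scene):
        if obj.is_empty:  # a zero-vertex PLY loads as an empty scene
            return ColoredPointCloud(np.empty((0, 3)), np.empty((0, 3)), "reconstruction")
        raise FormatError(f"{path}: multi-geometry PLY scenes are not supported")
    points = np.asarray(obj.vertices, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise FormatError(f"{path}: missing x,y,z vertex properties")
    n = points.shape[0]

    colors = None
    vc = getattr(getattr(obj, "visual", None), "vertex_colors", None)
    if vc is None:
        try:
            vc = obj.colors
        except Exception:
            vc = None
    if vc is not None and len(vc) == n and n > 0:
        colors = np.asarray(vc, dtype=np.float64)[:, :3]
    if colors is None:
        raw = obj.metadata.get("_ply_raw", {}).get("vertex", {})
        colors = _colors_from_raw(raw, n)
    if colors is None:
        log.warning("%s: no color properties; filling with mid-gray", path)
        colors = np.full((n, 3), DEFAULT_GRAY, dtype=np.float64)
    # uchar (or float-encoded 0..255) colors are normalized to [0,1]
    if colors.size and colors.max() > 1.0:
        colors = colors / 255.0
    colors = np.clip(colors, 0.0, 1.0)

    finite = np.isfinite(points).all(axis=1)
    if not finite.all():
        log.warning("%s: dropped %d rows with non-finite coordinates", path, int((~finite).sum()))
        points, colors = points[finite], colors[finite]

    units = "reconstruction"
    try:
        with open(path, "rb") as fh:
            header = fh.read(4096).split(b"end_header")[0]
        if b"comment units=mm" in header:
            units = "mm"
    except OSError:
        pass
    return ColoredPointCloud(points, colors, units)


def write_ply(cloud: ColoredPointCloud, path, binary: bool = False) -> None:
    """Write a PLY with float64 coordinates and uchar colors.

    ``binary`` selects binary little-endian; default is ASCII. The units
    tag is preserved in a header comment so metric clouds survive a file
    round trip. Round trip through :func:`read_ply` reproduces coordinates
    to 1e-6 and colors to 1/255.
    """
    pts = cloud.points
    cols = np.clip(np.rint(cloud.colors * 255.0), 0, 255).astype(np.uint8)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"comment units={cloud.units}\n"
        f"element vertex {len(pts)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        "end_header\n"
    )
    try:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            if binary:
                rec = np.empty(
                    len(pts),
                    dtype=[("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                           ("red", "u1"), ("green", "u1"), ("blue", "u1")],
                )
                rec["x"], rec["y"], rec["z"] = pts.T if len(pts) else ((), (), ())
                rec["red"], rec["green"], rec["blue"] = cols.T if len(pts) else ((), (), ())
                fh.write(rec.tobytes())
            else:
                for p, c in zip(pts, cols):
                    fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {c[0]} {c[1]} {c[2]}\n".encode())
    except OSError as exc:
        raise FormatError(f"cannot write PLY to {path}: {exc}") from exc


def statistical_outlier_mask(
    cloud: ColoredPointCloud, k: int = 8, sigma_mult: float = 2.0
) -> np.ndarray:
    """Boolean mask of points whose mean k-NN distance is unremarkable.

    A point survives if its mean distance to its ``k`` nearest neighbors
    is within ``mean + sigma_mult * std`` of the population of such
    distances. The statistic assumes roughly uniform sampling density
    across the cloud; apply it per segment when densities differ.
    """
    from scipy.spatial import cKDTree

    if cloud.n <= k:
        raise ParameterError(f"need more than k={k} points, got {cloud.n}")
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=k + 1)  # first neighbor is self
    mean_d = dist[:, 1:].mean(axis=1)
    return mean_d <= mean_d.mean() + sigma_mult * mean_d.std()


def remove_statistical_outliers(
    cloud: ColoredPointCloud, k: int = 8, sigma_mult: float = 2.0
) -> ColoredPointCloud:
    """Drop points flagged by :func:`statistical_outlier_mask`.

    The standard pre-fit cleaning filter; output preserves input order
    (a subset).
    """
    return cloud.select(statistical_outlier_mask(cloud, k, sigma_mult))
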