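"""Pipeline configuration: defaults, YAML loading, strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .detection import ColorThresholds
from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Every tunable of the calibrate → transform → phenotype workflow.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default. The full effective
    config is echoed into every output artifact.
    """

    d_true: float = 200.0  # printed ring diameter, mm

    # color segmentation (HSV; red wraps the hue circle)
    hue_low_1: float = 0.0
    hue_high_1: float = 20.0
    hue_low_2: float = 340.0
    hue_high_2: float = 360.0
    sat_min: float = 0.4
    val_min: float = 0.2

    # clustering / ring selection
    eps: float | None = None  # None: 2x median NN distance of the red subset
    min_cluster: int = 100
    planarity_max: float = 0.05
    annularity_max: float = 0.25

    # RANSAC + least-squares circle fit
    n_iter: int = 2000
    inlier_tol: float | None = None  # None: 2% of the radius guess
    min_inlier_frac: float = 0.3
    seed: int = 0

    # optional statistical-outlier cleaning before detection
    clean: bool = True
    clean_k: int = 8
    clean_sigma: float = 2.0

    # world frame
    center_origin: bool = True  # ring center -> origin, ring plane -> z=0

    # trait extraction
    height_lo_pct: float = 0.5
    height_hi_pct: float = 99.5
    n_bins: int = 20
    grid_res: float = 2.0  # mm, occupancy grid of the main projection area
    voxel: float = 5.0     # mm, compactness / spatial occupancy voxels
    mesh_k: int = 12
    mesh_edge_factor: float = 6.0

    def thresholds(self) -> ColorThresholds:
        return ColorThresholds(
            self.hue_low_1, self.hue_high_1, self.hue_low_2, self.hue_high_2,
            self.sat_min, self.val_min,
        )

    def trait_params(self) -> dict:
        return {
            "height_lo_pct": self.height_lo_pct, "height_hi_pct": self.height_hi_pct,
            "n_bins": self.n_bins, "grid_res": self.grid_res, "voxel": self.voxel,
            "mesh_k": self.mesh_k, "mesh_edge_factor": self.mesh_edge_factor,
        }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
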