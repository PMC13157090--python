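"""Robustness sweep: factorial stress test of the calibration pipeline.

Four factors degrade ring detection in the field: coordinate noise
(reconstruction quality), arc occlusion (leaves covering the ring),
ring inclination (uneven ground), and chromatic jitter plus red clutter
(illumination and background complexity). The sweep generates a scene
per factor combination and replicate, runs the full pipeline, and
records success and error metrics per row — single-scene failures are
recorded, never fatal, so a whole grid always yields a complete table.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import product

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import RingCalError
from .pipeline import calibrate_scene
from .scenes import LABEL_RING, SceneSpec, make_scene

SWEEP_COLUMNS = [
    "noise_sigma", "occlusion_frac", "inclination_deg", "clutter", "jitter",
    "replicate", "seed", "success", "error_stage", "scale_rel_error",
    "normal_error_deg", "ring_selection_purity",
]

_CLUTTER_SPHERE = ({"kind": "sphere", "size": 80.0, "position": (400.0, 0.0, 80.0),
                    "n_points": 2000},)


def evaluate_scene(spec: SceneSpec, config: PipelineConfig | None = None) -> dict:
    """Run calibration on one generated scene; compare against truth."""
    cloud, truth = make_scene(spec)
    out = {"success": False, "error_stage": None, "scale_rel_error": None,
           "normal_error_deg": None, "ring_selection_purity": None}
    try:
        cal = calibrate_scene(cloud, config)
    except RingCalError as exc:
        out["error_stage"] = type(exc).__name__
        return out
    out["success"] = True
    out["scale_rel_error"] = abs(cal.transform.s - truth.expected_scale) / truth.expected_scale
    # recovered up-axis in scene coordinates vs the true ring normal
    up_scene = cal.transform.R @ np.array([0.0, 0.0, 1.0])
    cosang = abs(float(np.dot(up_scene, truth.ring_normal)))
    out["normal_error_deg"] = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    sel = cal.ring.indices  # input-cloud numbering, valid with cleaning on
    if len(sel):
        out["ring_selection_purity"] = float((truth.labels[sel] == LABEL_RING).mean())
    return out


def run_sweep(
    grid: dict,
    replicates: int = 5,
    base_seed: int = 0,
    base_spec: SceneSpec | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Full-factorial sweep over the robustness factors.

    ``grid`` maps any of ``noise_sigma``, ``occlusion_frac``,
    ``inclination_deg``, ``clutter`` (bool: add a red sphere),
    ``jitter`` (chromatic jitter scale multiplier) to level lists.
    Returns one row per scene; an empty grid yields a header-only table.
    """
    base = base_spec or SceneSpec()
    if not grid:  # no factors at all: nothing to run
        return pd.DataFrame(columns=SWEEP_COLUMNS)
    levels = {
        "noise_sigma": grid.get("noise_sigma", [base.noise_sigma]),
        "occlusion_frac": grid.get("occlusion_frac", [base.occlusion_frac]),
        "inclination_deg": grid.get("inclination_deg", [base.inclination_deg]),
        "clutter": grid.get("clutter", [bool(base.clutter)]),
        "jitter": grid.get("jitter", [1.0]),
    }
    if any(len(v) == 0 for v in levels.values()) or replicates <= 0:
        return pd.DataFrame(columns=SWEEP_COLUMNS)

    rows = []
    combos = list(product(*levels.values()))
    for combo_i, (noise, occ, incl, clut, jit) in enumerate(combos):
        for rep in range(replicates):
            seed = int(base_seed + 1000 * combo_i + rep)
            spec = replace(
                base,
                noise_sigma=float(noise),
                occlusion_frac=float(occ),
                inclination_deg=float(incl),
                clutter=_CLUTTER_SPHERE if clut else (),
                hue_jitter=base.hue_jitter * jit,
                sat_jitter=base.sat_jitter * jit,
                val_jitter=base.val_jitter * jit,
                seed=seed,
            )
            row = {
                "noise_sigma": noise, "occlusion_frac": occ,
                "inclination_deg": incl, "clutter": bool(clut), "jitter": jit,
                "replicate": rep, "seed": seed,
            }
            row.update(evaluate_scene(spec, config))
            rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
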