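"""End-to-end study drivers: template rendering, variability, prediction.

Each driver runs the full pipeline — blend a head, ray-cast the five
occlusion maps from the right eye, extract theta(phi), integrate the
projected solid angle — and is fully reproducible from (model, config,
seed).  Per-face boundary renders are cached on disk keyed by a content
hash of the mesh and rig parameters, so re-runs are cheap.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boundary import (BoundaryFunction, DEFAULT_N_BINS, extract_boundary,
                       percent_decrease, projected_solid_angle,
                       read_boundary_csv, write_boundary_csv)
from .camera import EyePose, SensorRig, build_rig
from .mesh import TriangleMesh
from .morphable import MorphableHeadModel, blend_face
from .optimize import error_summary
from .raycast import trace_occlusion
from .templates import (TemplateSet, boundary_sq_error, predict_signed_batch,
                        sample_coefficients)

__all__ = [
    "ExperimentConfig",
    "eye_rig",
    "trace_boundary",
    "template_coefficient_grid",
    "render_template_set",
    "run_variability_experiment",
    "run_prediction_experiment",
]

log = logging.getLogger("fieldray")


@dataclass
class ExperimentConfig:
    """Scale and bookkeeping knobs shared by the experiment drivers."""

    res: int = 1024
    n_bins: int = DEFAULT_N_BINS
    n_faces: int = 10_000
    seed: int = 0
    out_dir: Path | None = None
    eps_offset: float = 1e-4

    def __post_init__(self) -> None:
        if self.res < 2 or self.n_bins < 1 or self.n_faces < 1:
            raise ValueError("res, n_bins and n_faces must be positive")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def metadata(self) -> dict:
        return {
            "fieldray_version": __version__,
            "res": self.res,
            "n_bins": self.n_bins,
            "n_faces": self.n_faces,
            "seed": self.seed,
        }


def eye_rig(model: MorphableHeadModel, cfg: ExperimentConfig) -> SensorRig:
    """Five-camera rig at the model's right-eye anchor."""
    if model.eye_anchor is None:
        raise ValueError("model has no eye_anchor; set it in the manifest")
    pose = EyePose.from_anchor(model.eye_anchor, model.forward, model.up)
    return build_rig(pose, res=cfg.res, eps_offset=cfg.eps_offset)


def trace_boundary(
    mesh: TriangleMesh, rig: SensorRig, n_bins: int
) -> BoundaryFunction:
    """Ray-cast a head and extract its visual-field boundary."""
    return extract_boundary(trace_occlusion(mesh, rig), rig, n_bins)


def _mesh_key(mesh: TriangleMesh, rig: SensorRig, n_bins: int) -> str:
    h = hashlib.blake2b(digest_size=16)
    h.update(mesh.vertices.tobytes())
    h.update(mesh.faces.tobytes())
    h.update(rig.eye.origin.tobytes())
    h.update(rig.eye.basis().tobytes())
    h.update(np.float64([rig.res, rig.eps_offset, n_bins]).tobytes())
    return h.hexdigest()


def _cached_boundary(
    mesh: TriangleMesh, rig: SensorRig, n_bins: int, cache_dir: Path | None
) -> BoundaryFunction:
    if cache_dir is None:
        return trace_boundary(mesh, rig, n_bins)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{_mesh_key(mesh, rig, n_bins)}.csv"
    if path.exists():
        return read_boundary_csv(path)
    b = trace_boundary(mesh, rig, n_bins)
    write_boundary_csv(b, path)
    return b


def template_coefficient_grid(n_ids: int) -> np.ndarray:
    """(2 n_ids + 1, n_ids) coefficients: generic, then each parameter at ±1.

    Row 0 is all-zero; rows 1..n_ids set one parameter to +1 and rows
    n_ids+1..2 n_ids set it to -1, every other parameter staying zero —
    the face set whose boundaries form the template basis (201 faces for
    100 parameters).
    """
    grid = np.zeros((2 * n_ids + 1, n_ids))
    for i in range(n_ids):
        grid[1 + i, i] = 1.0
        grid[1 + n_ids + i, i] = -1.0
    return grid


def render_template_set(
    model: MorphableHeadModel, cfg: ExperimentConfig
) -> TemplateSet:
    """Trace the generic and every single-parameter ±1 head into templates."""
    rig = eye_rig(model, cfg)
    cache = cfg.out_dir / "cache" if cfg.out_dir else None
    grid = template_coefficient_grid(model.n_ids)
    boundaries = []
    for k, c in enumerate(grid):
        log.info("template face %d/%d", k + 1, len(grid))
        boundaries.append(
            _cached_boundary(blend_face(model, c), rig, cfg.n_bins, cache).theta
        )
    B = np.stack(boundaries)
    n = model.n_ids
    return TemplateSet(B[0], B[1 : 1 + n], B[1 + n :])


def run_variability_experiment(
    model: MorphableHeadModel, cfg: ExperimentConfig
) -> dict:
    """Percent decrease of the projected solid angle over random heads.

    Returns per-face percent decreases plus their min/mean/median/max; with
    ``cfg.out_dir`` set, writes ``variability.csv`` and ``variability.json``.
    """
    rig = eye_rig(model, cfg)
    coeffs = sample_coefficients(cfg.n_faces, model.n_ids, cfg.seed)
    cache = cfg.out_dir / "cache" if cfg.out_dir else None
    percents = np.empty(cfg.n_faces)
    for j, c in enumerate(coeffs):
        log.info("variability face %d/%d", j + 1, cfg.n_faces)
        b = _cached_boundary(blend_face(model, c), rig, cfg.n_bins, cache)
        percents[j] = percent_decrease(projected_solid_angle(b))
    out = {
        "percent_decrease": percents,
        "summary": error_summary(percents),
        "metadata": cfg.metadata(),
    }
    if cfg.out_dir:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"face": np.arange(cfg.n_faces), "percent_decrease": percents}
        ).to_csv(cfg.out_dir / "variability.csv", index=False)
        (cfg.out_dir / "variability.json").write_text(
            json.dumps({"summary": out["summary"], "metadata": out["metadata"]},
                       indent=1),
            encoding="utf-8",
        )
    return out


def run_prediction_experiment(
    model: MorphableHeadModel,
    cfg: ExperimentConfig,
    templates: TemplateSet | None = None,
) -> dict:
    """Squared error of linearly predicted vs traced boundaries.

    Uses the given (possibly optimized) template set, rendering one if
    none is supplied; reports per-face errors, their summary and the
    indices of the best / median / 95th-percentile / worst faces.
    """
    if templates is None:
        templates = render_template_set(model, cfg)
    rig = eye_rig(model, cfg)
    cache = cfg.out_dir / "cache" if cfg.out_dir else None
    coeffs = sample_coefficients(cfg.n_faces, model.n_ids, cfg.seed)
    preds = predict_signed_batch(templates, coeffs)
    errors = np.empty(cfg.n_faces)
    rendered = np.empty_like(preds)
    for j, c in enumerate(coeffs):
        log.info("prediction face %d/%d", j + 1, cfg.n_faces)
        rendered[j] = _cached_boundary(blend_face(model, c), rig,
                                       cfg.n_bins, cache).theta
        errors[j] = boundary_sq_error(preds[j], rendered[j])
    order = np.argsort(errors, kind="stable")
    key_faces = {
        "best": int(order[0]),
        "median": int(order[(len(order) - 1) // 2]),
        "p95": int(order[min(len(order) - 1, round(0.95 * (len(order) - 1)))]),
        "worst": int(order[-1]),
    }
    out = {
        "errors": errors,
        "summary": error_summary(errors),
        "key_faces": key_faces,
        "coefficients": coeffs,
        "predicted": preds,
        "rendered": rendered,
        "metadata": cfg.metadata(),
    }
    if cfg.out_dir:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"face": np.arange(cfg.n_faces), "sq_error": errors}).to_csv(
            cfg.out_dir / "prediction_errors.csv", index=False
        )
        (cfg.out_dir / "prediction.json").write_text(
            json.dumps({"summary": out["summary"], "key_faces": key_faces,
                        "metadata": out["metadata"]}, indent=1),
            encoding="utf-8",
        )
    return out
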