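"""Morphable head models: a generic mesh plus PCA morph targets.

A morphable model represents an identity space: every target mesh shares
the generic mesh's topology, and a novel head is synthesised by adding
coefficient-weighted vertex offsets (blendshapes),

    M_new = M_g + sum_i c_i * (M_i - M_g),

where ``c_i`` is the coefficient along the i-th identity direction.  The
model is linear in the coefficients; samplers conventionally restrict
``c_i`` to [-1, 1] but the synthesis itself accepts any real values.

Models are described on disk by a small YAML/JSON manifest::

    generic: generic.obj
    targets: [id000.obj, id001.obj, ...]
    eye_anchor: [x, y, z]        # optional, right-eye centre in mm
    forward: [0, 0, 1]           # optional gaze axis, default +z
    up: [0, 1, 0]                # optional head-up axis, default +y
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .mesh import MeshError, TriangleMesh, read_obj, write_obj

__all__ = [
    "MorphableHeadModel",
    "FaceCoefficients",
    "load_morph_model",
    "save_morph_model",
    "blend_face",
]


@dataclass
class FaceCoefficients:
    """Ordered identity coefficients, one per morph target."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.float64).ravel()
        if not np.isfinite(self.c).all():
            raise ValueError("coefficients must be finite")

    def __len__(self) -> int:
        return len(self.c)


@dataclass
class MorphableHeadModel:
    """Generic mesh plus ``n_ids`` morph targets of identical topology."""

    generic: TriangleMesh
    targets: list[TriangleMesh]
    eye_anchor: np.ndarray | None = None
    forward: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.generic.validate()
        for k, t in enumerate(self.targets):
            if not self.generic.same_topology(t):
                raise MeshError(
                    f"morph target {k} does not share the generic mesh's topology"
                )
        if self.eye_anchor is not None:
            self.eye_anchor = np.asarray(self.eye_anchor, dtype=np.float64).reshape(3)
        self.forward = np.asarray(self.forward, dtype=np.float64).reshape(3)
        self.up = np.asarray(self.up, dtype=np.float64).reshape(3)

    @property
    def n_ids(self) -> int:
        return len(self.targets)

    def coefficients(self, c: Sequence[float] | FaceCoefficients) -> FaceCoefficients:
        fc = c if isinstance(c, FaceCoefficients) else FaceCoefficients(np.asarray(c))
        if len(fc) != self.n_ids:
            raise ValueError(
                f"expected {self.n_ids} coefficients, got {len(fc)}"
            )
        return fc

    # offsets (n_ids, n_vertices, 3) are the blendshape basis; cached lazily
    def _offsets(self) -> np.ndarray:
        if "offsets" not in self.metadata:
            self.metadata["offsets"] = np.stack(
                [t.vertices - self.generic.vertices for t in self.targets]
            ) if self.targets else np.zeros((0,) + self.generic.vertices.shape)
        return self.metadata["offsets"]


def blend_face(
    model: MorphableHeadModel, coeffs: Sequence[float] | FaceCoefficients
) -> TriangleMesh:
    """Synthesise a head by blending morph-target offsets into the generic mesh.

    Vertices are ``M_g + sum_i c_i * (M_i - M_g)``; connectivity is that of
    the generic mesh, unchanged.
    """
    fc = model.coefficients(coeffs)
    verts = model.generic.vertices
    if model.n_ids:
        verts = verts + np.tensordot(fc.c, model._offsets(), axes=1)
    return TriangleMesh(verts, model.generic.faces.copy())


def _read_manifest(path: Path) -> dict:
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_morph_model(manifest: str | os.PathLike) -> MorphableHeadModel:
    """Load a morphable model from a YAML/JSON manifest of OBJ paths.

    Topology consistency across all targets is validated; a mismatch
    raises :class:`~fieldray.mesh.MeshError` naming the target index.
    """
    mpath = Path(manifest)
    doc = _read_manifest(mpath)
    base = mpath.parent
    generic = read_obj(base / doc["generic"])
    targets = [read_obj(base / p) for p in doc.get("targets", [])]
    return MorphableHeadModel(
        generic,
        targets,
        eye_anchor=doc.get("eye_anchor"),
        forward=doc.get("forward", (0.0, 0.0, 1.0)),
        up=doc.get("up", (0.0, 1.0, 0.0)),
    )


def save_morph_model(model: MorphableHeadModel, out_dir: str | os.PathLike) -> Path:
    """Write a model as OBJs plus a ``manifest.yaml``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_obj(model.generic, out / "generic.obj")
    names = []
    for k, t in enumerate(model.targets):
        name = f"id{k:03d}.obj"
        write_obj(t, out / name)
        names.append(name)
    doc: dict = {"generic": "generic.obj", "targets": names}
    if model.eye_anchor is not None:
        doc["eye_anchor"] = [float(v) for v in model.eye_anchor]
    doc["forward"] = [float(v) for v in model.forward]
    doc["up"] = [float(v) for v in model.up]
    mpath = out / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return mpath
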