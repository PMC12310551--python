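"""Synthetic morphable heads and analytic occluders for testing.

The synthetic head stands in for an external scanned face model: a convex
cranium (an icosphere) carrying three protruding features that matter for
the eye's field of view — a nose on the nasal side, a brow ridge above the
right eye and a cheek bulge below it.  Each morph target displaces exactly
one feature radially through a smooth cosine-falloff field, so head
geometry varies linearly with the coefficients and visual-field changes
stay localised in azimuth.  The right-eye anchor sits 1 mm proud of the
socket surface, outside every feature's support.

The cap and half-space occluders have closed-form visual fields
(theta(phi) = theta0 everywhere, and a half-open field, respectively) and
anchor the end-to-end accuracy tests of the tracing pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .camera import EyePose
from .mesh import TriangleMesh
from .morphable import MorphableHeadModel

__all__ = [
    "SyntheticHeadSpec",
    "make_synthetic_model",
    "make_cap_occluder",
    "make_halfspace_occluder",
]


@dataclass
class SyntheticHeadSpec:
    """Parameters of the procedural head.

    Feature fields are (low, high) millimetre ranges: the generic head
    carries the mid-range protrusion and the morph target the high one, so
    coefficients in [-1, 1] sweep the full range.
    """

    cranium_radius: float = 100.0
    nose_length: tuple[float, float] = (6.0, 20.0)
    brow_protrusion: tuple[float, float] = (3.0, 12.0)
    cheek_height: tuple[float, float] = (2.0, 10.0)
    n_ids: int = 3
    mesh_resolution: int = 4  # icosphere subdivision level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cranium_radius <= 0:
            raise ValueError("cranium_radius must be positive")
        for name in ("nose_length", "brow_protrusion", "cheek_height"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if self.n_ids < 1:
            raise ValueError("n_ids must be >= 1")
        if self.mesh_resolution < 2:
            raise ValueError("mesh_resolution must be >= 2")


# unit directions (head frame: +x subject's right, +y up, +z facing direction)
_EYE_DIR = np.array([0.38, 0.10, 0.92])
_FEATURES = {  # name -> (centre direction, angular width deg)
    "nose": (np.array([0.0, -0.05, 1.0]), 18.0),
    "brow": (np.array([0.30, 0.38, 0.87]), 14.0),
    "cheek": (np.array([0.42, -0.22, 0.88]), 14.0),
}
_FEATURE_RANGES = {"nose": "nose_length", "brow": "brow_protrusion",
                   "cheek": "cheek_height"}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bump(verts_unit: np.ndarray, center: np.ndarray, width_deg: float) -> np.ndarray:
    """Cosine-falloff weight per vertex: 1 at the centre, 0 outside width."""
    ang = np.degrees(np.arccos(np.clip(verts_unit @ _unit(center), -1.0, 1.0)))
    w = np.cos(0.5 * np.pi * np.minimum(ang / width_deg, 1.0)) ** 2
    w[ang >= width_deg] = 0.0
    return w


def make_synthetic_model(
    spec: SyntheticHeadSpec, return_masks: bool = False
) -> MorphableHeadModel:
    """Build a synthetic morphable head; fully deterministic given the seed.

    Target ``i`` displaces feature ``i mod 3`` (nose, brow, cheek in turn);
    beyond the first three, feature centres are jittered reproducibly so
    every target is distinct.  ``return_masks`` additionally stores, in
    ``model.metadata['feature_masks']``, the per-target boolean vertex
    masks of each feature's support region.
    """
    rng = np.random.default_rng(spec.seed)
    base = trimesh.creation.icosphere(
        subdivisions=spec.mesh_resolution, radius=1.0
    )
    unit_verts = np.asarray(base.vertices, dtype=np.float64)
    unit_verts /= np.linalg.norm(unit_verts, axis=1, keepdims=True)
    faces = np.asarray(base.faces, dtype=np.int64)
    R = spec.cranium_radius

    # generic head: cranium + mid-range protrusion of every feature
    radial = np.full(len(unit_verts), R)
    feat_names = list(_FEATURES)
    for name in feat_names:
        lo, hi = getattr(spec, _FEATURE_RANGES[name])
        center, width = _FEATURES[name]
        radial = radial + 0.5 * (lo + hi) * _bump(unit_verts, center, width)
    generic = TriangleMesh(unit_verts * radial[:, None], faces)

    targets = []
    masks = []
    for i in range(spec.n_ids):
        name = feat_names[i % len(feat_names)]
        center, width = _FEATURES[name]
        if i >= len(feat_names):  # keep extra targets distinct but local
            tilt = rng.normal(scale=0.05, size=3)
            center = _unit(_unit(center) + tilt)
            width = width * float(rng.uniform(0.8, 1.0))
        lo, hi = getattr(spec, _FEATURE_RANGES[name])
        w = _bump(unit_verts, center, width)
        delta = (hi - 0.5 * (lo + hi)) * w  # +1 coefficient reaches `hi`
        tv = generic.vertices + unit_verts * delta[:, None]
        if not np.isfinite(tv).all():
            raise ValueError("synthetic mesh self-check failed: non-finite vertex")
        targets.append(TriangleMesh(tv, faces))
        masks.append(w > 0)

    eye_dir = _unit(_EYE_DIR)
    anchor = (R + 1.0) * eye_dir  # 1 mm proud of the (feature-free) socket
    model = MorphableHeadModel(
        generic, targets, eye_anchor=anchor,
        forward=(0.0, 0.0, 1.0), up=(0.0, 1.0, 0.0),
    )
    if return_masks:
        model.metadata["feature_masks"] = masks
        model.metadata["feature_names"] = [
            feat_names[i % len(feat_names)] for i in range(spec.n_ids)
        ]
    return model


def _standard_pose() -> EyePose:
    return EyePose(
        origin=np.zeros(3),
        forward=np.array([0.0, 0.0, 1.0]),
        up=np.array([0.0, 1.0, 0.0]),
        temporal=np.array([1.0, 0.0, 0.0]),
    )


def make_cap_occluder(
    theta0: float, radius: float = 50.0, margin: float = 15.0, res: int = 256
) -> tuple[TriangleMesh, EyePose]:
    """Spherical zone occluding exactly the directions theta > theta0.

    The zone spans polar angles [theta0, 90 + margin] for all phi on the
    sphere of the given radius centred at the eye; its true boundary is
    theta(phi) = theta0 and its projected solid angle pi sin^2(theta0).
    """
    if not 0.0 < theta0 < 90.0:
        raise ValueError("theta0 must lie strictly between 0 and 90 degrees")
    n_phi = max(int(res), 16)
    n_rings = max(n_phi // 4, 8)
    thetas = np.radians(np.linspace(theta0, 90.0 + margin, n_rings))
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    verts = radius * np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    faces = []
    for a in range(n_rings - 1):
        r0 = a * n_phi
        r1 = (a + 1) * n_phi
        for b in range(n_phi):
            b2 = (b + 1) % n_phi
            faces.append((r0 + b, r1 + b, r1 + b2))
            faces.append((r0 + b, r1 + b2, r0 + b2))
    return TriangleMesh(verts, np.array(faces)), _standard_pose()


def make_halfspace_occluder(
    drop: float = 1e-3, extent: float = 1e6
) -> tuple[TriangleMesh, EyePose]:
    """Huge horizontal quad just below the eye.

    In the limit drop -> 0, extent -> infinity it occludes exactly the
    downward directions, leaving the upper half of the front hemisphere
    (projected solid angle pi/2).
    """
    if drop < 0:
        raise ValueError("drop must be >= 0")
    y = -drop
    verts = np.array(
        [[-extent, y, -extent], [extent, y, -extent],
         [extent, y, extent], [-extent, y, extent]]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(verts, faces), _standard_pose()
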