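"""Deterministic binary visibility by ray casting.

For a perfectly non-reflective head surrounded by a constant-radiance
source, the radiance image seen from the eye is exactly the binary
visibility function: a pixel is dark iff the ray from the eye through that
pixel hits the head mesh.  Casting one primary ray per pixel centre is
therefore the mathematical equivalent of physically-based rendering of
that scene, with no Monte Carlo noise.

Two intersection paths are provided — exhaustive per-triangle testing and
a median-split BVH — that execute the *same* watertight
ray/triangle test, so the accelerated result equals brute force exactly.
Any hit counts as occluded, including edge grazes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .camera import FACE_NAMES, SensorRig, face_directions
from .mesh import TriangleMesh

__all__ = [
    "OcclusionMapSet",
    "intersect_ray",
    "intersect_rays",
    "trace_occlusion",
    "build_bvh",
    "save_occlusion_maps",
    "load_occlusion_maps",
]

OPEN = np.uint8(0)
OCCLUDED = np.uint8(1)


@dataclass
class OcclusionMapSet:
    """Five binary per-pixel occlusion images, one per rig face.

    ``maps[k][i, j]`` is 1 (OCCLUDED) where the eye ray through pixel
    (i, j) of face k hits the head mesh, else 0 (OPEN).  Face order
    follows :data:`fieldray.camera.FACE_NAMES`.
    """

    maps: np.ndarray  # (5, res, res) uint8

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.uint8)
        if self.maps.ndim != 3 or self.maps.shape[0] != len(FACE_NAMES):
            raise ValueError("expected (5, res, res) map stack")
        if not np.isin(self.maps, (0, 1)).all():
            raise ValueError("occlusion maps must be strictly binary")

    @property
    def res(self) -> int:
        return self.maps.shape[1]


@njit(cache=True, inline="always")
def _ray_frame(dx, dy, dz):
    """Watertight-test ray constants: dominant axis permutation and shears."""
    ax, ay, az = abs(dx), abs(dy), abs(dz)
    if az >= ax and az >= ay:
        kz = 2
    elif ay >= ax:
        kz = 1
    else:
        kz = 0
    kx = kz + 1
    if kx == 3:
        kx = 0
    ky = kx + 1
    if ky == 3:
        ky = 0
    d = (dx, dy, dz)
    if d[kz] < 0.0:  # preserve winding by swapping the shear axes
        kx, ky = ky, kx
    sx = d[kx] / d[kz]
    sy = d[ky] / d[kz]
    sz = 1.0 / d[kz]
    return kx, ky, kz, sx, sy, sz


@njit(cache=True, inline="always")
def _tri_hit(ox, oy, oz, kx, ky, kz, sx, sy, sz, v0, v1, v2):
    """Watertight ray/triangle test (shear + 2D edge functions).

    Edge and vertex grazes hit: the three edge functions must merely share
    a sign, and a shared edge evaluates identically for both triangles, so
    a seam ray cannot slip between them.  Returns t > 0 or inf.
    """
    o = (ox, oy, oz)
    a0 = v0[kx] - o[kx]
    a1 = v0[ky] - o[ky]
    a2 = v0[kz] - o[kz]
    b0 = v1[kx] - o[kx]
    b1 = v1[ky] - o[ky]
    b2 = v1[kz] - o[kz]
    c0 = v2[kx] - o[kx]
    c1 = v2[ky] - o[ky]
    c2 = v2[kz] - o[kz]
    axs = a0 - sx * a2
    ays = a1 - sy * a2
    bxs = b0 - sx * b2
    bys = b1 - sy * b2
    cxs = c0 - sx * c2
    cys = c1 - sy * c2
    u = cxs * bys - cys * bxs
    v = axs * cys - ays * cxs
    w = bxs * ays - bys * axs
    if (u < 0.0 or v < 0.0 or w < 0.0) and (u > 0.0 or v > 0.0 or w > 0.0):
        return np.inf
    det = u + v + w
    if det == 0.0:
        return np.inf
    t_scaled = u * sz * a2 + v * sz * b2 + w * sz * c2
    t = t_scaled / det
    if t <= 0.0:
        return np.inf
    return t


@njit(cache=True)
def _brute_kernel(origins, dirs, tris, out):
    n_rays = origins.shape[0]
    n_tris = tris.shape[0]
    for r in range(n_rays):
        ox, oy, oz = origins[r, 0], origins[r, 1], origins[r, 2]
        kx, ky, kz, sx, sy, sz = _ray_frame(dirs[r, 0], dirs[r, 1], dirs[r, 2])
        best = np.inf
        for k in range(n_tris):
            t = _tri_hit(ox, oy, oz, kx, ky, kz, sx, sy, sz,
                         tris[k, 0], tris[k, 1], tris[k, 2])
            if t < best:
                best = t
        out[r] = best


@njit(cache=True)
def _bvh_kernel(origins, dirs, tris, nodes_min, nodes_max, node_left,
                node_right, node_start, node_count, tri_index, out):
    n_rays = origins.shape[0]
    stack = np.empty(128, dtype=np.int64)
    for r in range(n_rays):
        ox, oy, oz = origins[r, 0], origins[r, 1], origins[r, 2]
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        kx, ky, kz, sx, sy, sz = _ray_frame(dx, dy, dz)
        inx = 1.0 / dx if dx != 0.0 else np.inf
        iny = 1.0 / dy if dy != 0.0 else np.inf
        inz = 1.0 / dz if dz != 0.0 else np.inf
        best = np.inf
        top = 0
        stack[top] = 0
        top += 1
        while top > 0:
            top -= 1
            node = stack[top]
            # slab test (conservative: never rejects a true hit nearer than best)
            t0 = 0.0
            t1 = best
            ok = True
            for ax in range(3):
                o = origins[r, ax]
                inv = inx if ax == 0 else (iny if ax == 1 else inz)
                lo = (nodes_min[node, ax] - o) * inv
                hi = (nodes_max[node, ax] - o) * inv
                if lo > hi:
                    lo, hi = hi, lo
                if np.isnan(lo):  # 0 * inf: origin on slab boundary
                    lo = -np.inf
                if np.isnan(hi):
                    hi = np.inf
                if lo > t0:
                    t0 = lo
                if hi < t1:
                    t1 = hi
                if t0 > t1:
                    ok = False
                    break
            if not ok:
                continue
            if node_left[node] < 0:  # leaf
                s = node_start[node]
                for kk in range(node_count[node]):
                    k = tri_index[s + kk]
                    t = _tri_hit(ox, oy, oz, kx, ky, kz, sx, sy, sz,
                                 tris[k, 0], tris[k, 1], tris[k, 2])
                    if t < best:
                        best = t
            else:
                stack[top] = node_left[node]
                top += 1
                stack[top] = node_right[node]
                top += 1
        out[r] = best


class _BVH:
    """Median-split bounding volume hierarchy over triangle centroids."""

    __slots__ = ("nodes_min", "nodes_max", "left", "right", "start", "count",
                 "tri_index", "tris")

    def __init__(self, mesh: TriangleMesh, leaf_size: int = 4):
        tris = np.ascontiguousarray(mesh.triangles(), dtype=np.float64)
        n = len(tris)
        lo = tris.min(axis=1)
        hi = tris.max(axis=1)
        centroids = tris.mean(axis=1)
        order = np.arange(n, dtype=np.int64)

        nodes_min: list[np.ndarray] = []
        nodes_max: list[np.ndarray] = []
        left: list[int] = []
        right: list[int] = []
        start: list[int] = []
        count: list[int] = []

        def build(beg: int, end: int) -> int:
            idx = order[beg:end]
            node = len(left)
            nodes_min.append(lo[idx].min(axis=0))
            nodes_max.append(hi[idx].max(axis=0))
            left.append(-1)
            right.append(-1)
            start.append(beg)
            count.append(end - beg)
            if end - beg > leaf_size:
                c = centroids[idx]
                axis = int(np.argmax(c.max(axis=0) - c.min(axis=0)))
                mid = (end - beg) // 2
                part = np.argpartition(c[:, axis], mid)
                order[beg:end] = idx[part]
                l = build(beg, beg + mid)
                r = build(beg + mid, end)
                left[node] = l
                right[node] = r
            return node

        if n:
            import sys

            rec = sys.getrecursionlimit()
            sys.setrecursionlimit(max(rec, 10000))
            build(0, n)
            sys.setrecursionlimit(rec)
        else:  # degenerate: single empty leaf
            nodes_min.append(np.zeros(3))
            nodes_max.append(np.zeros(3))
            left.append(-1)
            right.append(-1)
            start.append(0)
            count.append(0)
        self.nodes_min = np.ascontiguousarray(nodes_min, dtype=np.float64)
        self.nodes_max = np.ascontiguousarray(nodes_max, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.start = np.asarray(start, dtype=np.int64)
        self.count = np.asarray(count, dtype=np.int64)
        self.tri_index = order
        self.tris = tris


_BVH_CACHE: dict[tuple, _BVH] = {}


def build_bvh(mesh: TriangleMesh) -> _BVH:
    """Build (or fetch a cached) BVH for a mesh, keyed by geometry content."""
    key = (mesh.n_vertices, mesh.n_faces,
           hash(mesh.vertices.tobytes()), hash(mesh.faces.tobytes()))
    bvh = _BVH_CACHE.get(key)
    if bvh is None:
        bvh = _BVH(mesh)
        if len(_BVH_CACHE) > 8:  # meshes are large; keep the cache small
            _BVH_CACHE.clear()
        _BVH_CACHE[key] = bvh
    return bvh


def intersect_rays(
    mesh: TriangleMesh,
    origins: np.ndarray,
    dirs: np.ndarray,
    method: str = "bvh",
) -> np.ndarray:
    """Nearest-hit distances for a batch of rays (inf where no hit).

    ``method`` is ``"bvh"`` (default) or ``"brute"``; both return bitwise
    identical distances by construction.
    """
    origins = np.ascontiguousarray(np.atleast_2d(origins), dtype=np.float64)
    dirs = np.asarray(np.atleast_2d(dirs), dtype=np.float64)
    norms = np.linalg.norm(dirs, axis=-1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("degenerate (zero) ray direction")
    dirs = np.ascontiguousarray(dirs / norms)
    if origins.shape[0] == 1 and dirs.shape[0] > 1:
        origins = np.broadcast_to(origins, dirs.shape).copy()
    out = np.empty(len(dirs), dtype=np.float64)
    if mesh.n_faces == 0:
        out.fill(np.inf)
        return out
    if method == "brute":
        tris = np.ascontiguousarray(mesh.triangles(), dtype=np.float64)
        _brute_kernel(origins, dirs, tris, out)
    elif method == "bvh":
        b = build_bvh(mesh)
        _bvh_kernel(origins, dirs, b.tris, b.nodes_min, b.nodes_max,
                    b.left, b.right, b.start, b.count, b.tri_index, out)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def intersect_ray(
    mesh: TriangleMesh, origin, direction, method: str = "bvh"
) -> float | None:
    """Smallest positive hit distance of one ray, or None if it misses."""
    t = intersect_rays(mesh, np.asarray(origin), np.asarray(direction),
                       method=method)[0]
    return None if np.isinf(t) else float(t)


def trace_occlusion(
    mesh: TriangleMesh, rig: SensorRig, method: str = "bvh"
) -> OcclusionMapSet:
    """Cast one ray per pixel centre of every rig face against the head mesh."""
    mesh.validate(require_faces=False)
    res = rig.res
    maps = np.empty((rig.n_faces, res, res), dtype=np.uint8)
    origin = rig.ray_origin[None, :]
    for k in range(rig.n_faces):
        dirs = face_directions(rig, k).reshape(-1, 3)
        t = intersect_rays(mesh, origin, dirs, method=method)
        maps[k] = np.isfinite(t).reshape(res, res).astype(np.uint8)
    return OcclusionMapSet(maps)


def save_occlusion_maps(maps: OcclusionMapSet, out_dir) -> list:
    """Write the five maps as binary (P5) PGM images, occluded pixels black."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, name in enumerate(FACE_NAMES):
        img = ((1 - maps.maps[k]) * 255).astype(np.uint8)
        p = out / f"occlusion_{k}_{name}.pgm"
        Image.fromarray(img, mode="L").save(p)
        paths.append(p)
    return paths


def load_occlusion_maps(in_dir) -> OcclusionMapSet:
    """Read back PGM maps written by :func:`save_occlusion_maps`."""
    from pathlib import Path

    from PIL import Image

    base = Path(in_dir)
    stack = []
    for k, name in enumerate(FACE_NAMES):
        img = np.asarray(Image.open(base / f"occlusion_{k}_{name}.pgm"))
        stack.append((img < 128).astype(np.uint8))
    return OcclusionMapSet(np.stack(stack))
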