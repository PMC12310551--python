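"""Triangle meshes and minimal Wavefront OBJ input/output.

Meshes are the geometric substrate of the whole pipeline: the head is a
triangle soup that occludes light on its way to the eye.  Coordinates are
millimetres throughout the package.

Only the ``v`` and ``f`` records of the OBJ dialect are interpreted;
normals, texture coordinates and materials are ignored.  Faces with more
than three vertices are fan-triangulated.  That is all the morphable-head
meshes this package consumes ever contain.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TriangleMesh", "MeshError", "ObjParseError", "read_obj", "write_obj"]


class MeshError(ValueError):
    """Invalid mesh (bad indices, non-finite coordinates, no faces)."""


class ObjParseError(MeshError):
    """Malformed OBJ record; the message names the offending line."""


@dataclass
class TriangleMesh:
    """Indexed triangle mesh.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array, millimetres.
    faces : (n_faces, 3) int array of 0-based vertex indices.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- validation -----------------------------------------------------
    def validate(self, require_faces: bool = True) -> "TriangleMesh":
        if not np.isfinite(self.vertices).all():
            raise MeshError("mesh has non-finite vertex coordinates")
        if require_faces and len(self.faces) == 0:
            raise MeshError("mesh has no faces; an occluder needs at least one")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError(
                f"face index out of range [0, {len(self.vertices)})"
            )
        return self

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def same_topology(self, other: "TriangleMesh") -> bool:
        """True when the two meshes share vertex count and face list."""
        return self.n_vertices == other.n_vertices and np.array_equal(
            self.faces, other.faces
        )

    def triangles(self) -> np.ndarray:
        """(n_faces, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]


def read_obj(path: str | os.PathLike) -> TriangleMesh:
    """Read an ASCII OBJ file into a :class:`TriangleMesh`.

    Recognises ``v`` and ``f`` records; ``vn``/``vt``/``usemtl`` and
    comments are silently ignored.  Face indices may be of the
    ``v``, ``v/vt``, ``v/vt/vn`` or ``v//vn`` forms; negative (relative)
    indices are resolved against the vertices read so far.  Polygons are
    fan-triangulated around their first vertex.
    """
    vertices: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise ObjParseError(f"line {lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append((float(parts[1]), float(parts[2]), float(parts[3])))
                except ValueError as exc:
                    raise ObjParseError(
                        f"line {lineno}: non-numeric vertex coordinate"
                    ) from exc
            elif tag == "f":
                if len(parts) < 4:
                    raise ObjParseError(f"line {lineno}: face needs >= 3 vertices")
                idx = []
                for token in parts[1:]:
                    head = token.split("/")[0]
                    try:
                        k = int(head)
                    except ValueError as exc:
                        raise ObjParseError(
                            f"line {lineno}: non-integer face index {head!r}"
                        ) from exc
                    if k > 0:
                        k -= 1  # OBJ is 1-based
                    elif k < 0:
                        k += len(vertices)  # relative to vertices so far
                    else:
                        raise ObjParseError(f"line {lineno}: face index 0 is invalid")
                    if not 0 <= k < len(vertices):
                        raise ObjParseError(
                            f"line {lineno}: face index {head} out of range"
                        )
                    idx.append(k)
                for a, b in zip(idx[1:-1], idx[2:]):  # fan around idx[0]
                    faces.append((idx[0], a, b))
            # anything else (vn, vt, usemtl, o, g, s, mtllib...) is ignored
    return TriangleMesh(np.array(vertices, dtype=np.float64).reshape(-1, 3),
                        np.array(faces, dtype=np.int64).reshape(-1, 3)).validate(
                            require_faces=False)


def write_obj(mesh: TriangleMesh, path: str | os.PathLike, precision: int = 8) -> None:
    """Write a mesh as a standard OBJ (1-based indices, deterministic order)."""
    mesh.validate(require_faces=True)
    fmt = f"v {{:.{precision}g}} {{:.{precision}g}} {{:.{precision}g}}\n"
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, z in mesh.vertices:
            fh.write(fmt.format(x, y, z))
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")
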