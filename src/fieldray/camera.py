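"""Eye-centred camera rig and angular conventions.

The visual field is parameterised in eye-centred polar coordinates:
``theta`` is measured away from the ray pointing directly in front of the
eye, and ``phi`` is the angle around that ray, counter-clockwise starting
from the temporal direction (horizontally away from the nose), so that
phi = 0 is temporal, 90 superior, 180 nasal and 270 inferior, as seen
looking outward along the gaze axis.

The front hemisphere (theta <= 90 deg) is sampled by five square pinhole
cameras with 90 deg field of view, the faces of a cube centred on the eye:
forward, up, down, temporal and nasal.  Together their frusta cover every
front-hemisphere direction exactly once up to shared edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyePose",
    "SensorRig",
    "FACE_NAMES",
    "build_rig",
    "pixel_to_direction",
    "direction_to_polar",
    "direction_to_pixel",
]

FACE_NAMES = ("forward", "up", "down", "temporal", "nasal")

_ORTHO_TOL = 1e-9


@dataclass
class EyePose:
    """Position and orientation of one eye.

    ``forward`` is the gaze axis (theta = 0), ``temporal`` points
    horizontally away from the nose (phi = 0) and ``up`` completes the
    right-handed-on-the-face frame with up at phi = 90.  The three axes
    must be mutually orthonormal to 1e-9.
    """

    origin: np.ndarray
    forward: np.ndarray
    up: np.ndarray
    temporal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.forward = np.asarray(self.forward, dtype=np.float64).reshape(3)
        self.up = np.asarray(self.up, dtype=np.float64).reshape(3)
        self.temporal = np.asarray(self.temporal, dtype=np.float64).reshape(3)
        M = np.stack([self.temporal, self.up, self.forward])
        if not np.allclose(M @ M.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("forward/up/temporal must be mutually orthonormal")

    @classmethod
    def from_anchor(
        cls,
        origin,
        forward=(0.0, 0.0, 1.0),
        up=(0.0, 1.0, 0.0),
        right_eye: bool = True,
    ) -> "EyePose":
        """Build a pose from gaze and head-up axes.

        For the right eye the temporal axis is ``up x forward`` (to the
        subject's right); for the left eye it is the negation.
        """
        f = np.asarray(forward, dtype=np.float64)
        f = f / np.linalg.norm(f)
        u = np.asarray(up, dtype=np.float64)
        u = u - f * (u @ f)
        u = u / np.linalg.norm(u)
        t = np.cross(u, f)
        if not right_eye:
            t = -t
        return cls(np.asarray(origin, dtype=np.float64), f, u, t)

    def basis(self) -> np.ndarray:
        """Rows are (temporal, up, forward): world -> eye-local rotation."""
        return np.stack([self.temporal, self.up, self.forward])


# Face frames in eye-local coordinates (x=temporal, y=up, z=forward).
# Each row: (face forward, image right, image up); image-plane mapping is
# dir = f + u*right + v*up with u, v in [-1, 1] (tan of the 45 deg half FOV).
_FACE_AXES = {
    "forward": ((0, 0, 1), (1, 0, 0), (0, 1, 0)),
    "up": ((0, 1, 0), (1, 0, 0), (0, 0, -1)),
    "down": ((0, -1, 0), (1, 0, 0), (0, 0, 1)),
    "temporal": ((1, 0, 0), (0, 0, -1), (0, 1, 0)),
    "nasal": ((-1, 0, 0), (0, 0, 1), (0, 1, 0)),
}


@dataclass
class SensorRig:
    """Five eye-centred 90 deg-FOV square cameras covering the front hemisphere."""

    eye: EyePose
    fov: float = 90.0
    res: int = 1024
    eps_offset: float = 1e-4  # mm; ray origin lift along forward
    # (5, 3, 3) world-frame face axes, rows (f, right, up) per face
    face_axes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.fov != 90.0:
            raise ValueError("hemisphere coverage requires fov = 90 deg")
        if self.res < 2:
            raise ValueError("res must be >= 2")
        B = self.eye.basis()  # local row i = world axis expressed... rows t,u,f
        axes = []
        for name in FACE_NAMES:
            f, r, u = (np.array(v, dtype=np.float64) for v in _FACE_AXES[name])
            # local (x,y,z) -> world via x*temporal + y*up + z*forward
            axes.append(np.stack([v @ B for v in (f, r, u)]))
        self.face_axes = np.stack(axes)

    @property
    def ray_origin(self) -> np.ndarray:
        return self.eye.origin + self.eps_offset * self.eye.forward

    @property
    def n_faces(self) -> int:
        return len(FACE_NAMES)


def build_rig(
    eye: EyePose, fov: float = 90.0, res: int = 1024, eps_offset: float = 1e-4
) -> SensorRig:
    """Construct the five-camera rig for an eye pose."""
    return SensorRig(eye=eye, fov=fov, res=res, eps_offset=eps_offset)


def _pixel_uv(res: int, i, j):
    """Image-plane coordinates of pixel centres; row 0 is the top of the image."""
    u = (np.asarray(j, dtype=np.float64) + 0.5) * 2.0 / res - 1.0
    v = 1.0 - (np.asarray(i, dtype=np.float64) + 0.5) * 2.0 / res
    return u, v


def pixel_to_direction(rig: SensorRig, face_id: int, i, j) -> np.ndarray:
    """Unit direction through the centre of pixel (i=row, j=col) of one face."""
    i = np.asarray(i)
    j = np.asarray(j)
    if (i < 0).any() or (i >= rig.res).any() or (j < 0).any() or (j >= rig.res).any():
        raise IndexError("pixel index out of range")
    f, r, u = rig.face_axes[face_id]
    uu, vv = _pixel_uv(rig.res, i, j)
    d = f + np.multiply.outer(uu, r) + np.multiply.outer(vv, u)
    return (d / np.linalg.norm(d, axis=-1, keepdims=True)).squeeze()


def face_directions(rig: SensorRig, face_id: int) -> np.ndarray:
    """(res, res, 3) unit directions through every pixel centre of a face."""
    idx = np.arange(rig.res)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    f, r, u = rig.face_axes[face_id]
    uu, vv = _pixel_uv(rig.res, ii, jj)
    d = f + uu[..., None] * r + vv[..., None] * u
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def direction_to_polar(eye: EyePose, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polar angles (theta, phi) in degrees of unit direction(s).

    theta in [0, 180] from the forward axis; phi in [0, 360) counter-
    clockwise from temporal with up at 90.  phi of the forward direction
    itself is 0 by convention.
    """
    d = np.asarray(dirs, dtype=np.float64)
    n = np.linalg.norm(d, axis=-1)
    if (n == 0).any():
        raise ValueError("zero direction vector")
    d = d / n[..., None]
    cz = np.clip(d @ eye.forward, -1.0, 1.0)
    theta = np.degrees(np.arccos(cz))
    phi = np.degrees(np.arctan2(d @ eye.up, d @ eye.temporal)) % 360.0
    phi = np.where(theta == 0.0, 0.0, phi)
    return theta, phi


def direction_to_pixel(rig: SensorRig, dirs: np.ndarray):
    """Map direction(s) to (face_id, i, j) of the containing face.

    The containing face is the one whose forward axis has the largest dot
    product with the direction; directions outside all five frusta (behind
    the eye) get face_id -1.
    """
    d = np.atleast_2d(np.asarray(dirs, dtype=np.float64))
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    dots = d @ rig.face_axes[:, 0, :].T  # (n, 5)
    face = np.argmax(dots, axis=1)
    best = dots[np.arange(len(d)), face]
    r = rig.face_axes[face, 1, :]
    u = rig.face_axes[face, 2, :]
    uu = np.einsum("nk,nk->n", d, r) / best
    vv = np.einsum("nk,nk->n", d, u) / best
    j = np.floor((uu + 1.0) * 0.5 * rig.res).astype(np.int64)
    i = np.floor((1.0 - vv) * 0.5 * rig.res).astype(np.int64)
    inside = (best > 0) & (np.abs(uu) <= 1.0 + 1e-12) & (np.abs(vv) <= 1.0 + 1e-12)
    j = np.clip(j, 0, rig.res - 1)
    i = np.clip(i, 0, rig.res - 1)
    face = np.where(inside, face, -1)
    if np.asarray(dirs).ndim == 1:
        return int(face[0]), int(i[0]), int(j[0])
    return face, i, j
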