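"""Visual-field boundary functions theta(phi) and solid-angle metrics.

The visual field of one eye is summarised as a boundary function: for each
of ``n_bins`` equally spaced azimuth bins (default 36,000 over 360 deg),
the polar extent theta of the visible region, in degrees from the forward
ray.  Boundary pixels are open pixels with at least one occluded
4-neighbour (the neighbourhood is resolved across shared cube-face edges);
each contributes its (theta, phi) and per-bin theta values are averaged.

The headline scalar is the projected solid angle

    Omega = integral over the VF of cos(theta) sin(theta) dtheta dphi
          = sum_k (pi / n_bins) * sin^2(theta_k),

which equals pi sr for an unobstructed hemisphere; the cosine weight
models aperture foreshortening of oblique light.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import (SensorRig, direction_to_pixel, direction_to_polar,
                     pixel_to_direction, _pixel_uv)
from .raycast import OcclusionMapSet

__all__ = [
    "BoundaryFunction",
    "DEFAULT_N_BINS",
    "extract_boundary",
    "projected_solid_angle",
    "projected_solid_angle_from_maps",
    "percent_decrease",
    "solid_angle_report",
    "read_boundary_csv",
    "write_boundary_csv",
]

DEFAULT_N_BINS = 36_000


@dataclass
class BoundaryFunction:
    """theta(phi) sampled on equally spaced phi bins, degrees.

    Bin k covers phi in [k, k+1) * 360 / n_bins with centre (k + 0.5)
    * 360 / n_bins.  theta values lie in [0, 90].
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64).ravel()
        if self.theta.size == 0:
            raise ValueError("boundary needs at least one bin")
        if not np.isfinite(self.theta).all():
            raise ValueError("boundary has non-finite theta")
        if (self.theta < 0).any() or (self.theta > 90).any():
            raise ValueError("theta must lie in [0, 90] degrees")

    @property
    def n_bins(self) -> int:
        return self.theta.size

    @property
    def phi_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * 360.0 / self.n_bins

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.theta, dtype=dtype)


def _as_theta(b) -> np.ndarray:
    return b.theta if isinstance(b, BoundaryFunction) else np.asarray(b, float)


def _padded_occlusion(maps: np.ndarray, rig: SensorRig) -> np.ndarray:
    """(5, res+2, res+2) maps with borders filled from neighbouring faces.

    A border cell takes the occlusion value of the pixel (possibly on
    another face) whose centre direction continues past the face edge;
    directions outside every frustum copy the nearest in-face pixel so
    the rig's back rim never spawns spurious boundary pixels.
    """
    res = rig.res
    padded = np.zeros((len(maps), res + 2, res + 2), dtype=np.uint8)
    padded[:, 1:-1, 1:-1] = maps
    idx = np.arange(res)
    for k in range(len(maps)):
        f, r, u = rig.face_axes[k]
        for ii, jj in ((np.full(res, -1), idx), (np.full(res, res), idx),
                       (idx, np.full(res, -1)), (idx, np.full(res, res))):
            uu, vv = _pixel_uv(res, ii, jj)
            dirs = f + uu[:, None] * r + vv[:, None] * u
            nf, ni, nj = direction_to_pixel(rig, dirs)
            vals = np.where(nf >= 0, maps[np.clip(nf, 0, None), ni, nj],
                            maps[k, np.clip(ii, 0, res - 1),
                                 np.clip(jj, 0, res - 1)])
            padded[k, ii + 1, jj + 1] = vals
    return padded


def _fill_empty_bins(theta: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Circular linear interpolation over empty phi bins."""
    n = theta.size
    if not filled.any():
        return np.full(n, 90.0)
    if filled.all():
        return theta
    x = np.flatnonzero(filled).astype(np.float64)
    y = theta[filled]
    # wrap one sample on each side for periodic interpolation
    xe = np.concatenate([[x[-1] - n], x, [x[0] + n]])
    ye = np.concatenate([[y[-1]], y, [y[0]]])
    out = theta.copy()
    empty = ~filled
    out[empty] = np.interp(np.flatnonzero(empty).astype(np.float64), xe, ye)
    return out


def extract_boundary(
    maps: OcclusionMapSet, rig: SensorRig, n_bins: int = DEFAULT_N_BINS
) -> BoundaryFunction:
    """Extract theta(phi) from binary occlusion maps.

    Boundary pixels sit on either side of the occlusion edge: open pixels
    with an occluded 4-neighbour and occluded pixels with an open
    4-neighbour (two-sided, so the half-pixel quantisation biases cancel
    to first order).  The neighbourhood is resolved across shared
    cube-face edges.  Pixels with theta > 90 deg (outside the front
    hemisphere) are discarded.  Bins that receive no boundary pixel are
    filled by circular linear interpolation; with no boundary pixels at
    all the field is fully open (theta = 90 everywhere).
    """
    m = maps.maps
    if m.shape[1] != rig.res:
        raise ValueError("occlusion maps do not match rig resolution")
    padded = _padded_occlusion(m, rig)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for k in range(len(m)):
        p = padded[k]
        any_occ = (p[:-2, 1:-1] | p[2:, 1:-1]
                   | p[1:-1, :-2] | p[1:-1, 2:]).astype(bool)
        q = 1 - p
        any_open = (q[:-2, 1:-1] | q[2:, 1:-1]
                    | q[1:-1, :-2] | q[1:-1, 2:]).astype(bool)
        bmask = ((m[k] == 0) & any_occ) | ((m[k] == 1) & any_open)
        if not bmask.any():
            continue
        ii, jj = np.nonzero(bmask)
        dirs = pixel_to_direction(rig, k, ii, jj).reshape(-1, 3)
        theta, phi = direction_to_polar(rig.eye, dirs)
        keep = theta <= 90.0
        theta, phi = theta[keep], phi[keep]
        bins = np.minimum((phi / 360.0 * n_bins).astype(np.int64), n_bins - 1)
        sums += np.bincount(bins, weights=theta, minlength=n_bins)
        counts += np.bincount(bins, minlength=n_bins)
    filled = counts > 0
    theta = np.zeros(n_bins)
    theta[filled] = sums[filled] / counts[filled]
    theta = np.clip(_fill_empty_bins(theta, filled), 0.0, 90.0)
    return BoundaryFunction(theta)


def projected_solid_angle(b: BoundaryFunction | np.ndarray) -> float:
    """Cosine-weighted solid angle of the field, steradians.

    Closed form of the per-bin integral: Omega = sum_k dphi * sin^2(theta_k)/2
    with dphi = 2 pi / n_bins.  Equals pi for theta = 90 everywhere.
    """
    theta = _as_theta(b)
    if (theta < 0).any() or (theta > 90).any():
        raise ValueError("theta must lie in [0, 90] degrees")
    return float(np.pi / theta.size * np.sum(np.sin(np.radians(theta)) ** 2))


def projected_solid_angle_from_maps(maps: OcclusionMapSet, rig: SensorRig) -> float:
    """Cosine-weighted solid angle integrated directly over open pixels.

    Bypasses the theta(phi) parameterisation entirely: each open pixel with
    theta <= 90 contributes cos(theta) times its pixel solid angle
    dA / r^3 (dA the image-plane cell, r the distance to the pixel centre
    on the unit-focal plane).  Robust where the boundary representation is
    degenerate, e.g. a field boundary passing through the forward pole;
    agrees with the boundary-based integral on star-convex fields.
    """
    if maps.res != rig.res:
        raise ValueError("occlusion maps do not match rig resolution")
    dA = (2.0 / rig.res) ** 2
    total = 0.0
    idx = np.arange(rig.res)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    for k in range(len(maps.maps)):
        f, r, u = rig.face_axes[k]
        uu, vv = _pixel_uv(rig.res, ii, jj)
        d = f + uu[..., None] * r + vv[..., None] * u
        rn = np.linalg.norm(d, axis=-1)
        cos_theta = (d @ rig.eye.forward) / rn
        w = np.maximum(cos_theta, 0.0) * dA / rn**3
        total += float(np.sum(w * (maps.maps[k] == 0)))
    return total


def percent_decrease(omega: float) -> float:
    """Percentage reduction of Omega relative to the hemisphere's pi sr."""
    if not -1e-9 <= omega <= np.pi + 1e-9:
        raise ValueError("omega must lie in [0, pi] sr")
    return 100.0 * (np.pi - omega) / np.pi


def solid_angle_report(b: BoundaryFunction | np.ndarray) -> dict:
    """{'omega_sr', 'percent_decrease'} for one boundary function."""
    omega = projected_solid_angle(b)
    return {"omega_sr": omega, "percent_decrease": percent_decrease(omega)}


def write_boundary_csv(b: BoundaryFunction, path: str | os.PathLike) -> None:
    """Two-column CSV ``phi_deg,theta_deg``, one row per bin."""
    pd.DataFrame({"phi_deg": b.phi_centers, "theta_deg": b.theta}).to_csv(
        path, index=False
    )


def read_boundary_csv(path: str | os.PathLike) -> BoundaryFunction:
    df = pd.read_csv(path)
    if not {"phi_deg", "theta_deg"} <= set(df.columns):
        raise ValueError("boundary CSV needs phi_deg and theta_deg columns")
    return BoundaryFunction(df["theta_deg"].to_numpy())
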