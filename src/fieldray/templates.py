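"""Linear prediction of visual-field boundaries from identity coefficients.

Rendering a boundary for every head is expensive; the linear model
replaces it with template arithmetic.  Given the generic boundary
theta_g(phi) and the boundaries theta_{+i}, theta_{-i} obtained with the
i-th identity coefficient at +1 / -1 (all others zero), a novel head with
coefficients c is predicted either symmetrically,

    theta(phi) = theta_g + sum_i c_i (theta_{+i} - theta_g),

or treating the two signs of each coefficient as separate parameters,

    theta(phi) = theta_g + sum_i |c_i| (theta_{sign(c_i), i} - theta_g),

the latter capturing asymmetric responses (a nose lengthened vs shortened
does not dent the field symmetrically).  Predictions are clipped to
[0, 90] degrees.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .boundary import BoundaryFunction

__all__ = [
    "TemplateSet",
    "predict_symmetric",
    "predict_signed",
    "sample_coefficients",
    "boundary_sq_error",
    "load_template_set",
    "save_template_set",
]


def _theta(b) -> np.ndarray:
    return b.theta if isinstance(b, BoundaryFunction) else np.asarray(b, np.float64)


@dataclass
class TemplateSet:
    """Boundary templates: generic plus per-parameter +1 / -1 boundaries.

    ``theta_g`` is (n_bins,); ``theta_plus`` and ``theta_minus`` are
    (n_ids, n_bins) stacks sharing the same binning.
    """

    theta_g: np.ndarray
    theta_plus: np.ndarray
    theta_minus: np.ndarray

    def __post_init__(self) -> None:
        self.theta_g = _theta(self.theta_g).ravel()
        self.theta_plus = np.atleast_2d(np.asarray(self.theta_plus, np.float64))
        self.theta_minus = np.atleast_2d(np.asarray(self.theta_minus, np.float64))
        n = self.theta_g.size
        if self.theta_plus.shape[1] != n or self.theta_minus.shape[1] != n:
            raise ValueError("templates disagree on n_bins")
        if self.theta_plus.shape[0] != self.theta_minus.shape[0]:
            raise ValueError("theta_plus and theta_minus disagree on n_ids")

    @property
    def n_ids(self) -> int:
        return self.theta_plus.shape[0]

    @property
    def n_bins(self) -> int:
        return self.theta_g.size

    def as_vector(self) -> np.ndarray:
        """(2 n_ids + 1, n_bins) stack ordered [generic, +templates, -templates]."""
        return np.vstack([self.theta_g[None, :], self.theta_plus, self.theta_minus])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "TemplateSet":
        n_ids = (x.shape[0] - 1) // 2
        return cls(x[0], x[1 : 1 + n_ids], x[1 + n_ids :])

    def _check_coeffs(self, c) -> np.ndarray:
        arr = np.asarray(getattr(c, "c", c), dtype=np.float64)
        if arr.shape[-1] != self.n_ids:
            raise ValueError(f"expected {self.n_ids} coefficients, got {arr.shape[-1]}")
        return arr


def predict_symmetric_batch(
    t: TemplateSet, coeffs: np.ndarray, clip: bool = True
) -> np.ndarray:
    """(n_faces, n_bins) symmetric predictions for a coefficient matrix."""
    C = np.atleast_2d(t._check_coeffs(coeffs))
    pred = t.theta_g + C @ (t.theta_plus - t.theta_g)
    return np.clip(pred, 0.0, 90.0) if clip else pred


def predict_signed_batch(
    t: TemplateSet, coeffs: np.ndarray, clip: bool = True
) -> np.ndarray:
    """(n_faces, n_bins) sign-split predictions; sign(0) contributes nothing."""
    C = np.atleast_2d(t._check_coeffs(coeffs))
    pred = (
        t.theta_g
        + np.maximum(C, 0.0) @ (t.theta_plus - t.theta_g)
        + np.maximum(-C, 0.0) @ (t.theta_minus - t.theta_g)
    )
    return np.clip(pred, 0.0, 90.0) if clip else pred


def predict_symmetric(t: TemplateSet, coeffs) -> BoundaryFunction:
    """Predict one boundary by the symmetric linear model."""
    return BoundaryFunction(predict_symmetric_batch(t, coeffs)[0])


def predict_signed(t: TemplateSet, coeffs) -> BoundaryFunction:
    """Predict one boundary with the +/- directions as separate parameters."""
    return BoundaryFunction(predict_signed_batch(t, coeffs)[0])


def sample_coefficients(n: int, n_ids: int, seed: int | None = 0) -> np.ndarray:
    """(n, n_ids) i.i.d. uniform(-1, 1) identity coefficients (PCG64 stream)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(n, n_ids))


def boundary_sq_error(a, b) -> float:
    """Sum over phi bins of squared theta differences, degrees squared."""
    ta, tb = _theta(a).ravel(), _theta(b).ravel()
    if ta.size != tb.size:
        raise ValueError("boundaries disagree on n_bins")
    return float(np.sum((ta - tb) ** 2))


def save_template_set(t: TemplateSet, out_dir: str | os.PathLike) -> Path:
    """Write templates as per-boundary CSVs plus an ``index.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {"n_ids": t.n_ids, "n_bins": t.n_bins, "generic": "generic.csv",
             "plus": [], "minus": []}
    phi = (np.arange(t.n_bins) + 0.5) * 360.0 / t.n_bins

    def _write(theta: np.ndarray, name: str) -> None:
        # raw write: optimized templates may legitimately stray outside [0, 90]
        pd.DataFrame({"phi_deg": phi, "theta_deg": theta}).to_csv(
            out / name, index=False
        )

    _write(t.theta_g, "generic.csv")
    for i in range(t.n_ids):
        for sign, stack in (("plus", t.theta_plus), ("minus", t.theta_minus)):
            name = f"id{i:03d}_{sign}.csv"
            _write(stack[i], name)
            index[sign].append(name)
    (out / "index.json").write_text(json.dumps(index, indent=1), encoding="utf-8")
    return out / "index.json"


def load_template_set(index_path: str | os.PathLike) -> TemplateSet:
    base = Path(index_path)
    if base.is_dir():
        base = base / "index.json"
    index = json.loads(base.read_text(encoding="utf-8"))
    root = base.parent

    def _read(name: str) -> np.ndarray:
        return pd.read_csv(root / name)["theta_deg"].to_numpy()

    g = _read(index["generic"])
    plus = np.stack([_read(p) for p in index["plus"]])
    minus = np.stack([_read(p) for p in index["minus"]])
    return TemplateSet(g, plus, minus)
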