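"""Template optimization against rendered boundaries.

Rendered boundary templates are pixel-discrete and therefore not smooth;
optimizing them jointly reduces the prediction error of the linear model
on random heads.  The objective is the weighted quadratic loss

    L = w_pred * sum_phi sum_j (theta_j^pred - theta_j^rendered)^2
      + w_anchor * sum_phi [ (theta_g^opt - theta_g^rend)^2
                             + sum_i sum_± (theta_±i^opt - theta_±i^rend)^2 ],

with default weights 0.75 / 0.25: the first term scores sign-split linear
predictions (unclipped, keeping L quadratic) for the training heads, the
anchor term keeps the optimized templates near their rendered values.
Optimization is plain full-batch gradient descent from the rendered
templates, stopped when the validation loss

    L_val = sum_phi sum_j (theta_j^pred - theta_j^rendered)^2

over the reserved heads stops improving.  Because L is a convex quadratic
in the template values and the phi bins decouple, the exact minimizer
solves one small linear system shared by all bins; that closed form is the
oracle the iterative path is verified against.

The scikit-learn estimator :class:`TemplateBoundaryPredictor` packages
prediction and optimization behind fit/predict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .templates import (
    TemplateSet,
    predict_signed_batch,
    predict_symmetric_batch,
)

__all__ = [
    "FitConfig",
    "LossReport",
    "training_loss",
    "validation_loss",
    "fit_templates",
    "closed_form_templates",
    "error_summary",
    "TemplateBoundaryPredictor",
]


@dataclass
class FitConfig:
    """Hyper-parameters of the template fit.

    ``n_total`` random heads are drawn, the first ``n_validation`` of the
    seeded sample being reserved for validation.  ``w_pred``/``w_anchor``
    must sum to one.  The default learning rate suits the full 10,000-head
    scale; small instances need a proportionally larger one.
    """

    n_total: int = 10_000
    n_validation: int = 100
    w_pred: float = 0.75
    w_anchor: float = 0.25
    lr: float = 5e-8
    patience: int = 10
    max_epochs: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.w_pred + self.w_anchor, 1.0):
            raise ValueError("w_pred + w_anchor must equal 1")
        if not 0 < self.n_validation < self.n_total:
            raise ValueError("need 0 < n_validation < n_total")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class LossReport:
    epoch: int
    training_loss: float
    validation_loss: float


class DivergenceError(RuntimeError):
    """Gradient descent produced a non-finite loss; use a smaller lr."""


def _design_matrix(coeffs: np.ndarray, n_ids: int) -> np.ndarray:
    """Rows a_j with pred_j = a_j @ [theta_g; theta_plus; theta_minus]."""
    C = np.atleast_2d(np.asarray(coeffs, dtype=np.float64))
    if C.shape[1] != n_ids:
        raise ValueError(f"expected {n_ids} coefficients per face")
    pos = np.maximum(C, 0.0)
    neg = np.maximum(-C, 0.0)
    g = 1.0 - np.abs(C).sum(axis=1)
    return np.hstack([g[:, None], pos, neg])


def _check_faces(rendered: TemplateSet, coeffs, boundaries):
    A = _design_matrix(coeffs, rendered.n_ids)
    Y = np.atleast_2d(np.asarray(boundaries, dtype=np.float64))
    if Y.shape != (A.shape[0], rendered.n_bins):
        raise ValueError(
            f"expected boundaries of shape {(A.shape[0], rendered.n_bins)}, "
            f"got {Y.shape}"
        )
    return A, Y


def training_loss(
    opt: TemplateSet,
    rendered: TemplateSet,
    coeffs,
    boundaries,
    cfg: FitConfig | None = None,
) -> float:
    """Weighted prediction-plus-anchor loss of a candidate template set."""
    cfg = cfg or FitConfig()
    if opt.n_bins != rendered.n_bins or opt.n_ids != rendered.n_ids:
        raise ValueError("optimized and rendered template sets disagree in shape")
    A, Y = _check_faces(rendered, coeffs, boundaries)
    X = opt.as_vector()
    resid = A @ X - Y
    anchor = X - rendered.as_vector()
    return float(cfg.w_pred * np.sum(resid**2) + cfg.w_anchor * np.sum(anchor**2))


def validation_loss(opt: TemplateSet, coeffs, boundaries) -> float:
    """Unweighted squared prediction error over the reserved heads."""
    A, Y = _check_faces(opt, coeffs, boundaries)
    return float(np.sum((A @ opt.as_vector() - Y) ** 2))


def closed_form_templates(
    rendered: TemplateSet, coeffs, boundaries, cfg: FitConfig | None = None
) -> TemplateSet:
    """Exact minimizer of the training loss via shared normal equations.

    The loss decouples over phi bins and every bin shares the same
    (2 n_ids + 1)-dimensional system ``(w_pred A'A + w_anchor I) X =
    w_pred A'Y + w_anchor X_rend``; with ``w_anchor > 0`` the system is
    positive definite.  A singular system (possible only at w_anchor = 0)
    is reported, never silently regularized.
    """
    cfg = cfg or FitConfig()
    A, Y = _check_faces(rendered, coeffs, boundaries)
    X_r = rendered.as_vector()
    m = X_r.shape[0]
    H = cfg.w_pred * (A.T @ A) + cfg.w_anchor * np.eye(m)
    rhs = cfg.w_pred * (A.T @ Y) + cfg.w_anchor * X_r
    if np.linalg.matrix_rank(H) < m:
        raise np.linalg.LinAlgError(
            "normal equations are singular (no anchor term and rank-deficient "
            "coefficient coverage)"
        )
    return TemplateSet.from_vector(np.linalg.solve(H, rhs))


def fit_templates(
    rendered: TemplateSet,
    coeffs,
    boundaries,
    val_coeffs,
    val_boundaries,
    cfg: FitConfig | None = None,
    init: TemplateSet | None = None,
) -> tuple[TemplateSet, list[LossReport]]:
    """Full-batch gradient descent on the training loss.

    Starts from the rendered templates (or ``init`` when given) and stops
    once the validation loss has not improved for ``cfg.patience`` epochs
    (or at ``max_epochs``); returns the template set with the best
    validation loss together with the per-epoch loss history.
    """
    cfg = cfg or FitConfig()
    A, Y = _check_faces(rendered, coeffs, boundaries)
    A_val, Y_val = _check_faces(rendered, val_coeffs, val_boundaries)
    X_r = rendered.as_vector()
    X = (init.as_vector() if init is not None else X_r).copy()
    if X.shape != X_r.shape:
        raise ValueError("init templates disagree with rendered in shape")
    AtA = A.T @ A
    AtY = A.T @ Y

    best_X = X.copy()
    best_val = np.inf
    stall = 0
    history: list[LossReport] = []
    for epoch in range(cfg.max_epochs):
        with np.errstate(over="ignore", invalid="ignore"):
            grad = (2.0 * cfg.w_pred * (AtA @ X - AtY)
                    + 2.0 * cfg.w_anchor * (X - X_r))
            X = X - cfg.lr * grad
            resid = A @ X - Y
            train = (cfg.w_pred * np.sum(resid**2)
                     + cfg.w_anchor * np.sum((X - X_r) ** 2))
            val = float(np.sum((A_val @ X - Y_val) ** 2))
        if not np.isfinite(train) or not np.isfinite(val):
            raise DivergenceError(
                "training loss became non-finite; decrease the learning rate"
            )
        history.append(LossReport(epoch, float(train), val))
        if not np.isfinite(best_val) or val < best_val - 1e-15 * max(best_val, 1.0):
            best_val = val
            best_X = X.copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return TemplateSet.from_vector(best_X), history


def error_summary(errors) -> dict:
    """min / mean / median / max of per-face errors."""
    e = np.asarray(errors, dtype=np.float64).ravel()
    if e.size == 0:
        raise ValueError("empty error list")
    return {
        "min": float(e.min()),
        "mean": float(e.mean()),
        "median": float(np.median(e)),
        "max": float(e.max()),
    }


class TemplateBoundaryPredictor(BaseEstimator, RegressorMixin):
    """Linear visual-field boundary model with optional template optimization.

    Parameters
    ----------
    templates : TemplateSet
        Rendered boundary templates; the prediction basis and the anchor
        of the optimization.
    mode : {'signed', 'symmetric'}
        'signed' treats the +/- direction of each coefficient as separate
        parameters; 'symmetric' uses the +1 templates only.
    optimize : {'gd', 'exact', None}
        How :meth:`fit` refines the templates against rendered boundaries:
        gradient descent, the closed-form solve, or not at all.
    w_pred, w_anchor : float
        Loss weights (must sum to 1).
    lr, patience, max_epochs, n_validation : gradient-descent controls;
        the first ``n_validation`` rows of (X, y) are reserved for early
        stopping.
    clip : bool
        Clip predictions to [0, 90] degrees.

    Attributes
    ----------
    templates_ : TemplateSet — optimized (or copied) templates after fit.
    history_ : list[LossReport] — per-epoch losses ('gd' only).
    n_iter_ : int — gradient-descent epochs run.
    """

    def __init__(
        self,
        templates: TemplateSet | None = None,
        mode: str = "signed",
        optimize: str | None = "gd",
        w_pred: float = 0.75,
        w_anchor: float = 0.25,
        lr: float = 5e-8,
        patience: int = 10,
        max_epochs: int = 100_000,
        n_validation: int = 100,
        clip: bool = True,
    ):
        self.templates = templates
        self.mode = mode
        self.optimize = optimize
        self.w_pred = w_pred
        self.w_anchor = w_anchor
        self.lr = lr
        self.patience = patience
        self.max_epochs = max_epochs
        self.n_validation = n_validation
        self.clip = clip

    def _config(self, n_total: int) -> FitConfig:
        return FitConfig(
            n_total=n_total,
            n_validation=self.n_validation,
            w_pred=self.w_pred,
            w_anchor=self.w_anchor,
            lr=self.lr,
            patience=self.patience,
            max_epochs=self.max_epochs,
        )

    def fit(self, X, y):
        """Refine the templates on coefficient rows X and rendered boundaries y."""
        if self.templates is None:
            raise ValueError("templates must be provided before fitting")
        if self.mode not in ("signed", "symmetric"):
            raise ValueError("mode must be 'signed' or 'symmetric'")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.atleast_2d(np.asarray(y, dtype=np.float64))
        self.history_ = []
        if self.optimize is None:
            self.templates_ = self.templates
            self.n_iter_ = 0
            return self
        cfg = self._config(n_total=len(X))
        nv = cfg.n_validation
        Xv, yv, Xt, yt = X[:nv], y[:nv], X[nv:], y[nv:]
        if self.optimize == "exact":
            self.templates_ = closed_form_templates(self.templates, Xt, yt, cfg)
            self.n_iter_ = 0
        elif self.optimize == "gd":
            self.templates_, self.history_ = fit_templates(
                self.templates, Xt, yt, Xv, yv, cfg
            )
            self.n_iter_ = len(self.history_)
        else:
            raise ValueError("optimize must be 'gd', 'exact' or None")
        return self

    def predict(self, X) -> np.ndarray:
        """(n_faces, n_bins) predicted boundaries for coefficient rows X."""
        t = getattr(self, "templates_", None) or self.templates
        if t is None:
            raise ValueError("no templates available; construct or fit first")
        fn = predict_signed_batch if self.mode == "signed" else predict_symmetric_batch
        return fn(t, X, clip=self.clip)

    def score(self, X, y) -> float:
        """Negative mean squared boundary error (higher is better)."""
        y = np.atleast_2d(np.asarray(y, dtype=np.float64))
        pred = self.predict(X)
        return -float(np.mean(np.sum((pred - y) ** 2, axis=1)))
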