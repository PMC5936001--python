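"""Per-observation influence diagnostics for logistic-type fits.

For a logistic model with fitted probabilities :math:`p_i` and an effective
design matrix X (intercept plus either the selected gene columns or the
latent scores, depending on the classifier), the hat matrix is

.. math:: H = V^{1/2} X (X^T V X)^{-1} X^T V^{1/2},

with V diagonal, :math:`v_i = p_i(1-p_i)`.  The standardized Pearson
residual and the one-step Cook's distance are

.. math::

    r_i = \\frac{y_i - \\hat p_i}{\\sqrt{p_i(1-p_i)}\\sqrt{1-h_{ii}}},
    \\qquad D_i = \\frac{r_i^2\\, h_{ii}}{1 - h_{ii}}.

Large :math:`D_i` flags observations that strongly perturb the fitted
values — the raw material for the rank-product consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InfluenceVector",
    "hat_diagonals",
    "standardized_pearson_residuals",
    "cooks_distance",
    "cooks_distance_for_model",
]

_EPS = 1e-10


@dataclass
class InfluenceVector:
    """Leverage, standardized residual and Cook's distance for one model."""

    sample_ids: list
    h: np.ndarray
    r: np.ndarray
    D: np.ndarray
    model_id: str = "model"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "model_id": self.model_id,
             "h": self.h, "r": self.r, "D": self.D}
        )


def _weighted_inverse_factor(design: np.ndarray, v: np.ndarray):
    """Return R such that (X^T V X)^{-1} = R R^T, via QR of V^{1/2} X.

    Rank-deficient weighted designs are ridge-stabilized with a warning
    naming the condition number.
    """
    Xw = design * np.sqrt(v)[:, None]
    _, Rf = np.linalg.qr(Xw, mode="reduced")
    diag = np.abs(np.diag(Rf))
    scale = diag.max() if diag.size else 0.0
    if scale == 0.0 or diag.min() < 1e-10 * scale:
        cond = np.inf if diag.min() == 0 else scale / diag.min()
        warnings.warn(
            f"weighted design is rank deficient (condition number ~{cond:.3g}); "
            "ridge-stabilizing the curvature",
            RuntimeWarning,
        )
        m = design.shape[1]
        ridge = (1e-8 * max(scale, 1.0)) ** 2
        G = Xw.T @ Xw + ridge * np.eye(m)
        Rf = np.linalg.cholesky(G).T
    return np.linalg.inv(Rf)


def hat_diagonals(
    design: np.ndarray,
    v: np.ndarray,
    design_eval: np.ndarray | None = None,
    v_eval: np.ndarray | None = None,
) -> np.ndarray:
    """Diagonal of the weighted hat matrix, without forming the n x n matrix.

    ``h_i = v_i * x_i^T (X^T V X)^{-1} x_i``.  When ``design_eval``/``v_eval``
    are given, the curvature comes from the (training) ``design``/``v`` but
    leverages are evaluated at the supplied rows — the rule used for
    observations held out of a resampled fit.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("weights v_i = p_i(1-p_i) must be positive")
    Rinv = _weighted_inverse_factor(design, v)
    if design_eval is None:
        design_eval, v_eval = design, v
    else:
        design_eval = np.atleast_2d(np.asarray(design_eval, dtype=float))
        v_eval = np.asarray(v_eval, dtype=float)
    B = design_eval @ Rinv
    h = v_eval * np.einsum("ij,ij->i", B, B)
    return np.clip(h, 0.0, None)


def standardized_pearson_residuals(
    y: np.ndarray, p_hat: np.ndarray, h: np.ndarray
) -> np.ndarray:
    """Pearson residuals standardized by leverage (see module formula)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p_hat, dtype=float), _EPS, 1 - _EPS)
    h = np.asarray(h, dtype=float)
    if np.any(h >= 1):
        raise ValueError("leverage h_ii >= 1: observation determines its own fit")
    return (y - p) / (np.sqrt(p * (1 - p)) * np.sqrt(1 - h))


def cooks_distance(y: np.ndarray, p_hat: np.ndarray, h: np.ndarray) -> np.ndarray:
    """One-step Cook's distance D_i = r_i^2 h_ii / (1 - h_ii)."""
    r = standardized_pearson_residuals(y, p_hat, h)
    h = np.asarray(h, dtype=float)
    return r * r * h / (1 - h)


def cooks_distance_for_model(
    fit, X: np.ndarray, y: np.ndarray, sample_ids=None, train_idx=None
) -> InfluenceVector:
    """Influence diagnostics for every observation under one fitted model.

    The model supplies its *effective design* (intercept + selected columns
    for the elastic-net refit, intercept + latent scores for the PLS
    classifiers) through ``fit.effective_design(X)`` and probabilities
    through ``fit.predict_proba(X)``.  When ``train_idx`` is given, the
    curvature (X^T V X)^{-1} is formed from the training rows only and
    held-out observations get leverages from their own x_i and v_i.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if sample_ids is None:
        sample_ids = list(range(n))
    design = fit.effective_design(X)
    p = np.clip(fit.predict_proba(X), _EPS, 1 - _EPS)
    v = p * (1 - p)
    if train_idx is None:
        h = hat_diagonals(design, v)
    else:
        train_idx = np.asarray(train_idx)
        h = hat_diagonals(design[train_idx], v[train_idx], design, v)
    # numerical guard: leverage is < 1 in exact arithmetic for any
    # observation that does not fully determine its own fitted value
    h = np.minimum(h, 1 - 1e-12)
    r = standardized_pearson_residuals(y, p, h)
    D = r * r * h / (1 - h)
    return InfluenceVector(
        sample_ids=list(sample_ids), h=h, r=r, D=D, model_id=getattr(fit, "model_id", "model")
    )
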