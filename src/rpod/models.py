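"""Sparse two-class classifiers for high-dimensional expression data.

Three complementary dimension-reduction strategies, mirroring common
practice for n << p transcriptomics classification:

``logit_en``
    Logistic regression with the elastic-net penalty
    ``lambda * [(1-alpha)/2 ||beta||_2^2 + alpha ||beta||_1]`` added to the
    (sum) negative log-likelihood; alpha=1 is the LASSO, alpha=0 ridge.
``splsda``
    Sparse partial least squares discriminant analysis: SPLS regression on
    the {0,1}-coded response builds L sparse latent scores, then an
    unpenalized logistic regression on the scores yields class
    probabilities.
``sgpls``
    Sparse generalized PLS: the logistic IRLS loop (weights
    v_i = p_i(1-p_i), working response z_i = eta_i + (y_i-p_i)/v_i) with
    sparse direction vectors extracted from M = X^T V z z^T V X at each
    iteration.

The SPLS direction vectors solve the l1-surrogate problem by
soft-thresholding the leading eigenvector of the current M and
renormalizing, with the threshold expressed as a fraction ``alpha`` of the
largest absolute loading (0 = dense PLS, -> 1 = single variable).

Columns are standardized internally; all reported coefficients are on the
original data scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Hyperparameters",
    "PLSFit",
    "ModelFit",
    "CVResult",
    "fit_logit_en",
    "fit_spls",
    "fit_splsda",
    "fit_sgpls",
    "fit_method",
    "cv_select",
    "predict_proba",
    "misclassifications",
]

_CLIP = 1e-10


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class Hyperparameters:
    method: str  # logit_en | splsda | sgpls
    alpha: float = 0.5      # EN mixing, or SPLS sparsity fraction
    lambda_: float = 1.0    # EN strength (logit_en only)
    n_latent: int = 1       # L, PLS variants only
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")


@dataclass
class PLSFit:
    """Internals of a (sparse) PLS decomposition on centered data."""

    W: np.ndarray          # (p, L) unit-norm direction vectors
    T: np.ndarray          # (n, L) scores
    P: np.ndarray          # (p, L) X loadings
    Q: np.ndarray          # (m, L) Y loadings
    R: np.ndarray          # (p, L) map: T = X_centered @ R
    coef: np.ndarray       # (p, m) regression coefficients, centered scale
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    active_sets: list = field(default_factory=list)
    irls_weights: np.ndarray | None = None   # SGPLS final v_i
    working_response: np.ndarray | None = None  # SGPLS final z_i

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xc @ self.R


@dataclass
class ModelFit:
    """A fitted classifier with everything influence scoring needs."""

    method: str
    hyperparameters: Hyperparameters
    beta: np.ndarray                 # (p,) original-scale coefficients
    intercept: float
    fitted_prob: np.ndarray
    selected: np.ndarray             # indices of nonzero / active genes
    n_features: int
    pls: PLSFit | None = None
    model_id: str = "model"
    converged: bool = True
    stage2_coef: np.ndarray | None = None     # PLS variants: [b0, gamma]
    refit_beta: np.ndarray | None = None      # logit_en unpenalized refit
    refit_intercept: float | None = None
    curvature_ridge: float = 0.0              # >0: penalized-curvature fallback

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability via the logistic function of x^T beta."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature mismatch: model has {self.n_features}, got {X.shape[1]}"
            )
        return _sigmoid(self.intercept + X @ self.beta)

    def influence_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities used for influence (unpenalized refit if available)."""
        if self.refit_beta is not None:
            X = np.asarray(X, dtype=float)
            return _sigmoid(self.refit_intercept + X @ self.refit_beta)
        if self.stage2_coef is not None:
            T = self.pls.transform(X)
            return _sigmoid(self.stage2_coef[0] + T @ self.stage2_coef[1:])
        return self.predict_proba(X)

    def effective_design(self, X: np.ndarray) -> np.ndarray:
        """Design matrix to which the hat-matrix formula applies.

        Elastic net: intercept + the selected columns (an unpenalized
        refit on that support backs the probabilities).  PLS variants:
        intercept + the L latent scores.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.pls is not None:
            return np.column_stack([np.ones(n), self.pls.transform(X)])
        if self.selected.size == 0:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n), X[:, self.selected]])


# --------------------------------------------------------------------------
# Elastic-net logistic regression
# --------------------------------------------------------------------------

def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def fit_logit_en(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambda_: float,
    max_iter: int = 2000,
    tol: float = 1e-7,
    standardize: bool = True,
    refit_influence: bool = True,
    model_id: str = "logit_en",
) -> ModelFit:
    """Elastic-net penalized logistic regression (intercept unpenalized).

    Minimizes sum of logistic deviances plus
    ``lambda * [(1-alpha)/2 ||beta||^2 + alpha ||beta||_1]`` on the
    standardized column scale; coefficients are returned on the original
    scale.  A single-class response or a negative penalty is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("response has a single class")
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    hp = Hyperparameters("logit_en", alpha=alpha, lambda_=lambda_,
                         max_iter=max_iter, tol=tol)
    Xs, mu, sd = _standardize(X) if standardize else (X, np.zeros(X.shape[1]), np.ones(X.shape[1]))

    if lambda_ == 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs",
                                 max_iter=max_iter, tol=tol)
    else:
        clf = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=alpha,
            C=1.0 / lambda_, max_iter=max_iter, tol=tol, random_state=0,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    beta_std = clf.coef_.ravel()
    beta = beta_std / sd
    intercept = float(clf.intercept_[0] - (beta_std * mu / sd).sum())
    selected = np.flatnonzero(beta_std != 0.0)
    if selected.size == 0:
        # exact optimum of the fully-shrunk model (saga crawls toward it)
        intercept = float(np.log(y.mean() / (1 - y.mean())))
    fit = ModelFit(
        method="logit_en", hyperparameters=hp, beta=beta, intercept=intercept,
        fitted_prob=np.clip(_sigmoid(intercept + X @ beta), _CLIP, 1 - _CLIP),
        selected=selected, n_features=X.shape[1], model_id=model_id,
        converged=clf.n_iter_[0] < max_iter,
    )
    if refit_influence:
        _attach_unpenalized_refit(fit, X, y)
    return fit


def _attach_unpenalized_refit(fit: ModelFit, X: np.ndarray, y: np.ndarray) -> None:
    """Unpenalized logistic refit on the selected support for influence.

    If the support is too large for n or the refit separates, fall back to
    the penalized fit's probabilities with a ridge-stabilized curvature
    (strength lambda*(1-alpha) on the standardized scale).
    """
    n = X.shape[0]
    sel = fit.selected
    hp = fit.hyperparameters
    if sel.size >= n - 1:
        fit.curvature_ridge = max(hp.lambda_ * (1 - hp.alpha), 1e-6)
        warnings.warn(
            "selected support >= n; using penalized curvature for influence",
            RuntimeWarning,
        )
        return
    if sel.size == 0:
        prev = y.mean()
        fit.refit_beta = np.zeros(X.shape[1])
        fit.refit_intercept = float(np.log(prev / (1 - prev))) if 0 < prev < 1 else 0.0
        return
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X[:, sel], y)
    coef = clf.coef_.ravel()
    p = _sigmoid(clf.intercept_[0] + X[:, sel] @ coef)
    separated = np.all((p > 0.5) == (y > 0.5)) and np.abs(coef).max() * np.abs(
        X[:, sel]
    ).max() > 50.0
    if separated:
        fit.curvature_ridge = max(hp.lambda_ * (1 - hp.alpha), 1e-6)
        warnings.warn(
            "separation in the unpenalized refit; using penalized curvature",
            RuntimeWarning,
        )
        return
    beta = np.zeros(X.shape[1])
    beta[sel] = coef
    fit.refit_beta = beta
    fit.refit_intercept = float(clf.intercept_[0])


# --------------------------------------------------------------------------
# Sparse PLS
# --------------------------------------------------------------------------

def _sparse_direction(A: np.ndarray, alpha_sparsity: float) -> np.ndarray:
    """Soft-thresholded leading eigenvector of M = A A^T, A = X^T Y (p, m).

    M is rank-m so the leading eigenvector is A v with v the top
    eigenvector of A^T A.  The threshold is ``alpha * max|w|``; if it
    removes every entry, the single largest-|w| variable is retained.
    """
    if A.ndim == 1:
        A = A[:, None]
    if A.shape[1] == 1:
        w = A[:, 0].copy()
    else:
        G = A.T @ A
        vals, vecs = np.linalg.eigh(G)
        w = A @ vecs[:, -1]
    amax = np.abs(w).max()
    if amax == 0.0:
        w = np.zeros_like(w)
        w[0] = 1.0
        return w
    thr = alpha_sparsity * amax
    w_t = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
    if not np.any(w_t):
        w_t = np.zeros_like(w)
        w_t[np.argmax(np.abs(w))] = np.sign(w[np.argmax(np.abs(w))])
    return w_t / np.linalg.norm(w_t)


def fit_spls(
    X: np.ndarray,
    Y: np.ndarray,
    L: int,
    alpha_sparsity: float,
    scale: bool = False,
) -> PLSFit:
    """Sparse PLS regression with X-deflation.

    Each of the L direction vectors is the unit-norm soft-thresholded
    leading eigenvector of the current M = X^T Y Y^T X; scores are
    T = X W (on the running deflated X), and regression coefficients come
    from the standard PLS identity  B = W (P^T W)^{-1} Q^T.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if L > min(n, p):
        raise ValueError(f"L={L} exceeds min(n, p)={min(n, p)}")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0) if scale else np.ones(p)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xc = (X - x_mean) / x_scale
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    Xd = Xc.copy()
    W = np.zeros((p, L))
    T = np.zeros((n, L))
    P = np.zeros((p, L))
    Q = np.zeros((Y.shape[1], L))
    active = []
    for l in range(L):
        A = Xd.T @ Yc
        w = _sparse_direction(A, alpha_sparsity)
        t = Xd @ w
        tt = t @ t
        if tt < 1e-14:
            # deflated X carries no signal along w; stop early
            W, T, P, Q = W[:, :l], T[:, :l], P[:, :l], Q[:, :l]
            break
        P[:, l] = Xd.T @ t / tt
        Q[:, l] = Yc.T @ t / tt
        W[:, l] = w
        T[:, l] = t
        active.append(np.flatnonzero(w))
        Xd = Xd - np.outer(t, P[:, l])
    L_eff = W.shape[1]
    if L_eff == 0:
        R = np.zeros((p, 0))
        coef = np.zeros((p, Y.shape[1]))
    else:
        R = W @ np.linalg.pinv(P.T @ W)
        coef = R @ Q.T
    return PLSFit(W=W, T=T, P=P, Q=Q, R=R, coef=coef, x_mean=x_mean,
                  x_scale=x_scale, y_mean=y_mean, active_sets=active)


def _stage2_logistic(T: np.ndarray, y: np.ndarray):
    """Unpenalized logistic fit on scores, ridge-stabilized on separation."""
    n = T.shape[0]
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(T, y)
    coef = clf.coef_.ravel()
    scale = np.abs(T).max(axis=0)
    if np.abs(coef * scale).max() > 50.0:
        warnings.warn(
            "separation in the score-space logistic fit; ridge-stabilized",
            RuntimeWarning,
        )
        clf = LogisticRegression(penalty="l2", C=float(n), solver="lbfgs",
                                 max_iter=1000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(T, y)
        coef = clf.coef_.ravel()
    return float(clf.intercept_[0]), coef


def fit_splsda(
    X: np.ndarray,
    y: np.ndarray,
    L: int,
    alpha_sparsity: float,
    scale: bool = False,
    model_id: str = "splsda",
) -> ModelFit:
    """SPLS-DA: SPLS on the dummy-coded response, then logistic on scores."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class")
    pls = fit_spls(X, y, L=L, alpha_sparsity=alpha_sparsity, scale=scale)
    b0, gamma = _stage2_logistic(pls.T, y)
    selected = (
        np.unique(np.concatenate(pls.active_sets)) if pls.active_sets else np.array([], int)
    )
    # logit = b0 + T gamma, T = (X - mu)/s @ R  =>  original-scale beta
    beta = (pls.R @ gamma) / pls.x_scale
    intercept = b0 - float(pls.x_mean @ beta)
    hp = Hyperparameters("splsda", alpha=alpha_sparsity, n_latent=L)
    return ModelFit(
        method="splsda", hyperparameters=hp, beta=beta, intercept=intercept,
        fitted_prob=np.clip(_sigmoid(b0 + pls.T @ gamma), _CLIP, 1 - _CLIP),
        selected=selected, n_features=X.shape[1], pls=pls, model_id=model_id,
        stage2_coef=np.concatenate([[b0], gamma]),
    )


def fit_sgpls(
    X: np.ndarray,
    y: np.ndarray,
    L: int,
    alpha_sparsity: float,
    max_iter: int = 50,
    tol: float = 1e-5,
    scale: bool = False,
    model_id: str = "sgpls",
) -> ModelFit:
    """Sparse generalized PLS via IRLS.

    Each iteration forms weights v_i = p_i(1-p_i) and working responses
    z_i, extracts L sparse directions from M = X^T V z z^T V X (rank one,
    so the leading eigenvector is proportional to X^T V z) with
    V-orthogonal deflation, solves the weighted least-squares problem of
    z on the scores, and updates the linear predictor.  Stops when
    max|delta beta| < tol or after max_iter iterations (then flagged
    non-converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class")
    n, p = X.shape
    if L > min(n, p):
        raise ValueError(f"L={L} exceeds min(n, p)={min(n, p)}")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0) if scale else np.ones(p)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xc = (X - x_mean) / x_scale

    prev_beta_c = np.zeros(p)
    b0 = float(np.log(y.mean() / (1 - y.mean())))
    eta = np.full(n, b0)
    converged = False
    pls = None
    gamma = np.zeros(L)
    for _ in range(max_iter):
        prob = np.clip(_sigmoid(eta), _CLIP, 1 - _CLIP)
        v = prob * (1 - prob)
        z = eta + (y - prob) / v
        # weighted centering of the working response problem
        vw = v / v.sum()
        z_off = float(vw @ z)
        zc = z - z_off
        Xd = Xc.copy()
        zd = zc.copy()
        W = np.zeros((p, L))
        T = np.zeros((n, L))
        P = np.zeros((p, L))
        active = []
        for l in range(L):
            w = _sparse_direction(Xd.T @ (v * zd), alpha_sparsity)
            t = Xd @ w
            tvt = t @ (v * t)
            if tvt < 1e-14:
                W, T, P = W[:, :l], T[:, :l], P[:, :l]
                break
            P[:, l] = Xd.T @ (v * t) / tvt
            W[:, l] = w
            T[:, l] = t
            active.append(np.flatnonzero(w))
            zd = zd - t * (t @ (v * zd) / tvt)
            Xd = Xd - np.outer(t, P[:, l])
        L_eff = W.shape[1]
        # weighted LS of z on [1, T]
        Dm = np.column_stack([np.ones(n), T[:, :L_eff]])
        sw = np.sqrt(v)
        sol, *_ = np.linalg.lstsq(Dm * sw[:, None], z * sw, rcond=None)
        b0, gamma = float(sol[0]), sol[1:]
        R = W[:, :L_eff] @ np.linalg.pinv(P[:, :L_eff].T @ W[:, :L_eff])
        # half-step damping: plain alternation between direction extraction
        # and the weighted LS can 2-cycle; averaging restores convergence
        beta_c = 0.5 * (R @ gamma) + 0.5 * prev_beta_c
        eta = np.clip(b0 + Xc @ beta_c, -30, 30)
        if np.max(np.abs(beta_c - prev_beta_c)) < tol:
            converged = True
            prev_beta_c = beta_c
            break
        prev_beta_c = beta_c
    prob = np.clip(_sigmoid(b0 + Xc @ prev_beta_c), _CLIP, 1 - _CLIP)
    v = prob * (1 - prob)
    z = np.clip(b0 + Xc @ prev_beta_c, -30, 30) + (y - prob) / v
    pls = PLSFit(
        W=W, T=T, P=P, Q=np.zeros((1, W.shape[1])), R=R,
        coef=prev_beta_c[:, None], x_mean=x_mean, x_scale=x_scale,
        y_mean=np.array([y.mean()]), active_sets=active,
        irls_weights=v, working_response=z,
    )
    if not converged:
        warnings.warn("SGPLS IRLS did not converge; returning last iterate",
                      RuntimeWarning)
    beta = prev_beta_c / x_scale
    intercept = b0 - float(x_mean @ beta)
    selected = np.unique(np.concatenate(active)) if active else np.array([], int)
    hp = Hyperparameters("sgpls", alpha=alpha_sparsity, n_latent=L,
                         max_iter=max_iter, tol=tol)
    return ModelFit(
        method="sgpls", hyperparameters=hp, beta=beta, intercept=intercept,
        fitted_prob=prob, selected=selected, n_features=p, pls=pls,
        model_id=model_id, converged=converged,
        stage2_coef=np.concatenate([[b0], gamma]),
    )


def fit_method(X, y, hp: Hyperparameters, model_id: str | None = None) -> ModelFit:
    """Dispatch on hp.method with the matching fitter."""
    mid = model_id or hp.method
    if hp.method == "logit_en":
        return fit_logit_en(X, y, alpha=hp.alpha, lambda_=hp.lambda_,
                            max_iter=max(hp.max_iter, 1000), tol=min(hp.tol, 1e-6),
                            model_id=mid)
    if hp.method == "splsda":
        return fit_splsda(X, y, L=hp.n_latent, alpha_sparsity=hp.alpha, model_id=mid)
    if hp.method == "sgpls":
        return fit_sgpls(X, y, L=hp.n_latent, alpha_sparsity=hp.alpha,
                         max_iter=hp.max_iter, tol=hp.tol, model_id=mid)
    raise ValueError(f"unknown method {hp.method!r}")


# --------------------------------------------------------------------------
# Cross-validated model selection
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    grid: list                     # list of (Hyperparameters, mean MSE)
    best: Hyperparameters
    best_mse: float
    fold_assignments: np.ndarray
    seed: int


def default_lambda_grid(X, y, alpha: float, n_points: int = 50, decades: float = 4.0):
    """Log-spaced penalty grid from lambda_max (all-zero solution) downward."""
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    resid = y - y.mean()
    lmax = np.abs(Xs.T @ resid).max() / max(alpha, 1e-3)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n_points)


def cv_select(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    alpha_grid: Sequence[float],
    L_grid: Sequence[int] = (1,),
    lambda_grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    max_redraws: int = 20,
) -> CVResult:
    """Grid search by stratified K-fold CV on held-out MSE = mean (y - p)^2.

    Ties are broken toward the smaller L, then the larger alpha.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(alpha_grid) == 0:
        raise ValueError("empty alpha grid")
    n = len(y)

    rng_seed = seed
    for attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        splits = list(skf.split(X, y))
        ok = all(len(np.unique(y[tr])) == 2 for tr, _ in splits)
        if ok:
            break
        warnings.warn("a CV fold lost a class; re-drawing folds", RuntimeWarning)
        rng_seed += 1
    else:
        raise ValueError("could not build class-complete CV folds")

    fold_assign = np.empty(n, dtype=int)
    for f, (_, te) in enumerate(splits):
        fold_assign[te] = f

    if method == "logit_en":
        grid_points = []
        for a in alpha_grid:
            lgrid = lambda_grid if lambda_grid is not None else default_lambda_grid(X, y, a, n_points=20)
            for lam in lgrid:
                grid_points.append(Hyperparameters("logit_en", alpha=a, lambda_=float(lam)))
    else:
        grid_points = [
            Hyperparameters(method, alpha=a, n_latent=int(L))
            for a in alpha_grid for L in L_grid
        ]

    results = []
    for hp in grid_points:
        errs = []
        for tr, te in splits:
            fit = fit_method(X[tr], y[tr], hp)
            p = np.clip(fit.predict_proba(X[te]), 0.0, 1.0)
            errs.append(np.mean((y[te] - p) ** 2))
        results.append((hp, float(np.mean(errs))))

    # argmin with ties -> smaller L, then larger alpha
    best_hp, best_mse = min(
        results, key=lambda t: (round(t[1], 12), t[0].n_latent, -t[0].alpha)
    )
    return CVResult(grid=results, best=best_hp, best_mse=best_mse,
                    fold_assignments=fold_assign, seed=seed)


def predict_proba(fit: ModelFit, X_new: np.ndarray) -> np.ndarray:
    return fit.predict_proba(X_new)


def misclassifications(fit: ModelFit, X: np.ndarray, y: np.ndarray,
                       threshold: float = 0.5) -> int:
    """Count of observations whose thresholded probability misses y."""
    p = fit.predict_proba(X)
    return int(np.sum((p > threshold).astype(int) != np.asarray(y).astype(int)))
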