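"""NIPALS partial least squares regression (single response).

This is the computational engine behind the adulteration-rate models,
the VIP importance scores and the coefficient weights used by CARS.
The single-response NIPALS recursion is deterministic: each component's
weight vector is the (normalised) covariance direction ``X'y`` of the
deflated data, so no iteration or random initialisation is involved.

Model form, with column-centred ``X`` and centred ``y``::

    w_a = X_a' y_a / ||X_a' y_a||      (weights)
    t_a = X_a w_a                      (scores)
    p_a = X_a' t_a / (t_a' t_a)        (X loadings)
    q_a = y_a' t_a / (t_a' t_a)        (y loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a

and the regression vector ``B = W (P'W)^{-1} q`` with the intercept
implied by centring.  Scores of distinct components are mutually
orthogonal; with as many components as the rank of the centred problem
the fit coincides with minimum-norm ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .exceptions import FitError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class PLSModel:
    """A fitted single-response PLS decomposition."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # (p, A) weights, unit columns
    P: np.ndarray  # (p, A) X loadings
    q: np.ndarray  # (A,) y loadings
    T: np.ndarray  # (n, A) scores, kept for diagnostics
    B: np.ndarray  # (p,) regression vector

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector using the leading ``n_components`` components."""
        a = self.n_components if n_components is None else int(n_components)
        if not 1 <= a <= self.n_components:
            raise ParameterError(
                f"n_components must lie in [1, {self.n_components}], got {a}"
            )
        Wa, Pa, qa = self.W[:, :a], self.P[:, :a], self.q[:a]
        # P'W is a small well-conditioned A x A system; solve, never invert
        return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit mean-centred NIPALS PLS1 with ``n_components`` latent variables.

    If the data run out of rank before ``n_components`` components the
    achieved number is used and a warning logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2 or y.size != n:
        raise ParameterError(f"need n >= 2 samples with matching y (n={n})")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ParameterError(
            f"n_components must lie in [1, min(n-1, p)] = "
            f"[1, {min(n - 1, p)}], got {n_components}"
        )
    if np.ptp(y) == 0:
        raise FitError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = X - x_mean
    ya = y - y_mean
    scale = np.linalg.norm(Xa.T @ ya)

    W, P, T, q = [], [], [], []
    for a in range(n_components):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(scale, 1.0):
            logger.warning("rank exhausted after %d components (requested %d)",
                           a, n_components)
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            logger.warning("degenerate score at component %d; stopping", a + 1)
            break
        p_a = Xa.T @ t / tt
        q_a = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p_a)
        ya = ya - q_a * t
        W.append(w)
        P.append(p_a)
        T.append(t)
        q.append(q_a)

    if not W:
        raise FitError("no PLS component could be extracted")
    model = PLSModel(
        n_components=len(W),
        x_mean=x_mean,
        y_mean=y_mean,
        W=np.column_stack(W),
        P=np.column_stack(P),
        q=np.array(q),
        T=np.column_stack(T),
        B=np.empty(p),
    )
    model.B = model.coefficients()
    return model


def pls_predict(model: PLSModel, X_new: np.ndarray,
                n_components: int | None = None) -> np.ndarray:
    """Predict: ``(X_new - x_mean) @ B + y_mean``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ParameterError(
            f"X_new has {X_new.shape[1]} columns; model was trained on "
            f"{model.x_mean.size}"
        )
    B = model.B if n_components is None else model.coefficients(n_components)
    return (X_new - model.x_mean) @ B + model.y_mean


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection for every predictor.

    ``VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )``
    with ``SS_a = q_a^2 t_a't_a`` the response variance captured by
    component ``a``.  The squared scores average to 1 over predictors.
    """
    p = model.W.shape[0]
    ss = model.q ** 2 * np.einsum("ij,ij->j", model.T, model.T)
    wnorm2 = np.einsum("ij,ij->j", model.W, model.W)
    contrib = (model.W ** 2 / wnorm2) @ ss
    total = ss.sum()
    if total <= 0:
        raise FitError("model captured no response variance; VIP undefined")
    return np.sqrt(p * contrib / total)


def choose_components(X: np.ndarray, y: np.ndarray, max_components: int = 15,
                      folds: int = 10, seed: int = 0) -> int:
    """Pick the latent-variable count minimising 10-fold RMSECV.

    One model with ``max_components`` components is fitted per fold and
    truncated to every smaller count, so the scan costs one fit per
    fold.  Ties (within 1e-12) break toward the smaller count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if folds > n or folds < 2:
        raise ParameterError(f"folds must lie in [2, n={n}], got {folds}")
    max_a = min(max_components, X.shape[1], n - n // folds - 1)
    if max_a < 1:
        raise ParameterError("no feasible component count")
    sse = np.zeros(max_a)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        model = pls_fit(X[train], y[train], min(max_a, len(train) - 1))
        for a in range(1, max_a + 1):
            a_eff = min(a, model.n_components)
            pred = pls_predict(model, X[test], n_components=a_eff)
            sse[a - 1] += float(np.sum((y[test] - pred) ** 2))
    rmsecv = np.sqrt(sse / n)
    best = float(rmsecv.min())
    return int(np.flatnonzero(rmsecv <= best + 1e-12)[0]) + 1
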