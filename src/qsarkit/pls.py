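"""Partial least squares (PLS1) regression and leave-one-out utilities.

A single PLS implementation is shared by the hologram and field-based 3D
arms of the pipeline.  It is the classical NIPALS / orthogonal-scores PLS1
algorithm: at each step the X-weight vector is the covariance direction
``w_k = X_k' y_k / ||X_k' y_k||``, scores ``t_k = X_k w_k``, loadings
``p_k = X_k' t_k / t_k' t_k`` and ``q_k = y_k' t_k / t_k' t_k``, after which
both blocks are deflated.  Because components are extracted sequentially the
fitted model is *nested*: predictions using the first ``k`` components are
available for every ``k`` up to ``n_components`` from one fit, which is what
makes leave-one-out component selection affordable.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class PLS1Regression(RegressorMixin, BaseEstimator):
    """PLS regression for a single response, via NIPALS.

    Parameters
    ----------
    n_components : int
        Number of latent components to extract.  Silently capped at
        ``min(n_samples - 1, n_features)`` and at the effective rank of X
        (extraction stops when a residual block is numerically zero).

    Attributes
    ----------
    x_mean_, y_mean_ : centering constants.
    x_weights_, x_loadings_ : (p, k) arrays W and P.
    y_loadings_ : (k,) array q.
    coef_ : (p,) regression coefficients on the original (centered) scale
        using all extracted components.
    n_components_ : number of components actually extracted.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        k_max = max(1, min(self.n_components, n - 1, p))
        W, P, Q = [], [], []
        eps = np.finfo(float).eps
        x_scale = np.linalg.norm(Xc) + eps
        for _ in range(k_max):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw < eps * 1e3 or np.linalg.norm(yc) < eps * 1e3:
                break
            w /= nw
            t = Xc @ w
            tt = t @ t
            if tt < (eps * x_scale) ** 2:
                break
            p_load = Xc.T @ t / tt
            q_load = yc @ t / tt
            Xc = Xc - np.outer(t, p_load)
            yc = yc - t * q_load
            W.append(w)
            P.append(p_load)
            Q.append(q_load)
        if not W:
            # degenerate: constant y or zero X -> mean-only model
            self.x_weights_ = np.zeros((p, 0))
            self.x_loadings_ = np.zeros((p, 0))
            self.y_loadings_ = np.zeros(0)
            self.coef_ = np.zeros(p)
            self.n_components_ = 0
            return self
        W = np.column_stack(W)
        P = np.column_stack(P)
        Q = np.asarray(Q)
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = Q
        # B = W (P'W)^-1 q ; P'W is upper triangular with unit diagonal
        self.coef_ = W @ np.linalg.solve(P.T @ W, Q)
        self.n_components_ = W.shape[1]
        return self

    def _coef_k(self, k: int) -> np.ndarray:
        """Regression coefficients using only the first k components."""
        if k <= 0 or self.n_components_ == 0:
            return np.zeros(self.x_weights_.shape[0])
        k = min(k, self.n_components_)
        W = self.x_weights_[:, :k]
        P = self.x_loadings_[:, :k]
        q = self.y_loadings_[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X, n_components: int | None = None):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        coef = self.coef_ if n_components is None else self._coef_k(n_components)
        return (X - self.x_mean_) @ coef + self.y_mean_

    def predict_components(self, X) -> np.ndarray:
        """Predictions for every component count 1..n_components_.

        Returns an (n_samples, n_components_) array whose column k-1 holds
        the prediction of the k-component model.
        """
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xc = X - self.x_mean_
        out = np.empty((X.shape[0], max(self.n_components_, 1)))
        if self.n_components_ == 0:
            out[:] = self.y_mean_
            return out
        for k in range(1, self.n_components_ + 1):
            out[:, k - 1] = Xc @ self._coef_k(k) + self.y_mean_
        return out


def press_q2(y_obs: np.ndarray, y_pred_loo: np.ndarray) -> tuple[float, float]:
    """q² = 1 − PRESS/SS_tot and SE_LOO = sqrt(PRESS/n) from LOO predictions."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred_loo = np.asarray(y_pred_loo, dtype=float)
    press = float(np.sum((y_obs - y_pred_loo) ** 2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance; q2 undefined")
    return 1.0 - press / ss_tot, np.sqrt(press / len(y_obs))


def loo_predictions_pls(X, y, max_components: int) -> np.ndarray:
    """Leave-one-out predictions for PLS1 at every component count.

    Each compound is removed entirely, the model refit on the remainder and
    the held-out compound predicted.  Returns (n, max_components); when fewer
    components are extractable in a fold the last available model is carried
    forward for the higher counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    out = np.empty((n, max_components))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        m = PLS1Regression(n_components=max_components).fit(X[keep], y[keep])
        preds = m.predict_components(X[i : i + 1])[0]
        k = len(preds)
        out[i, :k] = preds[:max_components]
        if k < max_components:
            out[i, k:] = preds[min(k, max_components) - 1]
    return out


def loo_q2_pls(X, y, max_components: int) -> tuple[int, float, float, np.ndarray]:
    """Select the PLS component count maximizing LOO q².

    Returns ``(best_k, q2, se_loo, loo_pred_best)``.
    """
    preds = loo_predictions_pls(X, y, max_components)
    q2s = np.array([press_q2(y, preds[:, k])[0] for k in range(preds.shape[1])])
    best = int(np.argmax(q2s))
    q2, se = press_q2(y, preds[:, best])
    return best + 1, q2, se, preds[:, best]


def ols_loo_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOO residuals of least squares with intercept, via the hat matrix.

    e_(-i) = e_i / (1 - h_ii); exact for linear smoothers, O(n p^2).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    # pseudo-inverse handles the well-posed case; rank deficiency is the
    # caller's problem (fit_mlr raises before getting here)
    pinv = np.linalg.pinv(A)
    h = np.einsum("ij,ji->i", A, pinv)
    resid = y - A @ (pinv @ y)
    denom = 1.0 - h
    if np.any(denom < 1e-10):
        raise ValueError("leverage ~ 1: a compound determines its own fit")
    return resid / denom
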