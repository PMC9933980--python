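"""Native partial least squares regression (NIPALS, single response).

Implemented from first principles because the PLS regression-coefficient
vector is also the workhorse inside the CARS and UVE band selectors, which
need access to coefficients refit many times on resampled calibration sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PLSError(RuntimeError):
    pass


@dataclass
class PLSModel:
    """Fitted PLS1 model. ``coef_`` maps raw (uncentered) X to y."""

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray  # W, p × a (X weights)
    loadings: np.ndarray  # P, p × a (X loadings)
    y_loadings: np.ndarray  # q, a
    scores: np.ndarray  # T, n × a (training scores, mutually orthogonal)
    coef_: np.ndarray  # p, on the original X/y scale
    intercept_: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scale: bool = False,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> PLSModel:
    """Fit PLS1 by NIPALS on centered (optionally unit-variance) data.

    For a single response the NIPALS weight vector is available in closed
    form per component (w ∝ Xᵀy), but the iterative loop is retained with the
    stated iteration cap and tolerance so the multi-block structure is
    explicit; it converges on the first pass for one response column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise PLSError(f"X has {n} rows but y has {y.size} entries")
    if n_components < 1 or n_components > min(n - 1, p):
        raise PLSError(
            f"n_components={n_components} invalid for {n} samples x {p} variables"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        y_scale = float(y.std(ddof=1)) or 1.0
    else:
        x_scale = np.ones(p)
        y_scale = 1.0
    E = (X - x_mean) / x_scale
    f = (y - y_mean) / y_scale

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual X carries no covariance with y; truncate
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            n_components = a
            break
        w = w / norm
        t = E @ w
        for _ in range(max_iter):
            # PLS1: the weight update is a fixed point after one pass
            t_new = E @ w
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t), 1e-30):
                t = t_new
                break
            t = t_new
        else:
            raise PLSError(f"NIPALS did not converge within {max_iter} iterations")
        tt = float(t @ t)
        if tt < 1e-14:
            n_components = a
            W, P, T = W[:, :a], P[:, :a], T[:, :a]
            q = q[:a]
            break
        p_load = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_load, q_a, t
    if n_components == 0:
        # degenerate problem (constant y or zero X): intercept-only model
        beta_std = np.zeros(p)
    else:
        # B = W (PᵀW)⁻¹ q on the standardized scale
        PtW = P.T @ W
        beta_std = W @ np.linalg.solve(PtW, q)
    coef = beta_std * y_scale / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        weights=W,
        loadings=P,
        y_loadings=q,
        scores=T,
        coef_=coef,
        intercept_=intercept,
    )


def pls_coefficients(X: np.ndarray, y: np.ndarray, n_components: int, scale: bool = False) -> np.ndarray:
    """Regression-coefficient vector of a PLS1 fit (selection methods' weight source)."""
    return pls_fit(X, y, n_components, scale=scale).coef_


def max_components(n_samples: int, n_vars: int, requested: int) -> int:
    """Clamp a requested component count to what the data can support."""
    return max(1, min(requested, n_samples - 1, n_vars))
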