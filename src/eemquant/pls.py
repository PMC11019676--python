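"""Multi-response partial least squares (PLS2) with leave-one-out CV.

NIPALS on mean-centred X and Y (no variance scaling by default: after DRS
normalisation the features share units).  Component count is chosen from
the LOOCV mean-squared-error curve with a relative-improvement elbow rule,
and recovery is summarised by the per-response coefficient of determination
of the LOOCV predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-13


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PLSModel:
    n_components: int            # requested k
    n_extracted: int             # components actually extracted (<= k)
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_scale: np.ndarray          # ones unless autoscaling was requested
    weights: np.ndarray          # W, p x k
    x_loadings: np.ndarray       # P, p x k
    y_loadings: np.ndarray       # Q, q x k
    x_scores: np.ndarray         # T, n x k
    coef: np.ndarray             # p x q on the original X scale, all extracted components

    def coef_for(self, k: int) -> np.ndarray:
        """Prediction map (original X scale) using the first k components."""
        k = min(k, self.n_extracted)
        if k < 1:
            return np.zeros_like(self.coef)
        W, P, Q = self.weights[:, :k], self.x_loadings[:, :k], self.y_loadings[:, :k]
        return (W @ np.linalg.solve(P.T @ W, Q.T)) / self.x_scale[:, None]


def fit_pls(X: np.ndarray, Y: np.ndarray, k: int, *, scale: bool = False,
            tol: float = 1e-10, max_iter: int = 500) -> PLSModel:
    """NIPALS PLS2 with k components on mean-centred data.

    Deterministic: the score iteration for each component starts from the
    residual-Y column with the largest variance.  If the residuals are
    exhausted before k components (exactly collinear data), the remaining
    components are left null rather than treated as failure.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values are not supported")
    n, p = X.shape
    q = Y.shape[1]
    if k < 1 or k > min(n - 1, p):
        raise ValueError(f"k must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    Xc = Xc / x_scale
    Yc = Y - y_mean
    x_norm0 = max(float(np.abs(Xc).max()), 1.0)

    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros((q, k))
    T = np.zeros((n, k))
    extracted = 0

    for a in range(k):
        y_var = (Yc ** 2).sum(axis=0)
        if float(y_var.max()) <= (_EPS * x_norm0) ** 2 * n:
            break  # Y residual exhausted
        u = Yc[:, int(np.argmax(y_var))].copy()
        t_prev = None
        degenerate = False
        converged = False
        for _ in range(max_iter):
            w = Xc.T @ u
            w_norm = float(np.linalg.norm(w))
            if w_norm <= _EPS * x_norm0:
                degenerate = True
                break
            w = w / w_norm
            t = Xc @ w
            tt = float(t @ t)
            if tt <= (_EPS * x_norm0) ** 2:
                degenerate = True
                break
            qv = Yc.T @ t / tt
            if q == 1:
                converged = True
                break
            u = Yc @ qv / float(qv @ qv)
            if t_prev is not None and np.linalg.norm(t - t_prev) <= tol * max(np.linalg.norm(t), 1.0):
                converged = True
                break
            t_prev = t
        if degenerate:
            break
        if not converged:
            raise ConvergenceError(f"NIPALS did not converge for component {a + 1}")
        pv = Xc.T @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, qv, t
        Xc = Xc - np.outer(t, pv)
        Yc = Yc - np.outer(t, qv)
        extracted += 1

    model = PLSModel(n_components=k, n_extracted=extracted, x_mean=x_mean,
                     y_mean=y_mean, x_scale=x_scale, weights=W, x_loadings=P,
                     y_loadings=Q, x_scores=T, coef=np.zeros((p, q)))
    model.coef = model.coef_for(extracted) if extracted else np.zeros((p, q))
    return model


def predict(model: PLSModel, X: np.ndarray, k: int | None = None) -> np.ndarray:
    """Yhat = (X - x_mean) @ coef + y_mean, optionally truncated to k components."""
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValueError("X column count does not match the fitted model")
    coef = model.coef if k is None else model.coef_for(k)
    out = (X - model.x_mean) @ coef + model.y_mean
    return out[0] if one_d else out


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary.

    ``predictions_per_k[k]`` holds the n x q out-of-sample predictions made
    with k components; row i always comes from a model fitted without
    row i.  ``mse_per_k`` is the mean squared error over all rows and
    responses, on their natural concentration scales.
    """

    predictions_per_k: dict[int, np.ndarray]
    mse_per_k: dict[int, float]
    k_max: int
    selected_k: int | None = None
    r2: np.ndarray | None = None
    row_ids: list | None = None

    @property
    def predictions(self) -> np.ndarray:
        k = self.selected_k if self.selected_k is not None else self.k_max
        return self.predictions_per_k[k]

    def predictions_at(self, k: int) -> np.ndarray:
        return self.predictions_per_k[k]


def loocv(X: np.ndarray, Y: np.ndarray, k_max: int, *, scale: bool = False) -> CVResult:
    """Exactly n refits; row i predicted by a model that never saw row i.

    One k_max-component NIPALS fit per left-out row yields the nested
    predictions for every k in 1..k_max.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape[0], Y.shape[1]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if k_max < 1 or k_max > min(n - 2, X.shape[1]):
        raise ValueError("k_max must be in [1, min(n-2, p)] for leave-one-out folds")
    preds = {k: np.empty((n, q)) for k in range(1, k_max + 1)}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls(X[mask], Y[mask], k_max, scale=scale)
        for k in range(1, k_max + 1):
            preds[k][i] = predict(model, X[i], k=k)
    mse = {k: float(np.mean((preds[k] - Y) ** 2)) for k in preds}
    return CVResult(predictions_per_k=preds, mse_per_k=mse, k_max=k_max)


def select_components(mse_per_k: dict[int, float], tau: float = 0.01) -> int:
    """Smallest k whose improvement to k+1 falls below tau relative to
    MSE(1); the largest k if the curve keeps improving to the end."""
    if not mse_per_k:
        raise ValueError("mse_per_k is empty")
    if tau <= 0:
        raise ValueError("tau must be positive")
    ks = sorted(mse_per_k)
    ref = mse_per_k[ks[0]]
    if ref == 0:
        return ks[0]
    for k, k_next in zip(ks, ks[1:]):
        if (mse_per_k[k] - mse_per_k[k_next]) / ref < tau:
            return k
    return ks[-1]


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Coefficient of determination 1 - SSE/SST per response column."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.ndim == 1:
        y_true = y_true[:, None]
        y_pred = np.asarray(y_pred, dtype=float)[:, None]
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    if y_true.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    sst = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(sst == 0):
        raise ValueError("R^2 undefined for a zero-variance response")
    sse = ((y_true - y_pred) ** 2).sum(axis=0)
    return 1.0 - sse / sst
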