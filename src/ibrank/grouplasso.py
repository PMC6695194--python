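"""Multinomial logistic regression with a group-lasso penalty.

The model maps a target's (column-scaled) activity profile x to a cluster
label y in {1..K}:

    Pr(y = k | x) = softmax(w_k0 + w_k' x)_k

fitted by minimizing the summed negative log-likelihood plus
lambda * sum_j ||w_.j||_2, where the group w_.j collects the K weights of
compound j.  The group norm zeroes whole compounds at once, so the set of
surviving groups is a feature (informer) selection.  Individual groups can
be exempted from the penalty, which is what the greedy selection loop and
the unpenalized refit need.

Solver: FISTA (accelerated proximal gradient) with a fixed step from the
spectral norm of the design.  Intercepts are never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MultinomialModel", "fit_multinomial_group_lasso", "lambda_max"]


class ConvergenceError(RuntimeError):
    """Inner optimization failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class MultinomialModel:
    """Fitted multinomial logistic model over K target clusters.

    ``weights`` is (K, n): row k holds compound weights for cluster k, so
    column j is the group whose Euclidean norm measures how strongly
    compound j discriminates the clusters.
    """

    intercepts: np.ndarray
    weights: np.ndarray
    K: int
    lam: float
    compound_ids: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    objective: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def group_norms(self) -> np.ndarray:
        return np.linalg.norm(self.weights, axis=0)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for one profile (softmax over w_k0 + w_k'x)."""
        logits = self.intercepts + self.weights @ np.asarray(x, dtype=float)
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()

    def log_likelihood(self, X: np.ndarray, y: np.ndarray) -> float:
        logits = self.intercepts[None, :] + X @ self.weights.T
        logits -= logits.max(axis=1, keepdims=True)
        logZ = np.log(np.exp(logits).sum(axis=1))
        return float((logits[np.arange(len(y)), y] - logZ).sum())


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _nll(X, Y, b, W, ridge):
    logits = b[None, :] + X @ W.T
    z = logits - logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(z).sum(axis=1)) + logits.max(axis=1)
    ll = (logits * Y).sum() - logZ.sum()
    return -ll + 0.5 * ridge * float((W * W).sum())


def lambda_max(X: np.ndarray, y: np.ndarray, K: int) -> float:
    """Smallest penalty at which every (penalized) group is zero.

    Computed from the gradient of the log-likelihood at W = 0 with
    intercepts at their unconstrained optimum (class log-frequencies).
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    Y = np.zeros((m, K))
    Y[np.arange(m), y] = 1.0
    freq = Y.mean(axis=0)
    P = np.tile(freq, (m, 1))
    G = (P - Y).T @ X  # (K, n)
    return float(np.linalg.norm(G, axis=0).max())


def _fit_smooth(X, Y, K, ridge, tol, max_iter, warm):
    from scipy.optimize import minimize

    m, n = X.shape

    def unpack(theta):
        b = theta[:K]
        W = theta[K:].reshape(K, n)
        return b, W

    def fun(theta):
        b, W = unpack(theta)
        logits = b[None, :] + X @ W.T
        zmax = logits.max(axis=1, keepdims=True)
        logZ = np.log(np.exp(logits - zmax).sum(axis=1)) + zmax[:, 0]
        f = -(logits * Y).sum() + logZ.sum() + 0.5 * ridge * (W * W).sum()
        P = _softmax_rows(logits)
        R = P - Y
        gb = R.sum(axis=0)
        gW = R.T @ X + ridge * W
        return f, np.concatenate([gb, gW.ravel()])

    theta0 = (
        np.concatenate([warm[0], np.asarray(warm[1]).ravel()])
        if warm is not None
        else np.zeros(K + K * n)
    )
    res = minimize(
        fun,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": 1e-7},
    )
    b, W = unpack(res.x)
    return MultinomialModel(
        intercepts=b,
        weights=W,
        K=K,
        lam=0.0,
        objective=float(res.fun),
        n_iter=int(res.nit),
        converged=True,
        diagnostics={"ridge": ridge, "lbfgs_status": int(res.status)},
    )


def fit_multinomial_group_lasso(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    lam: float,
    unpenalized: np.ndarray | None = None,
    ridge: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 10000,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> MultinomialModel:
    """Fit the penalized multinomial model by FISTA.

    Parameters
    ----------
    X : (m, n) feature matrix (targets x compounds, column-scaled).
    y : (m,) integer cluster labels in 0..K-1.
    lam : group-lasso weight applied to groups not marked unpenalized.
    unpenalized : boolean mask of length n; True exempts that compound's
        group from the penalty (used by greedy selection and refits).
    ridge : tiny quadratic stabilizer (used by the unpenalized refit where
        the likelihood is otherwise unbounded under separation).
    warm : optional (intercepts, weights) starting point.

    Stops when the relative objective change drops below ``tol``; raises
    :class:`ConvergenceError` after ``max_iter`` iterations otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    m, n = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if y.min() < 0 or y.max() >= K:
        raise ValueError("labels must lie in 0..K-1")
    if unpenalized is None:
        unpenalized = np.zeros(n, dtype=bool)
    penalized = ~np.asarray(unpenalized, dtype=bool)

    Y = np.zeros((m, K))
    Y[np.arange(m), y] = 1.0

    if lam == 0.0 or not penalized.any():
        # smooth problem: quasi-Newton is far faster than proximal steps,
        # especially near separation where the ridge sets the scale
        return _fit_smooth(X, Y, K, ridge, tol, max_iter, warm)

    if warm is not None:
        b = np.array(warm[0], dtype=float)
        W = np.array(warm[1], dtype=float)
    else:
        b = np.zeros(K)
        W = np.zeros((K, n))

    # Lipschitz bound for the softmax NLL gradient: 0.5 * ||[1 X]||_2^2.
    Xa = np.hstack([np.ones((m, 1)), X])
    smax = np.linalg.norm(Xa, 2)
    L = 0.5 * smax * smax + ridge
    step = 1.0 / L

    def penalty(Wm):
        return lam * np.linalg.norm(Wm[:, penalized], axis=0).sum()

    def objective(bv, Wm):
        return _nll(X, Y, bv, Wm, ridge) + penalty(Wm)

    f_prev = objective(b, W)
    vb, vW = b.copy(), W.copy()
    t_prev = 1.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        P = _softmax_rows(vb[None, :] + X @ vW.T)
        R = P - Y
        gb = R.sum(axis=0)
        gW = R.T @ X + ridge * vW

        b_new = vb - step * gb
        W_new = vW - step * gW
        if lam > 0 and penalized.any():
            norms = np.linalg.norm(W_new[:, penalized], axis=0)
            shrink = np.maximum(0.0, 1.0 - step * lam / np.maximum(norms, 1e-300))
            W_new[:, penalized] *= shrink[None, :]

        t = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev * t_prev))
        accel = (t_prev - 1.0) / t
        vb = b_new + accel * (b_new - b)
        vW = W_new + accel * (W_new - W)
        b, W = b_new, W_new
        t_prev = t

        f = objective(b, W)
        if f > f_prev:  # monotone restart
            vb, vW = b.copy(), W.copy()
            t_prev = 1.0
        if abs(f_prev - f) <= tol * max(1.0, abs(f_prev)):
            f_prev = f
            break
        f_prev = f
    else:
        raise ConvergenceError(
            f"group-lasso solver did not converge in {max_iter} iterations",
            {"n_iter": max_iter, "objective": f_prev, "tol": tol, "lam": lam},
        )

    return MultinomialModel(
        intercepts=b,
        weights=W,
        K=K,
        lam=lam,
        objective=float(f_prev),
        n_iter=n_iter,
        converged=True,
        diagnostics={"step": step, "ridge": ridge},
    )
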