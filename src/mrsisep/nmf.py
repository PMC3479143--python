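"""The five matrix-factorization algorithms and shared convergence logic.

All methods approximate ``X ~ W @ H`` with ``W`` (p x k sources) and
``H`` (k x n non-negative mixing matrix), minimizing the Frobenius
reconstruction error.  Four of them (euc, als, alspg, alsobs) require a
non-negative data matrix, so mixed-sign spectra must go through the
magnitude transform first.  The convex variant instead constrains the
sources to the column space of the data, ``W = X @ G`` with ``G >= 0``,
which accepts mixed-sign data and yields mixed-sign sources — the
natural representation for long-echo MR spectra with inverted peaks.

Methods:

* ``euc`` — Lee-Seung multiplicative updates for the Euclidean
  objective, with W columns rescaled to sum to one (scale folded into H
  so the reconstruction is unchanged).
* ``als`` — alternating least squares, negatives clipped to zero.
* ``alspg`` — alternating non-negative least squares, each subproblem
  solved by projected gradient descent with backtracking line search.
* ``alsobs`` — alternating least squares where clipped (pruned)
  negative entries are compensated by an Optimal-Brain-Surgeon
  second-order correction of the surviving entries, with damped
  subproblem Hessians.
* ``convex`` — convex-variant multiplicative updates on the positive /
  negative parts of the Gram matrix ``A = X^T X``.

Convergence is declared when the absolute change in Frobenius
reconstruction error between successive iterations falls below ``tol``
(default 1e-5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .initializers import InitResult

logger = logging.getLogger(__name__)

EPS = 1e-12  # denominator guard for multiplicative/ratio updates


class Method(str, Enum):
    EUC = "euc"
    ALS = "als"
    ALSPG = "alspg"
    ALSOBS = "alsobs"
    CONVEX = "convex"


@dataclass(frozen=True)
class PGParams:
    """Projected-gradient line-search settings for ``alspg``."""

    eta0: float = 1.0          # initial step size
    beta: float = 0.1          # backtracking shrink factor
    sigma: float = 0.01        # sufficient-decrease constant
    max_backtracks: int = 20
    inner_iters: int = 10      # PG steps per subproblem per outer iteration


@dataclass
class FactorizationConfig:
    method: Method = Method.CONVEX
    k: int = 2
    max_iter: int = 2000
    tol: float = 1e-5
    seed: int = 0
    pg: PGParams = field(default_factory=PGParams)
    lambda_w: float = 1e-3
    lambda_h: float = 1e-3

    def __post_init__(self) -> None:
        self.method = Method(self.method)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")


@dataclass
class FactorizationResult:
    W: np.ndarray
    H: np.ndarray
    G: np.ndarray | None
    error_trajectory: np.ndarray
    iterations: int
    converged: bool
    method: Method

    @property
    def final_error(self) -> float:
        return float(self.error_trajectory[-1])


def reconstruction_error(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Frobenius norm of the residual ||X - W H||_F."""
    return float(np.linalg.norm(X - W @ H))


# ---------------------------------------------------------------- euc


def euc_step(W: np.ndarray, H: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One Lee-Seung multiplicative update (H first, then W), followed by
    rescaling W columns to unit sum with the inverse folded into H."""
    H = H * (W.T @ X) / (W.T @ W @ H + EPS)
    W = W * (X @ H.T) / (W @ H @ H.T + EPS)
    scale = W.sum(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    W = W / scale
    H = H * scale[:, None]
    return W, H


# ---------------------------------------------------------------- als


def _lstsq(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares solve of A Z = B (SVD-based, so
    rank-deficient systems fall back to the pseudoinverse solution)."""
    return np.linalg.lstsq(A, B, rcond=None)[0]


def als_step(W: np.ndarray, H: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternating least squares with negatives clipped to zero."""
    H = np.maximum(_lstsq(W, X), 0.0)
    W = np.maximum(_lstsq(H.T, X.T).T, 0.0)
    return W, H


# ---------------------------------------------------------------- alspg


def _pg_subproblem(AtA: np.ndarray, AtB: np.ndarray, F: np.ndarray,
                   params: PGParams) -> np.ndarray:
    """Projected gradient descent on 0.5||A F - B||^2 over F >= 0.

    Gradient is AtA @ F - AtB.  Each step backtracks the step size until
    the Armijo-style sufficient-decrease condition holds; if no
    decreasing step is found within the cap the factor is left as is.
    """

    def objective(F_: np.ndarray) -> float:
        return 0.5 * float(np.sum(F_ * (AtA @ F_))) - float(np.sum(F_ * AtB))

    for _ in range(params.inner_iters):
        grad = AtA @ F - AtB
        obj = objective(F)
        eta = params.eta0
        for _ in range(params.max_backtracks):
            F_new = np.maximum(F - eta * grad, 0.0)
            step = F_new - F
            if objective(F_new) - obj <= params.sigma * float(np.sum(grad * step)):
                break
            eta *= params.beta
        else:
            logger.debug("alspg: no decreasing step found; keeping current factor")
            return F
        if not np.any(step):
            return F  # projected gradient vanished: subproblem solved
        F = F_new
    return F


def alspg_step(W: np.ndarray, H: np.ndarray, X: np.ndarray,
               params: PGParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Alternating NNLS via projected gradients (H subproblem, then W)."""
    if params is None:
        params = PGParams()
    H = _pg_subproblem(W.T @ W, W.T @ X, H, params)
    Wt = _pg_subproblem(H @ H.T, H @ X.T, W.T, params)
    return Wt.T, H


# ---------------------------------------------------------------- alsobs


def _obs_adjust_columns(F: np.ndarray, A: np.ndarray, lam: float,
                        lam_cap: float = 1e3) -> np.ndarray:
    """Clip negatives in each column of the least-squares solution F and
    re-adjust the surviving entries with the Optimal-Brain-Surgeon
    correction for the quadratic subproblem with (damped) Hessian A.

    Pruning coordinates P of a quadratic expanded around its minimum
    changes the solution by delta = -A^{-1} E (E^T A^{-1} E)^{-1} E^T f,
    with E the selector of P — the block form of the textbook OBS rule.
    A singular damped system escalates lambda tenfold up to a cap, then
    skips the adjustment (plain clipping) with a warning.
    """
    k = F.shape[0]
    out = F.copy()
    for j in range(F.shape[1]):
        f = F[:, j]
        pruned = np.flatnonzero(f < 0)
        if pruned.size == 0 or pruned.size == k:
            out[:, j] = np.maximum(f, 0.0)
            continue
        lam_j = lam
        while True:
            try:
                Ainv = np.linalg.inv(A + lam_j * np.eye(k))
                block = np.linalg.inv(Ainv[np.ix_(pruned, pruned)])
                break
            except np.linalg.LinAlgError:
                lam_j *= 10.0
                if lam_j > lam_cap:
                    logger.warning("alsobs: singular damped Hessian; skipping OBS adjustment")
                    Ainv = None
                    break
        if Ainv is None:
            out[:, j] = np.maximum(f, 0.0)
            continue
        delta = -Ainv[:, pruned] @ (block @ f[pruned])
        out[:, j] = np.maximum(f + delta, 0.0)
    return out


def alsobs_step(W: np.ndarray, H: np.ndarray, X: np.ndarray,
                lambda_w: float = 1e-3, lambda_h: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """ALS solve per factor, with OBS compensation of clipped entries."""
    H_ls = _lstsq(W, X)
    H = _obs_adjust_columns(H_ls, W.T @ W, lambda_h)
    W_ls = _lstsq(H.T, X.T)  # k x p, columns are rows of W
    W = _obs_adjust_columns(W_ls, H @ H.T, lambda_w).T
    return W, H


# ---------------------------------------------------------------- convex


def _pos_neg(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split A into positive part and magnitude of negative part."""
    return np.maximum(A, 0.0), np.maximum(-A, 0.0)


def convex_step(G: np.ndarray, H: np.ndarray, X: np.ndarray,
                A_pos: np.ndarray | None = None,
                A_neg: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One convex-variant multiplicative update (H first, then G).

    With A = X^T X split as A = A+ - A-, both factors move by square-root
    multiplicative ratios, which preserves non-negativity; the sources
    are recomputed as W = X @ G by the caller.
    """
    if A_pos is None or A_neg is None:
        A_pos, A_neg = _pos_neg(X.T @ X)
    GtAp = G.T @ A_pos
    GtAn = G.T @ A_neg
    H = H * np.sqrt((GtAp + (GtAn @ G) @ H) / (GtAn + (GtAp @ G) @ H + EPS))
    HHt = H @ H.T
    G = G * np.sqrt((A_pos @ H.T + A_neg @ G @ HHt) / (A_neg @ H.T + A_pos @ G @ HHt + EPS))
    return G, H


# ---------------------------------------------------------------- driver


def factorize(X: np.ndarray, config: FactorizationConfig, init: InitResult) -> FactorizationResult:
    """Iterate the configured update scheme to convergence.

    Convergence: absolute change in ||X - W H||_F between successive
    iterations below ``config.tol``, or ``config.max_iter`` reached.
    Deterministic given (X, config, init).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    method = Method(config.method)
    if method is not Method.CONVEX and np.any(X < 0):
        raise ValueError(
            f"method '{method.value}' requires a non-negative data matrix; "
            "apply magnitude_transform first (only the convex variant accepts mixed sign)"
        )

    H = np.asarray(init.H0, dtype=float).copy()
    G = None
    if method is Method.CONVEX:
        if init.G0 is None:
            raise ValueError("convex factorization requires an init with G0")
        G = np.asarray(init.G0, dtype=float).copy()
        W = X @ G
        A_pos, A_neg = _pos_neg(X.T @ X)
    else:
        W = np.asarray(init.W0, dtype=float).copy()

    errors = [reconstruction_error(X, W, H)]
    converged = False
    iterations = 0
    for it in range(1, config.max_iter + 1):
        if method is Method.EUC:
            W, H = euc_step(W, H, X)
        elif method is Method.ALS:
            W, H = als_step(W, H, X)
        elif method is Method.ALSPG:
            W, H = alspg_step(W, H, X, config.pg)
        elif method is Method.ALSOBS:
            W, H = alsobs_step(W, H, X, config.lambda_w, config.lambda_h)
        else:
            G, H = convex_step(G, H, X, A_pos, A_neg)
            W = X @ G
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(H))):
            raise FloatingPointError(f"non-finite factor entries at iteration {it}")
        errors.append(reconstruction_error(X, W, H))
        iterations = it
        if config.tol > 0 and abs(errors[-1] - errors[-2]) < config.tol:
            converged = True
            break

    return FactorizationResult(
        W=W,
        H=H,
        G=G,
        error_trajectory=np.asarray(errors),
        iterations=iterations,
        converged=converged,
        method=method,
    )
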