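"""Update operations and data contracts of the L1/2 gLPCA ALM solver.

The model factorises a centred gene-expression matrix ``X`` (m genes x n
samples) as ``X = U V^T + S`` with orthonormal sample embedding ``V``
(n x k), gene loadings ``U`` (m x k) and an error matrix ``S`` penalised by
the entrywise L1/2 quasi-norm, plus a graph-Laplacian penalty
``alpha * tr(V^T L V)`` that pulls neighbouring samples together in the
embedding.  The constrained problem

    min ||S||_{1/2}^{1/2} + alpha * tr(V^T L V)
    s.t.  S = X - U V^T,  V^T V = I

is solved by augmented Lagrange multipliers: the S-update is the
half-thresholding proximal map, the V-update is an eigenproblem of the
normalised matrix ``G_beta``, the U-update is a closed-form least square,
and the multipliers ``Lambda`` are ascended while the penalty ``mu`` grows
geometrically.

The trade-off is parameterised by ``beta`` in [0, 1] instead of ``alpha``
through ``2*alpha/mu = (beta/(1-beta)) * (sigma_m/sigma_l)``, where
``sigma_m`` and ``sigma_l`` are the largest eigenvalues of ``M^T M`` and of
the Laplacian ``L``.  ``beta = 0`` recovers standard PCA and ``beta = 1``
Laplacian embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import eigh

from .exceptions import InvalidConfigurationError
from .thresholding import half_threshold_matrix

__all__ = [
    "SolverConfig",
    "Decomposition",
    "l12_norm",
    "update_s",
    "update_u",
    "build_g_beta",
    "update_v",
    "update_multipliers",
    "objective",
    "solve",
    "solve_glpca",
]


@dataclass(frozen=True)
class SolverConfig:
    """Free parameters of the solver.

    Parameters
    ----------
    k : int
        Embedding dimension, ``1 <= k < n``.
    beta : float
        Graph-embedding weight in [0, 1]; 0 is PCA, 1 is Laplacian
        embedding.
    mu0 : float
        Initial ALM penalty (default 0.3).
    rho : float
        Geometric growth factor of ``mu`` (> 1; default 1.2).
    n_neighbors : int
        Degree of the sample kNN graph.
    metric : str
        Distance used to build the graph.
    max_iter : int
        Iteration cap of the ALM loop.
    tol : float
        Convergence tolerance on the relative constraint residual
        ``||S - X + U V^T||_F / max(1, ||X||_F)``.
    mu_max : float
        Cap on ``mu`` to avoid numeric overflow.
    center : bool
        Centre each gene row across samples before solving.
    seed : int or None
        Recorded in run reports; the solver itself is deterministic.
    """

    k: int = 2
    beta: float = 0.5
    mu0: float = 0.3
    rho: float = 1.2
    n_neighbors: int = 5
    metric: str = "euclidean"
    max_iter: int = 200
    tol: float = 1e-6
    mu_max: float = 1e12
    center: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise InvalidConfigurationError("beta must lie in [0, 1]")
        if self.rho <= 1.0:
            raise InvalidConfigurationError("rho must exceed 1")
        if self.mu0 <= 0.0:
            raise InvalidConfigurationError("mu0 must be positive")
        if self.k < 1:
            raise InvalidConfigurationError("k must be at least 1")
        if self.max_iter < 1:
            raise InvalidConfigurationError("max_iter must be at least 1")
        if self.tol <= 0.0:
            raise InvalidConfigurationError("tol must be positive")


@dataclass
class Decomposition:
    """Solver output: factors, error matrix, multipliers and traces.

    ``U`` is (m, k), ``V`` is (n, k) with ``V^T V = I``, ``S`` and
    ``Lambda`` are (m, n).  The traces carry one entry per ALM iteration.
    """

    U: np.ndarray
    V: np.ndarray
    S: np.ndarray
    Lambda: np.ndarray
    objective_trace: np.ndarray
    residual_trace: np.ndarray
    orthonormality_trace: np.ndarray
    converged: bool
    iterations: int
    config: SolverConfig
    objective_is_penalty_only: bool = False
    feature_scores: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.feature_scores is None:
            self.feature_scores = np.linalg.norm(self.U, axis=1)


def l12_norm(A):
    """Entrywise L1/2 quasi-norm ``sum_ij |a_ij|^(1/2)``."""
    return float(np.sqrt(np.abs(A)).sum())


def _largest_eigenvalue(A):
    n = A.shape[0]
    return float(eigh(A, eigvals_only=True, subset_by_index=[n - 1, n - 1])[0])


def update_s(X, U, V, Lam, mu):
    """S-update: half-threshold the shifted residual.

    ``S = H_{2/mu}(X - U V^T - Lambda/mu)`` — the proximal map of
    ``||S||_{1/2}^{1/2} + (mu/2)||S - B||_F^2`` after dividing through by
    ``mu/2`` (effective weight ``lam = 2/mu``).
    """
    if mu <= 0:
        raise InvalidConfigurationError("mu must be positive")
    B = X - U @ V.T - Lam / mu
    return half_threshold_matrix(B, 2.0 / mu)


def update_u(M, V):
    """U-update: ``U = M V``, the least-squares minimiser of
    ``||M - U V^T||_F^2`` for orthonormal ``V``."""
    M = np.asarray(M, dtype=float)
    V = np.asarray(V, dtype=float)
    if M.shape[1] != V.shape[0]:
        raise InvalidConfigurationError(
            f"shape mismatch: M is {M.shape}, V is {V.shape}"
        )
    return M @ V


def build_g_beta(M, L, beta, *, sigma_l=None, deflate=True, return_sigma_m=False):
    """Assemble the normalised eigenproblem matrix ``G_beta``.

    ``G_beta = (1-beta) (I - M^T M / sigma_m) + beta L / sigma_l
    [+ e e^T / n]``, where ``e`` is the all-ones vector.  Both summands are
    PSD by construction (``sigma_m``, ``sigma_l`` are the top eigenvalues
    of ``M^T M`` and ``L``).  With row-centred ``M`` the undeflated matrix
    satisfies ``G_beta e = (1-beta) e``; the rank-one deflation lifts the
    eigenvalue of ``e`` by one so the bottom-k eigenvectors never include
    the constant vector.

    If ``M`` is identically zero, ``sigma_m`` is undefined; the PCA part is
    dropped with a warning.
    """
    if not 0.0 <= beta <= 1.0:
        raise InvalidConfigurationError("beta must lie in [0, 1]")
    M = np.asarray(M, dtype=float)
    L = np.asarray(L, dtype=float)
    n = M.shape[1]
    if L.shape != (n, n):
        raise InvalidConfigurationError("L must be n x n for n sample columns")
    if sigma_l is None:
        sigma_l = _largest_eigenvalue(L)
    MtM = M.T @ M
    sigma_m = _largest_eigenvalue(MtM) if np.any(M) else 0.0
    if sigma_m <= 0.0:
        warnings.warn(
            "M is zero: sigma_m undefined, dropping the PCA part of G_beta",
            RuntimeWarning,
            stacklevel=2,
        )
        G = beta * (L / sigma_l) if sigma_l > 0 else np.zeros((n, n))
    else:
        lap = beta * (L / sigma_l) if sigma_l > 0 else np.zeros((n, n))
        G = (1.0 - beta) * (np.eye(n) - MtM / sigma_m) + lap
    if deflate:
        G = G + np.ones((n, n)) / n
    G = (G + G.T) / 2.0
    if return_sigma_m:
        return G, sigma_m
    return G


def _fix_signs(V):
    """Orient each column so its largest-magnitude entry is positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def update_v(G, k):
    """V-update: orthonormal eigenvectors of the ``k`` smallest eigenvalues
    of the symmetric matrix ``G``, with a deterministic sign convention."""
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if k >= n:
        raise InvalidConfigurationError(f"k={k} must be smaller than n={n}")
    _, vecs = eigh(G)
    return _fix_signs(vecs[:, :k])


def update_multipliers(Lam, mu, S, X, U, V, rho):
    """Multiplier ascent and penalty growth:
    ``Lambda' = Lambda + mu (S - X + U V^T)``, ``mu' = rho mu``."""
    if rho <= 1.0:
        raise InvalidConfigurationError("rho must exceed 1")
    Lam_new = Lam + mu * (S - X + U @ V.T)
    return Lam_new, rho * mu


def objective(X, U, V, L, alpha_effective):
    """Model objective ``||X - U V^T||_{1/2}^{1/2} + alpha tr(V^T L V)``."""
    fit_term = l12_norm(X - U @ V.T)
    penalty = float(np.trace(V.T @ L @ V))
    return fit_term + alpha_effective * penalty


def _as_values(X):
    """Accept an ExpressionMatrix or a plain genes-x-samples array."""
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


def solve(X, config=None):
    """Run the full L1/2 gLPCA ALM solver on a genes-x-samples matrix.

    Thin wrapper over :class:`l12glpca.estimators.L12GLPCA` returning a
    :class:`Decomposition` in the genes-x-samples orientation.
    """
    from .estimators import L12GLPCA

    cfg = config if config is not None else SolverConfig()
    A = _as_values(X)
    est = L12GLPCA(
        n_components=cfg.k,
        beta=cfg.beta,
        mu0=cfg.mu0,
        rho=cfg.rho,
        n_neighbors=cfg.n_neighbors,
        metric=cfg.metric,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        mu_max=cfg.mu_max,
        center=cfg.center,
        random_state=cfg.seed,
    ).fit(A.T)
    return Decomposition(
        U=est.components_.T,
        V=est.embedding_,
        S=est.sparse_errors_.T,
        Lambda=est.multipliers_.T,
        objective_trace=est.objective_trace_,
        residual_trace=est.residual_trace_,
        orthonormality_trace=est.orthonormality_trace_,
        converged=est.converged_,
        iterations=est.n_iter_,
        config=cfg,
        objective_is_penalty_only=est.objective_is_penalty_only_,
    )


def solve_glpca(X, config=None):
    """Baseline gLPCA path (``S = 0``): one eigendecomposition of
    ``G_beta`` built from ``X`` itself, then ``U = X V``.

    ``beta = 0`` yields standard PCA, ``beta = 1`` Laplacian embedding.
    """
    from .estimators import GLPCA

    cfg = config if config is not None else SolverConfig()
    A = _as_values(X)
    est = GLPCA(
        n_components=cfg.k,
        beta=cfg.beta,
        n_neighbors=cfg.n_neighbors,
        metric=cfg.metric,
        center=cfg.center,
        random_state=cfg.seed,
    ).fit(A.T)
    m, n = A.shape
    return Decomposition(
        U=est.components_.T,
        V=est.embedding_,
        S=np.zeros((m, n)),
        Lambda=np.zeros((m, n)),
        objective_trace=est.objective_trace_,
        residual_trace=np.zeros(1),
        orthonormality_trace=est.orthonormality_trace_,
        converged=True,
        iterations=1,
        config=cfg,
        objective_is_penalty_only=(cfg.beta == 1.0),
    )
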