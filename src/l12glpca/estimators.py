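"""Scikit-learn style estimators for graph-Laplacian PCA variants.

Both estimators follow the sklearn convention that ``X`` is
``(n_samples, n_features)`` — i.e. samples in rows, genes in columns,
the *transpose* of the genes-x-samples orientation used in expression
files.  Fitted gene loadings are exposed as ``components_`` (k, n_features)
and the orthonormal sample embedding as ``embedding_`` (n_samples, k).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .decomposition import (
    build_g_beta,
    l12_norm,
    objective,
    update_multipliers,
    update_s,
    update_u,
    update_v,
)
from .exceptions import InvalidConfigurationError
from .graph import build_knn_graph, laplacian

__all__ = ["L12GLPCA", "GLPCA"]


class _GraphPCABase(TransformerMixin, BaseEstimator):
    """Shared preprocessing: validation, centring, sample kNN graph."""

    def _prepare(self, X):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        n, m = X.shape
        k = int(self.n_components)
        if not 1 <= k < n:
            raise InvalidConfigurationError(
                f"n_components={k} must satisfy 1 <= k < n_samples={n}"
            )
        if not 0.0 <= self.beta <= 1.0:
            raise InvalidConfigurationError("beta must lie in [0, 1]")
        if self.n_neighbors >= n:
            raise InvalidConfigurationError(
                f"n_neighbors={self.n_neighbors} must be smaller than "
                f"n_samples={n}"
            )
        self.n_features_in_ = m
        A = X.T.copy()  # genes x samples
        self.mean_ = A.mean(axis=1) if self.center else np.zeros(m)
        A -= self.mean_[:, None]
        self.graph_ = build_knn_graph(A, self.n_neighbors, metric=self.metric)
        L, sigma_l = laplacian(self.graph_, return_largest_eigenvalue=True)
        return A, L, sigma_l, k

    def _finalize(self, U, V):
        self.components_ = U.T
        self.embedding_ = V
        self.feature_scores_ = np.linalg.norm(U, axis=1)

    def transform(self, X):
        """Least-squares embedding of new samples onto the fitted loadings.

        Solves ``min_v ||x - U v||`` per centred sample; on training data
        this is only an approximation of ``embedding_`` because the model
        is not a plain least-squares fit.
        """
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        A = (X - self.mean_).T
        U = self.components_.T
        coords, *_ = np.linalg.lstsq(U, A, rcond=None)
        return coords.T

    def fit_transform(self, X, y=None):
        """Fit the model and return the sample embedding ``V``."""
        return self.fit(X).embedding_


class GLPCA(_GraphPCABase):
    """Graph-Laplacian PCA (closed form, no error term).

    Minimises ``||X - U V^T||_F^2 + alpha tr(V^T L V)`` over orthonormal
    ``V`` via a single eigendecomposition of the normalised matrix
    ``G_beta``; ``U = X V``.  ``beta = 0`` is standard PCA, ``beta = 1``
    Laplacian embedding.

    Parameters
    ----------
    n_components : int
        Embedding dimension ``k``.
    beta : float
        Graph-embedding weight in [0, 1].
    n_neighbors : int
        Degree of the sample kNN graph.
    metric : str
        Distance used for the graph.
    center : bool
        Centre each gene across samples before fitting.
    random_state : int or None
        Recorded only; the fit is deterministic.
    """

    def __init__(self, n_components=2, beta=0.5, n_neighbors=5,
                 metric="euclidean", center=True, random_state=None):
        self.n_components = n_components
        self.beta = beta
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.center = center
        self.random_state = random_state

    def fit(self, X, y=None):
        A, L, sigma_l, k = self._prepare(X)
        G, sigma_m = build_g_beta(A, L, self.beta, sigma_l=sigma_l,
                                  return_sigma_m=True)
        V = update_v(G, k)
        U = update_u(A, V)
        self._finalize(U, V)
        # Objective of the unnormalised formulation, for diagnostics.
        fit_term = float(np.linalg.norm(A - U @ V.T) ** 2)
        penalty = float(np.trace(V.T @ L @ V))
        if self.beta < 1.0 and sigma_m > 0 and sigma_l > 0:
            alpha = (self.beta / (1.0 - self.beta)) * (sigma_m / sigma_l)
            self.objective_trace_ = np.array([fit_term + alpha * penalty])
            self.objective_is_penalty_only_ = False
        else:
            self.objective_trace_ = np.array([penalty])
            self.objective_is_penalty_only_ = True
        self.orthonormality_trace_ = np.array(
            [float(np.max(np.abs(V.T @ V - np.eye(k))))]
        )
        self.n_iter_ = 1
        self.converged_ = True
        return self


class L12GLPCA(_GraphPCABase):
    """L1/2-norm constrained graph-Laplacian PCA, solved by ALM.

    Decomposes the centred data as ``X = U V^T + S`` where the error
    matrix ``S`` carries an entrywise L1/2 penalty (robustness to outliers)
    and the orthonormal embedding ``V`` carries a graph-Laplacian penalty.
    Each ALM sweep half-thresholds the residual into ``S``, rebuilds
    ``G_beta`` from ``M = X - S - Lambda/mu``, takes the bottom-k
    eigenvectors as ``V``, sets ``U = M V`` and ascends the multipliers
    while ``mu`` grows by ``rho`` per iteration.

    Parameters
    ----------
    n_components : int
        Embedding dimension ``k``.
    beta : float
        Graph-embedding weight in [0, 1].
    mu0 : float
        Initial ALM penalty (default 0.3).
    rho : float
        Penalty growth factor (> 1, default 1.2).
    n_neighbors, metric :
        Sample kNN graph parameters.
    max_iter : int
        ALM iteration cap.
    tol : float
        Convergence tolerance on the relative constraint residual.
    mu_max : float
        Cap on ``mu``.
    center : bool
        Centre each gene across samples before fitting.
    random_state : int or None
        Recorded only; the fit is deterministic.

    Attributes
    ----------
    components_ : (k, n_features) ndarray
        Gene loadings ``U^T``.
    embedding_ : (n_samples, k) ndarray
        Orthonormal sample embedding ``V``.
    sparse_errors_ : (n_samples, n_features) ndarray
        Error matrix ``S^T``.
    multipliers_ : (n_samples, n_features) ndarray
        Lagrange multipliers ``Lambda^T``.
    feature_scores_ : (n_features,) ndarray
        Euclidean norm of each gene's loading row; ranks feature genes.
    objective_trace_, residual_trace_, orthonormality_trace_ : ndarray
        Per-iteration model objective, relative constraint residual and
        ``max |V^T V - I|``.
    n_iter_ : int
        Iterations run.
    converged_ : bool
        Whether the residual fell below ``tol``.
    """

    def __init__(self, n_components=2, beta=0.5, mu0=0.3, rho=1.2,
                 n_neighbors=5, metric="euclidean", max_iter=200, tol=1e-6,
                 mu_max=1e12, center=True, random_state=None):
        self.n_components = n_components
        self.beta = beta
        self.mu0 = mu0
        self.rho = rho
        self.n_neighbors = n_neighbors
        self.metric = metric
        self.max_iter = max_iter
        self.tol = tol
        self.mu_max = mu_max
        self.center = center
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.mu0 <= 0:
            raise InvalidConfigurationError("mu0 must be positive")
        if self.rho <= 1.0:
            raise InvalidConfigurationError("rho must exceed 1")
        A, L, sigma_l, k = self._prepare(X)
        m, n = A.shape
        beta = float(self.beta)

        # Warm start from the gLPCA solution at the same beta: the first
        # S-update then acts on the gLPCA residual.
        G0 = build_g_beta(A, L, beta, sigma_l=sigma_l)
        V = update_v(G0, k)
        U = update_u(A, V)
        S = np.zeros((m, n))
        Lam = np.zeros((m, n))
        mu = float(self.mu0)
        norm_x = max(1.0, float(np.linalg.norm(A)))

        obj_trace, res_trace, ortho_trace = [], [], []
        converged = False
        n_iter = 0
        penalty_only = beta == 1.0
        for n_iter in range(1, self.max_iter + 1):
            S = update_s(A, U, V, Lam, mu)
            M = A - S - Lam / mu
            G, sigma_m = build_g_beta(M, L, beta, sigma_l=sigma_l,
                                      return_sigma_m=True)
            V = update_v(G, k)
            U = update_u(M, V)
            residual = float(np.linalg.norm(S - A + U @ V.T)) / norm_x
            if penalty_only or sigma_m <= 0 or sigma_l <= 0:
                obj = float(np.trace(V.T @ L @ V))
            else:
                # 2*alpha/mu is held at (beta/(1-beta))*(sigma_m/sigma_l),
                # recomputed each iteration from the current M.
                alpha = (mu / 2.0) * (beta / (1.0 - beta)) * (sigma_m / sigma_l)
                obj = objective(A, U, V, L, alpha)
            obj_trace.append(obj)
            res_trace.append(residual)
            ortho_trace.append(float(np.max(np.abs(V.T @ V - np.eye(k)))))
            Lam, mu_next = update_multipliers(Lam, mu, S, A, U, V, self.rho)
            if residual <= self.tol:
                converged = True
                break
            mu = min(mu_next, self.mu_max)

        self._finalize(U, V)
        self.sparse_errors_ = S.T
        self.multipliers_ = Lam.T
        self.objective_trace_ = np.asarray(obj_trace)
        self.residual_trace_ = np.asarray(res_trace)
        self.orthonormality_trace_ = np.asarray(ortho_trace)
        self.objective_is_penalty_only_ = penalty_only
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self
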