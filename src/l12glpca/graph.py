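"""k-nearest-neighbour affinity graph and its Laplacian.

The graph is built between the *sample* columns of the expression matrix:
the embedding ``V`` produced by the solvers lives in sample space, and the
Laplacian quadratic form ``tr(V^T L V)`` penalises embedding differences
between neighbouring samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

from .exceptions import ContractViolationError, InvalidConfigurationError

__all__ = ["NeighborGraph", "build_knn_graph", "laplacian"]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric 0/1 kNN affinity graph on the sample columns.

    Attributes
    ----------
    W : (n, n) ndarray
        Binary symmetric weight matrix with zero diagonal.
    D : (n, n) ndarray
        Diagonal degree matrix, ``D_ii = sum_j W_ij``.
    L : (n, n) ndarray
        Combinatorial Laplacian ``L = D - W``; rows sum to zero and the
        matrix is positive semidefinite.
    n_neighbors : int
        Number of neighbours each node requested (before OR-symmetrisation).
    """

    W: np.ndarray
    D: np.ndarray
    L: np.ndarray
    n_neighbors: int


def build_knn_graph(X, n_neighbors, metric="euclidean"):
    """Build the symmetric kNN graph between the columns of ``X``.

    ``W_ij = 1`` iff sample ``i`` is among the ``n_neighbors`` nearest of
    sample ``j`` *or* vice versa; a sample is never its own neighbour.
    Ties at equal distance are broken deterministically towards the lower
    column index, so duplicate columns are allowed.

    Parameters
    ----------
    X : (m, n) array_like
        Data matrix; distances are computed between the ``n`` columns.
    n_neighbors : int
        Neighbourhood size, ``1 <= n_neighbors <= n - 1``.
    metric : str
        Any distance name accepted by :func:`scipy.spatial.distance.cdist`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidConfigurationError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise InvalidConfigurationError("X contains non-finite entries")
    n = X.shape[1]
    n_neighbors = int(n_neighbors)
    if n_neighbors < 1:
        raise InvalidConfigurationError("n_neighbors must be positive")
    if n_neighbors >= n:
        raise InvalidConfigurationError(
            f"n_neighbors={n_neighbors} must be smaller than the number of "
            f"samples n={n}"
        )

    dist = cdist(X.T, X.T, metric=metric)
    W = np.zeros((n, n))
    for j in range(n):
        # Stable sort: among equal distances the lower index comes first.
        order = np.argsort(dist[:, j], kind="stable")
        picked = 0
        for i in order:
            if i == j:
                continue
            W[i, j] = 1.0
            picked += 1
            if picked == n_neighbors:
                break
    W = np.maximum(W, W.T)  # OR-symmetrisation
    D = np.diag(W.sum(axis=1))
    return NeighborGraph(W=W, D=D, L=D - W, n_neighbors=n_neighbors)


def laplacian(graph, return_largest_eigenvalue=False):
    """Return ``L = D - W`` (optionally with its largest eigenvalue).

    Raises
    ------
    ContractViolationError
        If the stored weight matrix is not symmetric.
    """
    W = np.asarray(graph.W, dtype=float)
    if not np.array_equal(W, W.T):
        raise ContractViolationError("weight matrix W is not symmetric")
    L = np.asarray(graph.L, dtype=float)
    if return_largest_eigenvalue:
        n = L.shape[0]
        sigma_l = float(eigh(L, eigvals_only=True, subset_by_index=[n - 1, n - 1])[0])
        return L, sigma_l
    return L
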