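import numpy as np
import pytest
from scipy.linalg import eigh, subspace_angles

from l12glpca import (
    InvalidConfigurationError,
    SolverConfig,
    build_g_beta,
    build_knn_graph,
    l12_norm,
    laplacian,
    objective,
    solve,
    solve_glpca,
    update_multipliers,
    update_s,
    update_u,
    update_v,
)
from l12glpca.thresholding import half_threshold_scalar

from conftest import random_orthonormal


def centered(A):
    return A - A.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------- update_s

def test_update_s_vanishing_threshold_limit(rng):
    X = rng.standard_normal((6, 4))
    V = random_orthonormal(rng, 4, 2)
    U = rng.standard_normal((6, 2))
    Lam = rng.standard_normal((6, 4))
    mu = 1e12
    S = update_s(X, U, V, Lam, mu)
    np.testing.assert_allclose(S, X - U @ V.T - Lam / mu, atol=1e-5)


def test_update_s_zero_residual_gives_zero(rng):
    V = random_orthonormal(rng, 4, 2)
    U = rng.standard_normal((6, 2))
    X = U @ V.T
    S = update_s(X, U, V, np.zeros((6, 4)), mu=1.0)
    np.testing.assert_array_equal(S, 0.0)


def test_update_s_matches_scalar_prox_oracle(rng):
    X = rng.standard_normal((5, 4)) * 3
    V = random_orthonormal(rng, 4, 2)
    U = rng.standard_normal((5, 2))
    Lam = rng.standard_normal((5, 4))
    mu = 0.8
    S = update_s(X, U, V, Lam, mu)
    B = X - U @ V.T - Lam / mu
    expected = np.array([[half_threshold_scalar(b, 2.0 / mu) for b in row]
                         for row in B])
    np.testing.assert_allclose(S, expected, rtol=1e-12)


def test_update_s_requires_positive_mu(rng):
    with pytest.raises(InvalidConfigurationError):
        update_s(np.zeros((2, 2)), np.zeros((2, 1)), np.eye(2)[:, :1],
                 np.zeros((2, 2)), mu=0.0)


# ---------------------------------------------------------------- update_u

def test_update_u_identity_embedding(rng):
    M = rng.standard_normal((5, 4))
    V = np.eye(4)[:, :2]
    np.testing.assert_array_equal(update_u(M, V), M[:, :2])
    np.testing.assert_array_equal(update_u(np.zeros((5, 4)), V), 0.0)


def test_update_u_is_least_squares_optimal(rng):
    M = rng.standard_normal((8, 5))
    V = random_orthonormal(rng, 5, 3)
    U = update_u(M, V)
    best = np.linalg.norm(M - U @ V.T)
    for _ in range(100):
        U_pert = U + 0.1 * rng.standard_normal(U.shape)
        assert best <= np.linalg.norm(M - U_pert @ V.T) + 1e-12


def test_update_u_shape_mismatch(rng):
    with pytest.raises(InvalidConfigurationError):
        update_u(rng.standard_normal((4, 3)), rng.standard_normal((5, 2)))


# ------------------------------------------------------------- build_g_beta

@pytest.fixture
def sample_graph(rng):
    M = centered(rng.standard_normal((30, 8)))
    g = build_knn_graph(M, n_neighbors=3)
    L, sigma_l = laplacian(g, return_largest_eigenvalue=True)
    return M, L, sigma_l


@pytest.mark.parametrize("beta", [0.0, 0.3, 0.5, 0.9, 1.0])
def test_g_beta_constant_eigenvector(sample_graph, beta):
    """Before deflation G_beta e = (1-beta) e for row-centred M; the
    deflation lifts that eigenvalue by exactly one."""
    M, L, sigma_l = sample_graph
    e = np.ones(8)
    G_raw = build_g_beta(M, L, beta, sigma_l=sigma_l, deflate=False)
    np.testing.assert_allclose(G_raw @ e, (1.0 - beta) * e, atol=1e-8)
    G = build_g_beta(M, L, beta, sigma_l=sigma_l)
    np.testing.assert_allclose(G @ e, (2.0 - beta) * e, atol=1e-8)


@pytest.mark.parametrize("beta", [0.0, 0.5, 1.0])
def test_g_beta_positive_semidefinite(sample_graph, beta):
    M, L, sigma_l = sample_graph
    G = build_g_beta(M, L, beta, sigma_l=sigma_l)
    assert eigh(G, eigvals_only=True)[0] >= -1e-8


def test_g_beta_zero_beta_substitution(rng):
    """With sigma_m scaled to 1, G_0 = I - M^T M + e e^T / n."""
    M = rng.standard_normal((20, 6))
    MtM = M.T @ M
    M = M / np.sqrt(eigh(MtM, eigvals_only=True)[-1])
    L = np.diag(np.ones(6))  # irrelevant at beta=0
    G = build_g_beta(M, L, 0.0, sigma_l=1.0)
    np.testing.assert_allclose(
        G, np.eye(6) - M.T @ M + np.ones((6, 6)) / 6, atol=1e-10)


def test_g_beta_zero_m_falls_back_with_warning():
    L = np.array([[1.0, -1.0], [-1.0, 1.0]])
    with pytest.warns(RuntimeWarning):
        G = build_g_beta(np.zeros((5, 2)), L, 0.5, sigma_l=2.0)
    np.testing.assert_allclose(G, 0.5 * L / 2.0 + np.ones((2, 2)) / 2)


# ----------------------------------------------------------------- update_v

def test_update_v_diagonal_case():
    G = np.diag([1.0, 2.0, 3.0, 4.0])
    V = update_v(G, 2)
    np.testing.assert_allclose(np.abs(V), np.eye(4)[:, :2], atol=1e-12)


def test_update_v_orthonormal_and_matches_eigh_oracle(rng):
    A = rng.standard_normal((7, 7))
    G = A + A.T
    V = update_v(G, 3)
    np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-8)
    _, vecs = eigh(G)
    assert np.max(subspace_angles(V, vecs[:, :3])) < 1e-6
    # deterministic sign convention: largest-magnitude entry positive
    for j in range(3):
        assert V[np.argmax(np.abs(V[:, j])), j] > 0


def test_update_v_k_too_large(rng):
    with pytest.raises(InvalidConfigurationError):
        update_v(np.eye(4), 4)


# ------------------------------------------------------- update_multipliers

def test_multiplier_update_rules(rng):
    V = random_orthonormal(rng, 4, 2)
    U = rng.standard_normal((6, 2))
    X = U @ V.T
    Lam = rng.standard_normal((6, 4))
    S = X - U @ V.T  # zero residual
    Lam2, mu2 = update_multipliers(Lam, 0.3, S, X, U, V, rho=1.2)
    np.testing.assert_allclose(Lam2, Lam)
    assert mu2 == pytest.approx(0.36)

    S = rng.standard_normal((6, 4))
    Lam2, _ = update_multipliers(np.zeros((6, 4)), 1.0, S, X, U, V, rho=1.5)
    np.testing.assert_allclose(Lam2, S - X + U @ V.T)
    with pytest.raises(InvalidConfigurationError):
        update_multipliers(Lam, 1.0, S, X, U, V, rho=1.0)


# ---------------------------------------------------------------- objective

def test_objective_values(rng):
    V = random_orthonormal(rng, 4, 2)
    U = rng.standard_normal((6, 2))
    X = U @ V.T
    L = np.eye(4)
    assert objective(X, U, V, L, 0.0) == pytest.approx(0.0)

    # residual entries {1, 4}: sum of square roots is 1 + 2 = 3
    X2 = np.array([[1.0, 0.0], [0.0, 4.0]])
    U2 = np.zeros((2, 1))
    V2 = np.eye(2)[:, :1]
    assert objective(X2, U2, V2, np.zeros((2, 2)), 0.0) == pytest.approx(3.0)

    X3 = rng.standard_normal((6, 4))
    L3 = np.diag(rng.uniform(1, 2, 4))
    alpha = 0.7
    expected = (np.sqrt(np.abs(X3 - U @ V.T)).sum()
                + alpha * np.trace(V.T @ L3 @ V))
    assert objective(X3, U, V, L3, alpha) == pytest.approx(expected)
    assert l12_norm(X2) == pytest.approx(3.0)


# ------------------------------------------------------------------- solver

def test_glpca_beta0_recovers_pca_subspace(rng):
    X = centered(rng.standard_normal((200, 10)))
    cfg = SolverConfig(k=3, beta=0.0, n_neighbors=3)
    d = solve_glpca(X, cfg)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    assert np.max(subspace_angles(d.V, Vt[:3].T)) < 1e-6


def test_glpca_beta1_recovers_laplacian_embedding(rng):
    X = centered(rng.standard_normal((200, 10)))
    cfg = SolverConfig(k=3, beta=1.0, n_neighbors=3)
    d = solve_glpca(X, cfg)
    g = build_knn_graph(X, n_neighbors=3)
    w, vecs = eigh(g.L)
    assert np.sum(w < 1e-10) == 1  # connected graph: unique null vector
    oracle = vecs[:, 1:4]  # bottom-k nontrivial eigenvectors
    assert np.max(subspace_angles(d.V, oracle)) < 1e-6


def test_glpca_objective_beats_random_subspaces(rng):
    X = centered(rng.standard_normal((60, 12)))
    cfg = SolverConfig(k=3, beta=0.5, n_neighbors=4)
    d = solve_glpca(X, cfg)
    g = build_knn_graph(X, n_neighbors=4)
    L = g.L
    sigma_m = eigh(X.T @ X, eigvals_only=True)[-1]
    sigma_l = eigh(L, eigvals_only=True)[-1]
    alpha = (0.5 / 0.5) * sigma_m / sigma_l

    def eq4(V):
        U = X @ V
        return (np.linalg.norm(X - U @ V.T) ** 2
                + alpha * np.trace(V.T @ L @ V))

    best = eq4(d.V)
    for _ in range(50):
        assert best <= eq4(random_orthonormal(rng, 12, 3)) + 1e-8


def test_solve_noiseless_low_rank_recovery(rng):
    U0 = rng.standard_normal((100, 4))
    V0 = random_orthonormal(rng, 12, 4)
    X = centered(U0 @ V0.T)
    cfg = SolverConfig(k=4, beta=0.2, n_neighbors=4)
    d = solve(X, cfg)
    rel = np.linalg.norm(X - d.U @ d.V.T - d.S) / np.linalg.norm(X)
    assert rel < 1e-3
    assert d.converged


def test_solve_traces_and_constraints(rng):
    X = rng.standard_normal((80, 10)) + 3 * rng.standard_normal((80, 1))
    cfg = SolverConfig(k=3, beta=0.5, n_neighbors=3)
    d = solve(X, cfg)
    # V orthonormal at every iteration
    assert np.max(d.orthonormality_trace) < 1e-8
    # residual trend: geometric mu growth drives the constraint residual
    # down over the last 10 iterations
    tail = d.residual_trace[-10:]
    assert np.all(np.diff(tail) < 0)
    assert d.residual_trace[-1] <= cfg.tol


def test_solve_is_deterministic(rng):
    X = rng.standard_normal((50, 8))
    cfg = SolverConfig(k=2, beta=0.4, n_neighbors=3)
    d1 = solve(X, cfg)
    d2 = solve(X, cfg)
    np.testing.assert_array_equal(d1.U, d2.U)
    np.testing.assert_array_equal(d1.objective_trace, d2.objective_trace)
    np.testing.assert_array_equal(d1.residual_trace, d2.residual_trace)


def test_solver_config_validation():
    with pytest.raises(InvalidConfigurationError):
        SolverConfig(beta=1.5)
    with pytest.raises(InvalidConfigurationError):
        SolverConfig(rho=0.9)
    with pytest.raises(InvalidConfigurationError):
        SolverConfig(mu0=-1.0)
    with pytest.raises(InvalidConfigurationError):
        SolverConfig(k=0)


def test_non_finite_input_rejected():
    X = np.full((10, 5), np.nan)
    with pytest.raises(ValueError):
        solve(X, SolverConfig(k=2, n_neighbors=2))
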