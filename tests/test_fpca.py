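"""FPCA core: smoothing, covariance, eigensystem, scores, embedding.

Derived expectations are computed by independent dense-grid / dense-linear-
algebra oracles inside the tests.
"""

import warnings

import numpy as np
import pytest

from scfpcde import (
    BSplineBasis,
    EigenSystem,
    ExpressionMatrix,
    PseudotimeAxis,
    cell_embedding,
    center_and_transform,
    eigendecompose,
    estimate_covariance,
    project_scores,
    smooth_trajectories,
)
from scfpcde.fpca import CovarianceSurface

from conftest import l2_orthonormal_damped_curves


# ---------------------------------------------------------------------------
# center_and_transform
# ---------------------------------------------------------------------------
def test_log_transform_and_centering_examples():
    e = np.e
    expr = ExpressionMatrix(
        np.array([[0.0, 0.0, 0.0], [0.0, e - 1, e**2 - 1], [5.0, 5.0, 5.0]]),
        np.array(["a", "b", "c"]),
        np.array(["c1", "c2", "c3"]),
        scale="counts",
    )
    out, means, const = center_and_transform(expr, pseudo_count=1.0)
    assert np.allclose(out.values[0], 0.0)
    assert np.allclose(out.values[1], [-1.0, 0.0, 1.0])
    assert np.allclose(out.values[2], 0.0)  # constants center to zero
    assert const.tolist() == [True, False, True]
    assert np.allclose(out.values.mean(axis=1), 0.0)
    assert means[1] == pytest.approx(1.0)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ExpressionMatrix(
            np.array([[-1.0, 2.0]]), np.array(["g"]), np.array(["a", "b"]),
            scale="counts",
        )


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------
def test_constant_gene_fits_constant(basis, small_axis):
    expr = ExpressionMatrix(
        np.full((1, 40), 3.7), np.array(["g"]), small_axis.cell_ids, scale="log"
    )
    centered, means, _ = center_and_transform(expr)
    sm = smooth_trajectories(centered, small_axis, basis, lam=5.0,
                             gene_means=means)
    grid = np.linspace(0, 1, 61)
    assert np.allclose(sm.evaluate(grid, centered=False), 3.7, atol=1e-9)


def test_huge_lambda_converges_to_least_squares_line(basis, small_axis, rng):
    y = 2.0 * small_axis.t - 0.7 + rng.normal(0, 0.3, size=40)
    expr = ExpressionMatrix(y[None, :] - y.mean(), np.array(["g"]),
                            small_axis.cell_ids, scale="log-centered")
    # analytic limit of a curvature penalty: the OLS straight line
    X = np.column_stack([np.ones(40), small_axis.t])
    beta = np.linalg.lstsq(X, expr.values[0], rcond=None)[0]
    sm = smooth_trajectories(expr, small_axis, basis, lam=1e6)
    err = np.max(np.abs(sm.evaluate(small_axis.t)[0] - X @ beta))
    assert err < 1e-5


def test_smoother_matches_dense_normal_equations_oracle(basis, rng):
    """Shared-smoother path == per-gene dense penalized least squares."""
    t = np.sort(rng.uniform(0, 1, 20))
    t[0], t[-1] = 0.0, 1.0
    axis = PseudotimeAxis(np.array([f"c{j}" for j in range(20)]), t)
    Y = rng.normal(size=(5, 20))
    Y -= Y.mean(axis=1, keepdims=True)
    expr = ExpressionMatrix(Y, np.array([f"g{i}" for i in range(5)]),
                            axis.cell_ids, scale="log-centered")
    lam = 0.1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm = smooth_trajectories(expr, axis, basis, lam=lam)
    B = basis.design(axis.t)
    P = basis.penalty()
    A = B.T @ B + lam * P
    for i in range(5):
        oracle = np.linalg.solve(A, B.T @ Y[i])
        assert np.allclose(sm.coef[i], oracle, atol=1e-8)


def test_smoother_invariant_to_cell_permutation(basis, small_axis, rng):
    Y = rng.normal(size=(6, 40))
    Y -= Y.mean(axis=1, keepdims=True)
    ids = small_axis.cell_ids
    expr = ExpressionMatrix(Y, np.array([f"g{i}" for i in range(6)]), ids,
                            scale="log-centered")
    sm = smooth_trajectories(expr, small_axis, basis, lam=0.05)
    perm = rng.permutation(40)
    axis_p = PseudotimeAxis(ids[perm], small_axis.t[perm])
    expr_p = ExpressionMatrix(Y[:, perm], expr.gene_ids, ids[perm],
                              scale="log-centered")
    sm_p = smooth_trajectories(expr_p, axis_p, basis, lam=0.05)
    assert np.allclose(sm.coef, sm_p.coef, atol=1e-10)


def test_gcv_selects_finite_lambda(small_smoothed):
    assert np.isfinite(small_smoothed.lam)


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------
def test_covariance_is_scaled_gram_of_coefficients(small_smoothed):
    A = small_smoothed.coef
    oracle = A.T @ A / A.shape[0]
    cov = estimate_covariance(small_smoothed)
    assert np.allclose(cov.M, oracle, atol=1e-12)
    assert np.allclose(cov.M, cov.M.T)
    # PSD up to round-off
    assert np.linalg.eigvalsh(cov.M).min() > -1e-10


def test_covariance_rank_one_and_sign_invariance(basis, small_smoothed):
    c = small_smoothed.coef[:1]
    sm1 = small_smoothed
    sm1.coef = c
    cov1 = None
    with pytest.warns(UserWarning):
        cov1 = estimate_covariance(sm1)
    assert np.allclose(cov1.M, np.outer(c[0], c[0]))
    # pairs (f, -f) give the same covariance as the unpaired set
    sm1.coef = np.vstack([c, -c])
    cov2 = estimate_covariance(sm1)
    assert np.allclose(cov2.M, cov1.M)


# ---------------------------------------------------------------------------
# eigendecomposition
# ---------------------------------------------------------------------------
def test_rank_one_covariance_eigenpair(basis):
    W = basis.gram()
    f = np.linspace(-1, 1, basis.n_basis)  # arbitrary coefficient vector
    cov = CovarianceSurface(M=np.outer(f, f), basis=basis, n_genes_used=1)
    eig = eigendecompose(cov, n_components=1)
    norm2 = f @ W @ f
    assert eig.eigenvalues[0] == pytest.approx(norm2, rel=1e-10)
    assert eig.var_explained[0] == pytest.approx(1.0)
    ratio = eig.coef[:, 0] * np.sqrt(norm2) / f
    assert np.allclose(np.abs(ratio), 1.0, atol=1e-8)


def test_eigenfunctions_orthonormal(small_smoothed):
    eig = eigendecompose(estimate_covariance(small_smoothed), n_components=5)
    W = small_smoothed.basis.gram()
    gram = eig.coef.T @ W @ eig.coef
    assert np.allclose(gram, np.eye(eig.L), atol=1e-8)
    assert np.all(np.diff(eig.eigenvalues) <= 1e-12)
    assert np.all(np.diff(eig.var_explained) >= -1e-12)
    assert eig.var_explained[-1] <= 1 + 1e-9


def test_known_spectrum_vs_dense_grid_oracle(basis):
    """Weighted damped-curve covariance vs a 501-point trapezoid oracle."""
    coef, w = l2_orthonormal_damped_curves(basis)
    M = (coef * w[None, :]) @ coef.T
    eig = eigendecompose(CovarianceSurface(M, basis, 3), n_components=3)
    assert np.allclose(eig.eigenvalues, w, rtol=1e-8)

    grid = np.linspace(0, 1, 501)
    d = basis.design(grid)
    C = d @ M @ d.T
    # discretized integral operator, symmetrized by sqrt trapezoid weights
    tw = np.full(501, grid[1] - grid[0])
    tw[[0, -1]] /= 2
    s = np.sqrt(tw)
    vals, vecs = np.linalg.eigh(s[:, None] * C * s[None, :])
    vals = vals[::-1][:3]
    vecs = vecs[:, ::-1][:, :3] / s[:, None]
    assert np.allclose(eig.eigenvalues, vals, rtol=1e-4)
    eig_grid = eig.evaluate(grid)
    for k in range(3):
        oracle_fn = vecs[:, k] / np.sqrt(np.sum(tw * vecs[:, k] ** 2))
        align = abs(np.sum(tw * oracle_fn * eig_grid[:, k]))
        assert align == pytest.approx(1.0, abs=1e-4)


def test_variance_bookkeeping(small_smoothed):
    cov = estimate_covariance(small_smoothed)
    eig = eigendecompose(cov, n_components="variance", var_threshold=1.0,
                         max_components=small_smoothed.basis.n_basis)
    assert np.sum(eig.eigenvalues) == pytest.approx(eig.total_variance, abs=1e-6)
    # total variance equals the integrated trace of the covariance surface
    grid = np.linspace(0, 1, 4001)
    d = small_smoothed.basis.design(grid)
    diag = np.einsum("ja,ab,jb->j", d, cov.M, d)
    assert np.trapezoid(diag, grid) == pytest.approx(eig.total_variance, rel=1e-6)


def test_eigenfunction_sign_rule_is_deterministic(small_smoothed):
    eig1 = eigendecompose(estimate_covariance(small_smoothed), n_components=4)
    eig2 = eigendecompose(estimate_covariance(small_smoothed), n_components=4)
    assert np.array_equal(eig1.coef, eig2.coef)
    tm = small_smoothed.basis.time_moment()
    assert np.all(eig1.coef.T @ tm >= -1e-10)


def test_requested_components_truncated_to_rank(basis):
    f = np.linspace(0.5, 1.5, basis.n_basis)
    cov = CovarianceSurface(np.outer(f, f), basis, 1)
    with pytest.warns(UserWarning, match="rank"):
        eig = eigendecompose(cov, n_components=5)
    assert eig.L == 1


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------
def test_zero_function_and_basis_alignment_scores(basis, small_smoothed):
    eig = eigendecompose(estimate_covariance(small_smoothed), n_components=3)
    sm = small_smoothed
    sm.coef = np.vstack([np.zeros(basis.n_basis), 3.0 * eig.coef[:, 0]])
    sm.gene_ids = np.array(["zero", "aligned"])
    scores = project_scores(sm, eig)
    assert np.allclose(scores.xi[0], 0.0, atol=1e-12)
    assert np.allclose(scores.xi[1], [3.0, 0.0, 0.0], atol=1e-8)


def test_scores_match_dense_quadrature_oracle(small_smoothed):
    eig = eigendecompose(estimate_covariance(small_smoothed), n_components=4)
    scores = project_scores(small_smoothed, eig)
    grid = np.linspace(0, 1, 2001)
    f = small_smoothed.evaluate(grid)
    phi = eig.evaluate(grid)
    oracle = np.trapezoid(f[:, :, None] * phi[None, :, :], grid, axis=1)
    assert np.allclose(scores.xi, oracle, atol=1e-6)


def test_basis_mismatch_rejected(small_smoothed):
    other = BSplineBasis(8, order=4)
    eig = EigenSystem(
        coef=np.zeros((8, 2)), eigenvalues=np.zeros(2),
        var_explained=np.zeros(2), basis=other, total_variance=0.0,
    )
    with pytest.raises(ValueError):
        project_scores(small_smoothed, eig)


def test_karhunen_loeve_optimality(small_smoothed, rng):
    """Top-L eigenfunctions beat 50 random orthonormal L-dim bases."""
    W = small_smoothed.basis.gram()
    A = small_smoothed.coef
    L = 3
    eig = eigendecompose(estimate_covariance(small_smoothed), n_components=L)
    total = np.einsum("ik,kl,il->i", A, W, A).sum()

    def retained(U):
        xi = A @ W @ U
        return np.sum(xi**2)

    best = retained(eig.coef)
    K = small_smoothed.basis.n_basis
    for _ in range(50):
        U = rng.normal(size=(K, L))
        for k in range(L):  # Gram-Schmidt in the L2 inner product
            for j in range(k):
                U[:, k] -= (U[:, j] @ W @ U[:, k]) * U[:, j]
            U[:, k] /= np.sqrt(U[:, k] @ W @ U[:, k])
        assert total - best <= total - retained(U) + 1e-9


def test_score_variances_recover_generating_weights(basis, rng):
    """Noise-free genes with known score variances on a fixed basis."""
    coef, w = l2_orthonormal_damped_curves(basis)
    G = 4000
    xi = rng.standard_normal((G, 3)) * np.sqrt(w)
    sm_coef = xi @ coef.T
    sm = _smoothed_stub(basis, sm_coef)
    eig = eigendecompose(estimate_covariance(sm), n_components=3)
    scores = project_scores(sm, eig)
    var = scores.xi.var(axis=0)
    # Monte-Carlo error of a sample variance is ~ w_k * sqrt(2/G)
    assert np.allclose(var, w, rtol=4 * np.sqrt(2 / G))


def _smoothed_stub(basis, coef):
    from scfpcde import SmoothedTrajectories

    G = coef.shape[0]
    return SmoothedTrajectories(
        coef=coef, basis=basis, gene_means=np.zeros(G),
        gene_ids=np.array([f"g{i}" for i in range(G)]),
        t=np.linspace(0, 1, 11), lam=0.0,
        smoother=np.zeros((basis.n_basis, 11)),
    )


# ---------------------------------------------------------------------------
# cell embedding
# ---------------------------------------------------------------------------
def test_embedding_inverts_exact_factorization(basis, rng):
    coef, w = l2_orthonormal_damped_curves(basis)
    t = np.linspace(0, 1, 30)
    axis = PseudotimeAxis(np.array([f"c{j}" for j in range(30)]), t)
    G = 200
    xi = rng.standard_normal((G, 3)) * np.sqrt(w)
    sm = _smoothed_stub(basis, xi @ coef.T)
    eig = eigendecompose(estimate_covariance(sm), n_components=3)
    scores = project_scores(sm, eig)
    # noiseless data Y = Ξ Φ(t)
    Y = scores.xi @ eig.evaluate(t).T
    expr = ExpressionMatrix(Y, sm.gene_ids, axis.cell_ids, scale="log-centered")
    coords, field = cell_embedding(expr, scores, eig, axis=axis)
    assert np.allclose(coords, eig.evaluate(t), atol=1e-6)
    # derivative field matches the dense finite-difference oracle
    h = 1e-6
    fd = (eig.evaluate(np.clip(t + h, 0, 1)) - eig.evaluate(np.clip(t - h, 0, 1)))
    span = np.clip(t + h, 0, 1) - np.clip(t - h, 0, 1)
    assert np.allclose(field, fd / span[:, None], atol=1e-4)


def test_embedding_matches_least_squares_oracle(small_smoothed, rng):
    eig = eigendecompose(estimate_covariance(small_smoothed), n_components=3)
    scores = project_scores(small_smoothed, eig)
    Y = rng.normal(size=(small_smoothed.n_genes, 15))
    expr = ExpressionMatrix(
        Y - Y.mean(axis=1, keepdims=True), small_smoothed.gene_ids,
        np.array([f"c{j}" for j in range(15)]), scale="log-centered",
    )
    coords, _ = cell_embedding(expr, scores, eig)
    for j in range(15):
        oracle = np.linalg.lstsq(scores.xi, expr.values[:, j], rcond=None)[0]
        assert np.allclose(coords[j], oracle, atol=1e-8)


# ---------------------------------------------------------------------------
# pseudotime axis
# ---------------------------------------------------------------------------
def test_pseudotime_rescaled_to_unit_interval():
    axis = PseudotimeAxis(np.array(["a", "b", "c"]), np.array([2.0, 4.0, 6.0]))
    assert np.allclose(axis.t, [0.0, 0.5, 1.0])


def test_degenerate_pseudotime_rejected():
    with pytest.raises(ValueError, match="identical"):
        PseudotimeAxis(np.array(["a", "b"]), np.array([3.0, 3.0]))
    with pytest.raises(ValueError, match="finite"):
        PseudotimeAxis(np.array(["a", "b"]), np.array([0.0, np.nan]))
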