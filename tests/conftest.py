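"""Shared fixtures: small synthetic instances built at test time."""

import numpy as np
import pytest

from scfpcde import (
    BSplineBasis,
    ExpressionMatrix,
    PseudotimeAxis,
    center_and_transform,
    smooth_trajectories,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def basis():
    return BSplineBasis(10, order=4, penalty_order=2)


@pytest.fixture
def small_axis():
    t = np.linspace(0.0, 1.0, 40)
    return PseudotimeAxis(np.array([f"c{j}" for j in range(40)]), t)


@pytest.fixture
def small_smoothed(rng, basis, small_axis):
    """20 random log-scale genes smoothed on a 40-cell grid."""
    values = rng.normal(size=(20, 40)) + rng.normal(size=(20, 1))
    expr = ExpressionMatrix(
        values,
        np.array([f"g{i}" for i in range(20)]),
        small_axis.cell_ids,
        scale="log",
    )
    centered, gene_means, _ = center_and_transform(expr)
    return smooth_trajectories(centered, small_axis, basis, lam=0.1,
                               gene_means=gene_means)


def l2_orthonormal_damped_curves(basis, weights=(1.0, 0.5, 0.25)):
    """Spline-space construction of the three damped mean-curve patterns,
    time-mean-centered and Gram-Schmidt orthonormalized in L2.

    Returns (coef, weights): coef is n_basis × 3, columns W-orthonormal.
    Used as a known eigenstructure for recovery tests.
    """
    from scfpcde import basis_functions

    W = basis.gram()
    grid = np.linspace(0, 1, 4001)
    design = basis.design(grid)
    phi = basis_functions(grid)  # 3 × grid
    # least-squares spline representation of each curve
    coef, *_ = np.linalg.lstsq(design, phi.T, rcond=None)
    # remove the time mean: the constant function has coefficient vector 1
    ones = np.ones(basis.n_basis)
    means = ones @ W @ coef  # ∫ φ_k dt  (since ∫ b_a = ones·W column sums)
    coef = coef - np.outer(ones, means)
    # Gram-Schmidt in the L2 inner product <u, v> = uᵀ W v
    for k in range(coef.shape[1]):
        for j in range(k):
            coef[:, k] -= (coef[:, j] @ W @ coef[:, k]) * coef[:, j]
        coef[:, k] /= np.sqrt(coef[:, k] @ W @ coef[:, k])
    return coef, np.asarray(weights, dtype=float)
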