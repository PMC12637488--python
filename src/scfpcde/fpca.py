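"""Functional PCA of gene expression trajectories along pseudotime.

Each gene's log-transformed, mean-centered expression is represented as a
penalized B-spline function of pseudotime.  The sample covariance operator
of these functions is eigendecomposed in the spline basis, yielding
eigenfunctions (dominant pseudo-temporal modes), eigenvalues (variance per
mode) and per-gene functional principal component (FPC) scores.

The eigenproblem ∫ C(s,t) Φ_k(s) ds = λ_k Φ_k(t) is solved in coefficient
space: with covariance coefficient matrix M and basis Gram matrix W = L Lᵀ,
the symmetrized problem Lᵀ M L v = λ v gives eigenfunction coefficients
u = L^{-T} v that are orthonormal in L2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh, solve_triangular

from .basis import BSplineBasis

__all__ = [
    "PseudotimeAxis",
    "ExpressionMatrix",
    "SmoothedTrajectories",
    "CovarianceSurface",
    "EigenSystem",
    "FPCScores",
    "center_and_transform",
    "smooth_trajectories",
    "estimate_covariance",
    "eigendecompose",
    "project_scores",
    "cell_embedding",
]

_DEFAULT_GCV_GRID = np.logspace(-8, 2, 21)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class PseudotimeAxis:
    """Per-cell pseudotime, affinely rescaled to [0, 1].

    Pseudotime is produced upstream (e.g. by a trajectory-inference tool)
    and treated as given.  ``cluster`` is an optional categorical label
    carried through for plotting.
    """

    cell_ids: np.ndarray
    t: np.ndarray
    cluster: Optional[np.ndarray] = None

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        t = np.asarray(self.t, dtype=float)
        if t.shape[0] != self.cell_ids.shape[0]:
            raise ValueError("pseudotime and cell_ids lengths differ")
        if not np.all(np.isfinite(t)):
            raise ValueError("pseudotime values must be finite")
        lo, hi = t.min(), t.max()
        if hi > lo:
            t = (t - lo) / (hi - lo)
        elif t.size > 1:
            raise ValueError(
                "all pseudotime values are identical; a degenerate axis "
                "carries no ordering information"
            )
        self.t = t

    def __len__(self):
        return self.t.shape[0]


@dataclass
class ExpressionMatrix:
    """Genes × cells expression values with an explicit scale flag."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale: str = "counts"  # "counts" | "log" | "log-centered"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes × cells)")
        g, n = self.values.shape
        if g != self.gene_ids.shape[0] or n != self.cell_ids.shape[0]:
            raise ValueError("expression dimensions do not match gene/cell ids")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        if self.scale == "counts" and np.any(self.values < 0):
            raise ValueError("negative values are not valid counts")

    @property
    def n_genes(self):
        return self.values.shape[0]

    @property
    def n_cells(self):
        return self.values.shape[1]


@dataclass
class SmoothedTrajectories:
    """Per-gene B-spline coefficient representation of log expression.

    ``coef[i] @ basis.design(t).T`` reconstructs gene i's centered smooth
    trajectory; adding ``gene_means[i]`` restores the log-scale level.
    ``smoother`` is the shared (n_basis × n_cells) penalized least-squares
    operator: because all genes share one pseudotime grid it is factored
    once and applied to every gene by matrix multiplication.
    """

    coef: np.ndarray
    basis: BSplineBasis
    gene_means: np.ndarray
    gene_ids: np.ndarray
    t: np.ndarray
    lam: float
    smoother: np.ndarray = field(repr=False)

    @property
    def n_genes(self):
        return self.coef.shape[0]

    def evaluate(self, tgrid, centered=True):
        """Evaluate smoothed trajectories on a pseudotime grid."""
        vals = self.coef @ self.basis.design(tgrid).T
        if not centered:
            vals = vals + self.gene_means[:, None]
        return vals


@dataclass
class CovarianceSurface:
    """Pseudotime covariance kernel C(s,t) in the tensor spline basis.

    ``C(s, t) = b(s)ᵀ M b(t)`` with symmetric PSD coefficient matrix M.
    """

    M: np.ndarray
    basis: BSplineBasis
    n_genes_used: int

    def evaluate(self, s, t):
        bs = self.basis.design(s)
        bt = self.basis.design(t)
        return bs @ self.M @ bt.T


@dataclass
class EigenSystem:
    """Eigenfunctions and eigenvalues of the pseudotime covariance operator.

    ``coef[:, k]`` holds the spline coefficients of Φ_k; eigenfunctions are
    L2-orthonormal and signed so that ∫ Φ_k(t)·t dt >= 0.
    """

    coef: np.ndarray  # n_basis × L
    eigenvalues: np.ndarray  # length L, descending
    var_explained: np.ndarray  # cumulative fraction, length L
    basis: BSplineBasis
    total_variance: float

    @property
    def L(self):
        return self.coef.shape[1]

    def evaluate(self, tgrid, deriv=0):
        """Eigenfunction (or derivative) values, shape (len(tgrid), L)."""
        return self.basis.design(tgrid, deriv=deriv) @ self.coef


@dataclass
class FPCScores:
    """Genes × L matrix of FPC scores ξ_ik = ∫ f_i(t) Φ_k(t) dt."""

    xi: np.ndarray
    gene_ids: np.ndarray

    @property
    def L(self):
        return self.xi.shape[1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------
def center_and_transform(expr, pseudo_count=1.0):
    """Log-transform counts and center each gene at functional mean zero.

    Counts are mapped through ``log(x + pseudo_count)``; pre-logged input
    (``scale="log"``) is centered only.  Returns the centered matrix, the
    per-gene means removed (for reconstruction) and a flag marking genes
    that were constant across cells (these carry no trajectory information
    and yield all-zero rows).
    """
    if expr.scale == "counts":
        logged = np.log(expr.values + pseudo_count)
    elif expr.scale == "log":
        logged = expr.values.copy()
    else:
        raise ValueError(f"cannot transform data already on scale {expr.scale!r}")
    gene_means = logged.mean(axis=1)
    centered = logged - gene_means[:, None]
    is_constant = np.ptp(logged, axis=1) == 0.0
    # constant rows are exactly zero after centering (not just to round-off)
    centered[is_constant] = 0.0
    out = ExpressionMatrix(
        centered, expr.gene_ids, expr.cell_ids, scale="log-centered"
    )
    return out, gene_means, is_constant


def _smoother_matrix(design, penalty, lam):
    """(n_basis × n_cells) operator mapping a data row to spline coefficients."""
    A = design.T @ design + lam * penalty
    try:
        c, low = cho_factor(A)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "singular penalized normal equations; increase the roughness "
            "penalty lambda or reduce n_basis relative to the number of "
            "distinct pseudotime values"
        ) from err
    smoother = cho_solve((c, low), design.T)
    edf = np.trace(cho_solve((c, low), design.T @ design))
    return smoother, edf


def gcv_select_lambda(Y, design, penalty, grid=None):
    """Pick the roughness penalty weight by generalized cross-validation.

    One λ is shared across genes: GCV(λ) = n · RSS(λ) / (n − edf(λ))²,
    with RSS pooled over genes and edf the trace of the hat matrix.
    """
    if grid is None:
        grid = _DEFAULT_GCV_GRID
    n = design.shape[0]
    best = (np.inf, None)
    for lam in np.asarray(grid, dtype=float):
        try:
            smoother, edf = _smoother_matrix(design, penalty, lam)
        except np.linalg.LinAlgError:
            continue
        if edf >= n:
            continue
        fitted = (Y @ smoother.T) @ design.T
        rss = float(((Y - fitted) ** 2).sum())
        score = n * rss / (n - edf) ** 2
        if score < best[0]:
            best = (score, float(lam))
    if best[1] is None:
        raise np.linalg.LinAlgError(
            "GCV failed for every candidate lambda; the smoothing problem "
            "is singular (too few distinct pseudotime values for n_basis)"
        )
    return best[1]


def smooth_trajectories(expr_log_centered, axis, basis, lam="gcv", gcv_grid=None,
                        gene_means=None):
    """Fit each gene's centered log expression as a penalized spline of t.

    Per gene the coefficients minimize
    Σ_j (Y_i(t_j) − f_i(t_j))² + λ ∫ (f_i^(m)(t))² dt.
    With ``lam="gcv"`` (default) λ is chosen by generalized cross-validation
    on a log-spaced grid, pooled across genes.
    """
    if expr_log_centered.scale != "log-centered":
        raise ValueError("smooth_trajectories expects log-centered expression")
    if not np.array_equal(expr_log_centered.cell_ids, axis.cell_ids):
        raise ValueError("expression columns and pseudotime axis disagree")
    n_distinct = np.unique(axis.t).size
    if n_distinct < basis.n_basis:
        warnings.warn(
            f"only {n_distinct} distinct pseudotime values for "
            f"{basis.n_basis} basis functions; the fit relies on the "
            "roughness penalty for identifiability",
            stacklevel=2,
        )
    design = basis.design(axis.t)
    penalty = basis.penalty()
    Y = expr_log_centered.values
    if lam == "gcv":
        lam = gcv_select_lambda(Y, design, penalty, grid=gcv_grid)
    lam = float(lam)
    if lam < 0:
        raise ValueError("roughness penalty weight must be >= 0")
    smoother, _ = _smoother_matrix(design, penalty, lam)
    coef = Y @ smoother.T
    if gene_means is None:
        gene_means = np.zeros(expr_log_centered.n_genes)
    return SmoothedTrajectories(
        coef=coef,
        basis=basis,
        gene_means=np.asarray(gene_means, dtype=float),
        gene_ids=expr_log_centered.gene_ids,
        t=axis.t,
        lam=lam,
        smoother=smoother,
    )


def estimate_covariance(smoothed, gene_subset=None):
    """Sample covariance surface C(s,t) = (1/G) Σ_i f_i(s) f_i(t).

    Genes are already mean-centered functions, so no further centering is
    applied.  ``gene_subset`` restricts the sum (used by the
    trajectory-informative-gene refinement)."""
    A = smoothed.coef if gene_subset is None else smoothed.coef[gene_subset]
    g = A.shape[0]
    if g == 0:
        raise ValueError("covariance requires at least one gene")
    if g == 1:
        warnings.warn("covariance from a single gene is rank-1", stacklevel=2)
    M = A.T @ A / g
    M = (M + M.T) / 2.0
    return CovarianceSurface(M=M, basis=smoothed.basis, n_genes_used=g)


def eigendecompose(cov, n_components="variance", var_threshold=0.9,
                   max_components=10):
    """Solve the functional eigenproblem of the covariance operator.

    ``n_components`` is either an integer L or ``"variance"``: retain the
    smallest L whose cumulative explained-variance fraction reaches
    ``var_threshold`` (capped at ``max_components`` and at the numerical
    rank).  Eigenfunctions come back L2-orthonormal, eigenvalues sorted
    descending, each eigenfunction signed so ∫ Φ_k(t)·t dt >= 0 (ties by
    the sign of Φ_k(0)) for run-to-run determinism.
    """
    basis = cov.basis
    W = basis.gram()
    Lw = cholesky(W, lower=True)
    T = Lw.T @ cov.M @ Lw
    vals, vecs = eigh((T + T.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]

    total = float(np.trace(cov.M @ W))
    rank = int(np.sum(vals > max(vals[0], 0.0) * 1e-12)) if vals[0] > 0 else 0

    if rank == 0:
        warnings.warn(
            "covariance operator is numerically zero; returning a single "
            "zero-variance component",
            stacklevel=2,
        )
        L = 1
    elif n_components == "variance":
        cum = np.cumsum(vals) / total if total > 0 else np.ones_like(vals)
        L = int(np.searchsorted(cum, var_threshold) + 1)
        L = min(L, max_components, rank)
    else:
        L = int(n_components)
        if L > rank:
            warnings.warn(
                f"requested {L} components but numerical rank is {rank}; "
                "truncating",
                stacklevel=2,
            )
            L = rank
    L = max(L, 1)

    U = solve_triangular(Lw, vecs[:, :L], trans="T", lower=True)
    # deterministic sign: positive projection onto t, ties by value at 0
    tm = basis.time_moment()
    proj = U.T @ tm
    at0 = (basis.design(np.array([0.0])) @ U).ravel()
    signs = np.where(np.abs(proj) > 1e-10, np.sign(proj), np.sign(at0))
    signs[signs == 0] = 1.0
    U = U * signs[None, :]

    lam = vals[:L]
    var_explained = (
        np.cumsum(lam) / total if total > 0 else np.zeros(L)
    )
    return EigenSystem(
        coef=U,
        eigenvalues=lam,
        var_explained=var_explained,
        basis=basis,
        total_variance=total,
    )


def project_scores(smoothed, eig):
    """FPC scores ξ_ik = ∫ f_i(t) Φ_k(t) dt via the basis Gram matrix.

    The resulting rank-L reconstruction Σ_k ξ_ik Φ_k is the L2-optimal
    approximation of f_i within the span of the retained eigenfunctions.
    """
    if smoothed.basis != eig.basis:
        raise ValueError("smoothed trajectories and eigensystem use different bases")
    W = smoothed.basis.gram()
    xi = smoothed.coef @ W @ eig.coef
    return FPCScores(xi=xi, gene_ids=smoothed.gene_ids)


def cell_embedding(expr_log_centered, scores, eig, axis=None):
    """Embed cells in FPC space; optionally attach a pseudotime derivative field.

    Cell j's coordinates are the least-squares solution of
    Y[:, j] ≈ Ξ · c, i.e. the Moore-Penrose pseudo-inverse of the gene score
    matrix applied to the cell's centered expression column.  For exact
    rank-L data Y = Ξ Φ(t) this returns Φ_k(t_j) itself.  When ``axis`` is
    given, the directional field (Φ'_1(t_j), …, Φ'_L(t_j)) is evaluated from
    B-spline derivative coefficients and returned alongside.
    """
    if expr_log_centered.scale != "log-centered":
        raise ValueError("cell_embedding expects log-centered expression")
    Xi = scores.xi
    if Xi.shape[0] != expr_log_centered.n_genes:
        raise ValueError("scores and expression cover different gene sets")
    if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
        warnings.warn(
            "rank-deficient FPC score matrix; embedding is the minimum-norm "
            "least-squares solution",
            stacklevel=2,
        )
    coords = (np.linalg.pinv(Xi) @ expr_log_centered.values).T  # cells × L
    if axis is None:
        return coords, None
    field = eig.evaluate(axis.t, deriv=1)  # cells × L
    return coords, field
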