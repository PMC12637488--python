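"""Distance statistic, permutation null and gene calling.

The test statistic for gene i is the squared Euclidean norm of its FPC
scores, D_i = Σ_k ξ_ik², i.e. the squared L2 distance between the zero
function and the gene's trajectory projected onto the span of the retained
eigenfunctions.  Its null distribution is built by permuting pseudotime
labels across cells and recomputing D; the empirical p-value pools null
statistics across all genes:

    p_i = (1 / (B·G)) Σ_b Σ_g 1{ D_g^(b) >= D_i }.

During permutation the eigenfunctions are held fixed at their
observed-data estimates — the statistic is a projection norm onto a basis
learned once from the observed data — so only the (cheap) re-smoothing and
re-projection are repeated per permutation.  Refitting the full FPCA per
permutation is available through the model interface for sensitivity
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationNull",
    "distance_statistic",
    "permutation_null",
    "empirical_pvalue",
    "bh_fdr",
    "select_tigs",
    "fpcf_statistic",
]


@dataclass
class PermutationNull:
    """Null statistics from pseudotime-label permutations.

    ``null_stats`` is B × G (permutations × genes) of D under the null;
    ``fpcf_stats``, when present, holds the functional-F statistic computed
    on the same permutations for the FPC-F baseline.
    """

    null_stats: np.ndarray
    B: int
    G: int
    seed: Optional[int] = None
    fpcf_stats: Optional[np.ndarray] = None

    def __post_init__(self):
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if self.null_stats.shape != (self.B, self.G):
            raise ValueError("null_stats shape must be (B, G)")
        if self.B * self.G == 0:
            raise ValueError("permutation null must contain at least one statistic")


def distance_statistic(scores):
    """D_i = Σ_k ξ_ik², the squared norm of each gene's FPC score vector."""
    xi = scores.xi if hasattr(scores, "xi") else np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ValueError("FPC scores must be finite")
    return np.einsum("ik,ik->i", xi, xi)


def fpcf_statistic(smoothed, eig, scores=None, eps=1e-8):
    """Functional-F baseline: ratio of projected to residual trajectory variance.

    F_i = D_i / (r_i + eps) where r_i = ‖f_i‖² − D_i is the squared L2
    distance between the smoothed gene and its rank-L projection.  When a
    gene lies (numerically) inside the eigenfunction span the denominator
    collapses and F is capped only by the floor ``eps`` — the instability
    that motivates the distance statistic.  Flagged experimental.
    """
    from .fpca import project_scores

    if scores is None:
        scores = project_scores(smoothed, eig)
    D = distance_statistic(scores)
    W = smoothed.basis.gram()
    norm2 = np.einsum("ik,kl,il->i", smoothed.coef, W, smoothed.coef)
    resid = np.clip(norm2 - D, 0.0, None)
    return D / (resid + eps)


def permutation_null(expr_log_centered, smoothed, eig, n_permutations,
                     seed=None, rng=None, permutations=None,
                     include_fpcf=False, fpcf_eps=1e-8):
    """Recompute D under ``n_permutations`` pseudotime-label shuffles.

    Because every gene shares one pseudotime grid, shuffling pseudotime
    labels across cells is identical to applying the fixed smoother matrix
    to column-permuted expression; scores are then projected onto the FIXED
    observed-data eigenfunctions.  ``permutations`` may supply explicit
    index arrays (e.g. the identity, for testing); otherwise shuffles are
    drawn from ``rng``/``seed``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    Y = (
        expr_log_centered.values
        if hasattr(expr_log_centered, "values")
        else np.asarray(expr_log_centered, dtype=float)
    )
    G, n = Y.shape
    if rng is None:
        rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = [rng.permutation(n) for _ in range(n_permutations)]
    elif len(permutations) != n_permutations:
        raise ValueError("explicit permutation list length mismatch")

    W = smoothed.basis.gram()
    WU = W @ eig.coef  # n_basis × L
    null_D = np.empty((n_permutations, G))
    null_F = np.empty((n_permutations, G)) if include_fpcf else None
    if include_fpcf:
        St = smoothed.smoother.T  # n × n_basis
        for b, perm in enumerate(permutations):
            coef_b = Y[:, perm] @ St
            xi = coef_b @ WU
            D = np.einsum("ik,ik->i", xi, xi)
            null_D[b] = D
            norm2 = np.einsum("ik,kl,il->i", coef_b, W, coef_b)
            resid = np.clip(norm2 - D, 0.0, None)
            null_F[b] = D / (resid + fpcf_eps)
    else:
        T = smoothed.smoother.T @ WU  # n × L : data row -> scores directly
        for b, perm in enumerate(permutations):
            xi = Y[:, perm] @ T
            null_D[b] = np.einsum("ik,ik->i", xi, xi)
    return PermutationNull(
        null_stats=null_D, B=n_permutations, G=G, seed=seed, fpcf_stats=null_F
    )


def empirical_pvalue(D_obs, null, method="pooled", positive=False,
                     null_stats=None):
    """Permutation p-values from the (pooled) null.

    ``method="pooled"`` divides the inclusive exceedance count by B·G,
    sharing all genes' permutation statistics (this assumes cross-gene
    exchangeability of null D).  ``method="per-gene"`` uses only each
    gene's own B permutations.  ``positive=True`` applies the standard
    (1 + count) / (1 + total) guard so p is never exactly zero; the default
    reports the literal pooled count, which can reach 0.
    """
    D_obs = np.asarray(D_obs, dtype=float)
    stats = null.null_stats if null_stats is None else np.asarray(null_stats)
    if method == "pooled":
        flat = np.sort(stats, axis=None)
        total = flat.size
        count = total - np.searchsorted(flat, D_obs, side="left")
    elif method == "per-gene":
        if stats.shape[1] != D_obs.shape[0]:
            raise ValueError("per-gene null requires one column per gene")
        count = (stats >= D_obs[None, :]).sum(axis=0)
        total = stats.shape[0]
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    if positive:
        return (1.0 + count) / (1.0 + total)
    return count / total


def bh_fdr(p):
    """Benjamini-Hochberg step-up adjusted values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_tigs(D, fraction=0.25):
    """Indices of the ceil(fraction·G) genes with largest D.

    Trajectory-informative genes (TIGs) feed the second-stage eigenbasis
    re-estimation.  Ties at the cutoff keep the earlier-indexed gene
    (stable sort), so the selection is deterministic.
    """
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValueError("cannot select TIGs from an empty gene set")
    if not 0 < fraction <= 1:
        raise ValueError("tig fraction must be in (0, 1]")
    k = math.ceil(fraction * D.size)
    order = np.argsort(-D, kind="stable")
    return np.sort(order[:k])
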