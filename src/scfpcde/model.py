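"""Model/results interface for the trajectory FPC differential-expression test.

``ScFPCDE`` holds the data and model settings; ``fit()`` runs the full
pipeline — log transform and centering, penalized-spline smoothing, staged
FPCA with trajectory-informative-gene (TIG) refinement, permutation null,
pooled empirical p-values and BH-FDR — and returns an ``ScFPCDEResults``
carrying per-gene statistics, the eigensystem and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .basis import BSplineBasis
from .detest import (
    PermutationNull,
    bh_fdr,
    distance_statistic,
    empirical_pvalue,
    fpcf_statistic,
    permutation_null,
    select_tigs,
)
from .fpca import (
    EigenSystem,
    ExpressionMatrix,
    FPCScores,
    PseudotimeAxis,
    SmoothedTrajectories,
    cell_embedding,
    center_and_transform,
    estimate_covariance,
    eigendecompose,
    project_scores,
    smooth_trajectories,
)

__all__ = ["ScFPCDE", "ScFPCDEResults", "run_scfpcde"]


class ScFPCDE:
    """Trajectory differential-expression model for one gene × cell matrix.

    Parameters
    ----------
    expression : ExpressionMatrix or array-like
        Genes × cells raw counts (default) or pre-logged values
        (``scale="log"``).
    pseudotime : PseudotimeAxis or array-like
        Per-cell pseudotime; rescaled affinely to [0, 1].
    n_basis, order, penalty_order : int
        Penalized B-spline settings (10 cubic splines, curvature penalty).
    smoothing : "gcv" or float
        Roughness penalty weight λ, or "gcv" to select it by generalized
        cross-validation pooled over genes.
    n_components : "variance" or int
        Retained FPC count L: smallest L reaching ``var_threshold``
        cumulative explained variance (capped at ``max_components``), or a
        fixed integer.
    tig_fraction : float
        Fraction of genes (ranked by D) kept as trajectory-informative
        genes for eigenbasis re-estimation.
    n_stages : int
        1 = plain FPCA; 2 (default) = re-estimate the covariance and
        eigenfunctions from TIGs and re-project all genes.
    """

    def __init__(self, expression, pseudotime, *, gene_ids=None, cell_ids=None,
                 scale="counts", pseudo_count=1.0, n_basis=10, order=4,
                 penalty_order=2, smoothing="gcv", gcv_grid=None,
                 n_components="variance", var_threshold=0.9, max_components=10,
                 tig_fraction=0.25, n_stages=2):
        if isinstance(expression, ExpressionMatrix):
            self.expression = expression
        else:
            values = np.asarray(expression, dtype=float)
            if gene_ids is None:
                gene_ids = np.array([f"gene{i + 1}" for i in range(values.shape[0])])
            if cell_ids is None:
                cell_ids = np.array([f"cell{j + 1}" for j in range(values.shape[1])])
            self.expression = ExpressionMatrix(values, gene_ids, cell_ids, scale=scale)
        if isinstance(pseudotime, PseudotimeAxis):
            self.pseudotime = pseudotime
        else:
            self.pseudotime = PseudotimeAxis(self.expression.cell_ids,
                                             np.asarray(pseudotime, dtype=float))
        if not np.array_equal(self.expression.cell_ids, self.pseudotime.cell_ids):
            raise ValueError("expression and pseudotime cover different cells")
        if n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        self.pseudo_count = float(pseudo_count)
        self.basis = BSplineBasis(n_basis, order=order, penalty_order=penalty_order)
        self.smoothing = smoothing
        self.gcv_grid = gcv_grid
        self.n_components = n_components
        self.var_threshold = float(var_threshold)
        self.max_components = int(max_components)
        self.tig_fraction = float(tig_fraction)
        self.n_stages = int(n_stages)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, expression_df, pseudotime, **kwargs):
        """Build from a genes × cells DataFrame and a per-cell pseudotime Series.

        ``pseudotime`` may be a Series indexed by cell id (aligned to the
        DataFrame columns) or a plain sequence in column order.
        """
        if isinstance(pseudotime, pd.Series):
            missing = [c for c in expression_df.columns if c not in pseudotime.index]
            if missing:
                raise ValueError(f"pseudotime missing for {len(missing)} cells")
            pseudotime = pseudotime.loc[expression_df.columns].to_numpy()
        expr = ExpressionMatrix(
            expression_df.to_numpy(dtype=float),
            expression_df.index.to_numpy(),
            expression_df.columns.to_numpy(),
            scale=kwargs.pop("scale", "counts"),
        )
        return cls(expr, pseudotime, **kwargs)

    # ------------------------------------------------------------------
    def _eigensystem_for(self, coef_matrix, smoothed, gene_subset=None):
        cov = estimate_covariance(smoothed, gene_subset=gene_subset)
        return eigendecompose(
            cov,
            n_components=self.n_components,
            var_threshold=self.var_threshold,
            max_components=self.max_components,
        )

    def _staged_fpca(self, smoothed):
        """Stage 1: FPCA on all genes; stages >= 2: refine on TIGs.

        Returns (eig, scores, D, tig_index, stage1_D, stage1_eig).
        """
        eig = self._eigensystem_for(smoothed.coef, smoothed)
        scores = project_scores(smoothed, eig)
        D = distance_statistic(scores)
        stage1_D, stage1_eig = D, eig
        tigs = None
        for _ in range(1, self.n_stages):
            tigs = select_tigs(D, self.tig_fraction)
            eig = self._eigensystem_for(smoothed.coef, smoothed, gene_subset=tigs)
            scores = project_scores(smoothed, eig)
            D = distance_statistic(scores)
        if tigs is None:
            tigs = select_tigs(D, self.tig_fraction)
        return eig, scores, D, tigs, stage1_D, stage1_eig

    def fit(self, n_permutations=100, alpha=0.05, seed=None, null="pooled",
            positive_pvalues=False, refit_basis=False, compute_fpcf=False,
            fpcf_eps=1e-8):
        """Run the two-stage test and return an ``ScFPCDEResults``.

        ``null`` selects pooled (divide by B·G; default) or per-gene
        (divide by B) empirical p-values.  ``positive_pvalues`` applies the
        (1+count)/(1+total) guard.  ``refit_basis`` re-runs the staged FPCA
        inside every permutation instead of holding the eigenfunctions
        fixed (slow; sensitivity analysis only).  ``compute_fpcf`` also
        evaluates the functional-F baseline on the same permutations.
        """
        centered, gene_means, is_constant = center_and_transform(
            self.expression, pseudo_count=self.pseudo_count
        )
        smoothed = smooth_trajectories(
            centered, self.pseudotime, self.basis,
            lam=self.smoothing, gcv_grid=self.gcv_grid, gene_means=gene_means,
        )
        eig, scores, D, tigs, stage1_D, stage1_eig = self._staged_fpca(smoothed)

        rng = np.random.default_rng(seed)
        n = centered.n_cells
        perms = [rng.permutation(n) for _ in range(n_permutations)]
        if refit_basis:
            null_obj = self._refit_null(centered, smoothed, perms, seed,
                                        compute_fpcf, fpcf_eps)
        else:
            null_obj = permutation_null(
                centered, smoothed, eig, n_permutations,
                permutations=perms, include_fpcf=compute_fpcf,
                fpcf_eps=fpcf_eps, seed=seed,
            )
        p = empirical_pvalue(D, null_obj, method=null, positive=positive_pvalues)
        q = bh_fdr(p)

        fpcf = fpcf_p = None
        if compute_fpcf:
            fpcf = fpcf_statistic(smoothed, eig, scores=scores, eps=fpcf_eps)
            fpcf_p = empirical_pvalue(
                fpcf, null_obj, method=null, positive=positive_pvalues,
                null_stats=null_obj.fpcf_stats,
            )

        is_tig = np.zeros(centered.n_genes, dtype=bool)
        is_tig[tigs] = True
        return ScFPCDEResults(
            model=self,
            centered=centered,
            gene_means=gene_means,
            is_constant=is_constant,
            smoothed=smoothed,
            eigensystem=eig,
            stage1_eigensystem=stage1_eig,
            scores=scores,
            D=D,
            stage1_D=stage1_D,
            null=null_obj,
            p=p,
            q=q,
            alpha=float(alpha),
            is_tig=is_tig,
            seed=seed,
            null_method=null,
            fpcf=fpcf,
            fpcf_p=fpcf_p,
        )

    def _refit_null(self, centered, smoothed, perms, seed, compute_fpcf, fpcf_eps):
        """Re-run the staged FPCA inside each permutation (sensitivity mode)."""
        Y = centered.values
        G = Y.shape[0]
        null_D = np.empty((len(perms), G))
        null_F = np.empty((len(perms), G)) if compute_fpcf else None
        for b, perm in enumerate(perms):
            coef_b = Y[:, perm] @ smoothed.smoother.T
            sm_b = SmoothedTrajectories(
                coef=coef_b, basis=smoothed.basis, gene_means=smoothed.gene_means,
                gene_ids=smoothed.gene_ids, t=smoothed.t, lam=smoothed.lam,
                smoother=smoothed.smoother,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                eig_b, scores_b, D_b, *_ = self._staged_fpca(sm_b)
            null_D[b] = D_b
            if compute_fpcf:
                null_F[b] = fpcf_statistic(sm_b, eig_b, scores=scores_b,
                                           eps=fpcf_eps)
        return PermutationNull(null_stats=null_D, B=len(perms), G=G,
                               seed=seed, fpcf_stats=null_F)


# ---------------------------------------------------------------------------
@dataclass
class ScFPCDEResults:
    """Per-gene test output plus the fitted functional objects."""

    model: ScFPCDE
    centered: ExpressionMatrix
    gene_means: np.ndarray
    is_constant: np.ndarray
    smoothed: SmoothedTrajectories
    eigensystem: EigenSystem
    stage1_eigensystem: EigenSystem
    scores: FPCScores
    D: np.ndarray
    stage1_D: np.ndarray
    null: PermutationNull
    p: np.ndarray
    q: np.ndarray
    alpha: float
    is_tig: np.ndarray
    seed: Optional[int]
    null_method: str
    fpcf: Optional[np.ndarray] = None
    fpcf_p: Optional[np.ndarray] = None

    @property
    def gene_ids(self):
        return self.centered.gene_ids

    @property
    def is_tdeg(self):
        """TDEG call at BH-FDR q < alpha."""
        return self.q < self.alpha

    @property
    def n_components(self):
        return self.eigensystem.L

    def to_frame(self):
        """Per-gene results table (gene order preserved)."""
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "D": self.D,
                "p": self.p,
                "q": self.q,
                "is_tig": self.is_tig,
                "is_tdeg": self.is_tdeg,
            }
        )

    def cell_embedding(self, derivative_field=True):
        """Cells × L FPC-space coordinates (+ pseudotime derivative field)."""
        return cell_embedding(
            self.centered, self.scores, self.eigensystem,
            axis=self.model.pseudotime if derivative_field else None,
        )

    # ------------------------------------------------------------------
    def summary(self, top=10):
        """Human-readable fit summary with the strongest genes."""
        eig = self.eigensystem
        lines = [
            "scFPC-DE trajectory differential expression",
            "=" * 60,
            f"genes: {self.centered.n_genes}    cells: {self.centered.n_cells}",
            f"basis: {self.model.basis!r}, lambda = {self.smoothed.lam:.4g}",
            f"components L = {eig.L} "
            f"(cumulative variance {eig.var_explained[-1] * 100:.1f}%)",
            "eigenvalues: "
            + ", ".join(f"{v:.4g}" for v in eig.eigenvalues),
            f"permutations B = {self.null.B} ({self.null_method} null), "
            f"seed = {self.seed}",
            f"TIGs: {int(self.is_tig.sum())}    "
            f"TDEGs (q < {self.alpha:g}): {int(self.is_tdeg.sum())}",
            "-" * 60,
        ]
        frame = self.to_frame().sort_values("D", ascending=False).head(top)
        lines.append(frame.to_string(index=False,
                                     float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def plot_eigenfunctions(self, ax=None, n_points=201):
        """Plot the retained eigenfunctions over pseudotime."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 1, n_points)
        vals = self.eigensystem.evaluate(grid)
        for k in range(self.eigensystem.L):
            lam = self.eigensystem.eigenvalues[k]
            ax.plot(grid, vals[:, k], label=f"FPC {k + 1} (λ={lam:.3g})")
        ax.set_xlabel("pseudotime")
        ax.set_ylabel("eigenfunction")
        ax.legend()
        return ax

    def plot_gene(self, gene_id, ax=None, n_points=201):
        """Observed centered log expression and the smoothed trajectory."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = int(np.flatnonzero(self.gene_ids == gene_id)[0])
        t = self.model.pseudotime.t
        ax.plot(t, self.centered.values[idx], ".", alpha=0.3, label="cells")
        grid = np.linspace(0, 1, n_points)
        ax.plot(grid, self.smoothed.evaluate(grid)[idx], lw=2, label="smooth fit")
        ax.set_title(f"{gene_id}: D={self.D[idx]:.3g}, q={self.q[idx]:.3g}")
        ax.set_xlabel("pseudotime")
        ax.set_ylabel("centered log expression")
        ax.legend()
        return ax

    def plot_score_space(self, ax=None, components=(0, 1)):
        """Gene scatter in FPC score space, TDEG calls highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a, b = components
        xi = self.scores.xi
        ax.scatter(xi[~self.is_tdeg, a], xi[~self.is_tdeg, b], s=5,
                   c="grey", label="null")
        ax.scatter(xi[self.is_tdeg, a], xi[self.is_tdeg, b], s=5,
                   c="black", label="TDEG")
        ax.set_xlabel(f"FPC score {a + 1}")
        ax.set_ylabel(f"FPC score {b + 1}")
        ax.legend()
        return ax


def run_scfpcde(expression, pseudotime, *, n_permutations=100, alpha=0.05,
                seed=None, **model_kwargs):
    """One-call convenience wrapper: build the model and fit it."""
    fit_keys = ("null", "positive_pvalues", "refit_basis", "compute_fpcf",
                "fpcf_eps")
    fit_kwargs = {k: model_kwargs.pop(k) for k in fit_keys if k in model_kwargs}
    model = ScFPCDE(expression, pseudotime, **model_kwargs)
    return model.fit(n_permutations=n_permutations, alpha=alpha, seed=seed,
                     **fit_kwargs)
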