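"""Penalized B-spline basis on the unit pseudotime interval.

All functional objects in this package (smoothed gene trajectories,
covariance surfaces, eigenfunctions) are represented by their coefficients
in a single B-spline basis on [0, 1].  L2 inner products are therefore
exact matrix expressions through the basis Gram matrix; no grid quadrature
enters the pipeline (grids are used only by test oracles).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = ["BSplineBasis", "build_basis"]


class BSplineBasis:
    """B-spline basis of a given order on [0, 1] with a roughness penalty.

    Parameters
    ----------
    n_basis : int
        Number of basis functions.  Must be >= ``order``.
    order : int
        Spline order (polynomial degree + 1).  ``order=4`` gives cubic
        splines, the default throughout the package.
    interior_knots : array-like, optional
        Strictly interior knot positions in (0, 1).  Defaults to
        ``n_basis - order`` equally spaced interior knots.
    penalty_order : int
        Derivative order whose integrated square is penalized during
        smoothing (2 = curvature penalty).
    """

    def __init__(self, n_basis, order=4, interior_knots=None, penalty_order=2):
        n_basis = int(n_basis)
        order = int(order)
        if order < 2:
            raise ValueError(f"order must be >= 2, got {order}")
        if n_basis < order:
            raise ValueError(
                f"n_basis ({n_basis}) must be at least the spline order ({order})"
            )
        if not 1 <= penalty_order < order:
            raise ValueError(
                f"penalty_order must be in [1, {order - 1}], got {penalty_order}"
            )
        if interior_knots is None:
            n_interior = n_basis - order
            interior_knots = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        interior_knots = np.asarray(interior_knots, dtype=float)
        if interior_knots.size != n_basis - order:
            raise ValueError(
                f"{n_basis} basis functions of order {order} require "
                f"{n_basis - order} interior knots, got {interior_knots.size}"
            )
        if interior_knots.size and (
            np.any(interior_knots <= 0.0)
            or np.any(interior_knots >= 1.0)
            or np.any(np.diff(interior_knots) < 0)
        ):
            raise ValueError("interior knots must be nondecreasing and inside (0, 1)")

        self.n_basis = n_basis
        self.order = order
        self.penalty_order = int(penalty_order)
        self.interior_knots = interior_knots
        # full knot vector with endpoint multiplicity = order
        self.knots = np.concatenate(
            [np.zeros(order), interior_knots, np.ones(order)]
        )
        self._splines = {}  # cache of BSpline objects keyed by derivative order

    # ------------------------------------------------------------------
    @property
    def degree(self):
        return self.order - 1

    def _spline(self, deriv=0):
        if deriv not in self._splines:
            base = BSpline(self.knots, np.eye(self.n_basis), self.degree)
            self._splines[deriv] = base if deriv == 0 else base.derivative(deriv)
        return self._splines[deriv]

    def design(self, x, deriv=0):
        """Evaluate all basis functions (or a derivative) at points ``x``.

        Returns an ``(len(x), n_basis)`` matrix.  Points must lie in [0, 1]
        up to floating-point slack.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise ValueError("evaluation points must lie in [0, 1]")
        x = np.clip(x, 0.0, 1.0)
        return self._spline(deriv)(x)

    # ------------------------------------------------------------------
    def _panel_quadrature(self):
        """Gauss-Legendre nodes/weights on each knot span.

        ``order + 1`` nodes per span integrate products of two basis
        functions (polynomial degree 2(order-1)) exactly.
        """
        breaks = np.unique(self.knots)
        gx, gw = leggauss(self.order + 1)
        half = np.diff(breaks) / 2.0
        mid = (breaks[1:] + breaks[:-1]) / 2.0
        nodes = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
        weights = (half[:, None] * gw[None, :]).ravel()
        return nodes, weights

    def product_integral(self, deriv_a=0, deriv_b=0):
        """Exact matrix of ∫ B_a^(da)(t) B_b^(db)(t) dt over [0, 1]."""
        nodes, weights = self._panel_quadrature()
        da = self.design(nodes, deriv_a)
        db = da if deriv_b == deriv_a else self.design(nodes, deriv_b)
        out = da.T @ (weights[:, None] * db)
        return (out + out.T) / 2.0 if deriv_a == deriv_b else out

    def gram(self):
        """Gram matrix W with W[a, b] = ∫ B_a(t) B_b(t) dt (symmetric PD)."""
        return self.product_integral(0, 0)

    def penalty(self):
        """Roughness penalty matrix ∫ B_a^(m) B_b^(m) dt for m = penalty_order."""
        m = self.penalty_order
        return self.product_integral(m, m)

    def time_moment(self):
        """Vector of ∫ B_a(t) · t dt, used for the eigenfunction sign rule."""
        nodes, weights = self._panel_quadrature()
        return self.design(nodes).T @ (weights * nodes)

    # ------------------------------------------------------------------
    def __eq__(self, other):
        return (
            isinstance(other, BSplineBasis)
            and self.n_basis == other.n_basis
            and self.order == other.order
            and np.allclose(self.knots, other.knots)
        )

    def __repr__(self):
        return (
            f"BSplineBasis(n_basis={self.n_basis}, order={self.order}, "
            f"penalty_order={self.penalty_order})"
        )


def build_basis(n_basis=10, order=4, penalty_order=2):
    """Equally spaced B-spline basis on [0, 1] (cubic by default)."""
    return BSplineBasis(n_basis, order=order, penalty_order=penalty_order)
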