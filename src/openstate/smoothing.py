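"""Penalized cubic regression splines with GCV-selected smoothness.

One-dimensional P-spline smoother in the Eilers & Marx style: an
equidistant cubic B-spline basis over the data support, a second-order
difference penalty on the coefficients, and the penalty weight chosen by
generalized cross-validation.  Because the knots are equidistant and
extend past the support, straight-line data lie in the penalty null
space and are reproduced to machine precision at any penalty weight.

Outside the fitted support the smooth continues linearly from the
boundary value and slope, so downstream consumers (drift models under
warming-driven bin switching, noise models evaluated at simulated
covers) get a defined, monotone-safe extrapolation instead of a
polynomial blow-up.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar

__all__ = ["PenalizedSpline"]


def _difference_matrix(k: int, order: int = 2) -> np.ndarray:
    d = np.eye(k)
    for _ in range(order):
        d = np.diff(d, axis=0)
    return d


class PenalizedSpline:
    """Penalized cubic regression spline ``y ~ s(x)``.

    Parameters
    ----------
    k
        Basis dimension (number of B-spline coefficients), default 10.
    degree
        Spline degree, default 3 (cubic).
    penalty_order
        Order of the difference penalty, default 2; its null space
        contains all straight lines, which are therefore never shrunk.
    lam
        Penalty weight.  ``None`` (default) selects it by minimizing
        the GCV score over a log-spaced grid with local refinement.
    """

    def __init__(self, k: int = 10, degree: int = 3, penalty_order: int = 2,
                 lam: float | None = None):
        if k < degree + 1:
            raise ValueError(f"basis dimension k={k} must be >= degree+1")
        self.k = k
        self.degree = degree
        self.penalty_order = penalty_order
        self.lam = lam

    # -- fitting -----------------------------------------------------------

    def fit(self, x, y, w=None) -> "PenalizedSpline":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if w is None:
            w = np.ones_like(y)
        else:
            w = np.asarray(w, dtype=float)[ok]
        if x.size < 2:
            raise ValueError("need at least 2 finite observations")

        xmin, xmax = float(x.min()), float(x.max())
        if xmax == xmin:
            raise ValueError("x is constant; cannot fit a smooth")
        k = min(self.k, max(self.degree + 1, np.unique(x).size))

        # equidistant knots extended `degree` segments past the support so
        # the Greville sites are equispaced and lines have zero penalty
        nseg = k - self.degree
        h = (xmax - xmin) / nseg
        t = xmin + h * np.arange(-self.degree, nseg + self.degree + 1)
        basis = BSpline.design_matrix(np.clip(x, xmin, xmax), t, self.degree)

        wb = basis.multiply(w[:, None]).tocsc()
        btb = (basis.T @ wb).toarray()
        bty = basis.T @ (w * y)
        ytwy = float(np.dot(w * y, y))
        pen = _difference_matrix(k, self.penalty_order)
        pen = pen.T @ pen
        n = x.size

        def solve(lam):
            coef = np.linalg.solve(btb + lam * pen, bty)
            # tr(H) = tr((B'WB + lam P)^-1 B'WB)
            edf = float(np.trace(np.linalg.solve(btb + lam * pen, btb)))
            rss = max(ytwy - 2.0 * coef @ bty + coef @ btb @ coef, 0.0)
            return coef, edf, rss

        if self.lam is not None:
            lam_opt = float(self.lam)
        else:
            def gcv(loglam):
                _, edf, rss = solve(10.0 ** loglam)
                denom = max(n - edf, 1e-10)
                return n * rss / denom ** 2

            grid = np.linspace(-6.0, 10.0, 33)
            scores = [gcv(g) for g in grid]
            i = int(np.argmin(scores))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            res = minimize_scalar(gcv, bounds=(lo, hi), method="bounded")
            lam_opt = float(10.0 ** res.x)

        coef, edf, rss = solve(lam_opt)
        self.lam_ = lam_opt
        self.edf_ = edf
        self.rss_ = rss
        self.n_ = n
        self.support_ = (xmin, xmax)
        self.spline_ = BSpline(t, coef, self.degree, extrapolate=False)
        d = self.spline_.derivative()
        self._b0 = (float(self.spline_(xmin)), float(d(xmin)))
        self._b1 = (float(self.spline_(xmax)), float(d(xmax)))
        return self

    # -- evaluation --------------------------------------------------------

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        xmin, xmax = self.support_
        out = np.empty_like(x)
        inside = (x >= xmin) & (x <= xmax)
        out[inside] = self.spline_(x[inside])
        lo = x < xmin
        hi = x > xmax
        out[lo] = self._b0[0] + self._b0[1] * (x[lo] - xmin)
        out[hi] = self._b1[0] + self._b1[1] * (x[hi] - xmax)
        return float(out[0]) if scalar else out

    def derivative(self, x):
        """First derivative of the smooth (constant beyond the support)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        xmin, xmax = self.support_
        d = self.spline_.derivative()
        out = np.empty_like(x)
        inside = (x >= xmin) & (x <= xmax)
        out[inside] = d(x[inside])
        out[x < xmin] = self._b0[1]
        out[x > xmax] = self._b1[1]
        return float(out[0]) if scalar else out
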