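"""Cyclic cubic regression spline basis with curvature penalty.

A spline on ``[lower, lower + period]`` parameterized by its values at k
evenly spaced knots, with value/first/second-derivative continuity across
the period boundary (the value at the last knot is identified with the
first).  The basis provides a design matrix in the knot-value coefficients
and the wiggliness penalty matrix S such that the integrated squared second
derivative of the spline equals ``beta' S beta``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CyclicCubicBasis"]


class CyclicCubicBasis:
    """Cyclic cubic regression spline on evenly spaced knots.

    Parameters
    ----------
    n_knots:
        Number of knots including both period endpoints; the number of free
        coefficients is ``n_knots - 1``.
    period, lower:
        The spline is periodic on ``[lower, lower + period]``; inputs are
        wrapped modulo the period before evaluation, so the design matrix is
        exactly invariant to adding any multiple of the period.
    """

    def __init__(self, n_knots: int = 8, period: float = 52.0, lower: float = 0.0):
        if n_knots < 4:
            raise ValueError("need at least 4 knots for a cyclic cubic spline")
        self.lower = float(lower)
        self.period = float(period)
        self.knots = np.linspace(lower, lower + period, n_knots)
        self.n_coef = n_knots - 1

        h = np.diff(self.knots)  # interval widths, length n_knots - 1
        m = self.n_coef
        B = np.zeros((m, m))
        D = np.zeros((m, m))
        for i in range(m):
            im = (i - 1) % m  # wraps: interval before knot 0 is the last one
            ip = (i + 1) % m
            h_prev, h_i = h[im], h[i]
            B[i, i] += (h_prev + h_i) / 3.0
            B[i, ip] += h_i / 6.0
            B[i, im] += h_prev / 6.0
            D[i, i] += -1.0 / h_prev - 1.0 / h_i
            D[i, ip] += 1.0 / h_i
            D[i, im] += 1.0 / h_prev
        self._h = h
        # second derivatives at knots: gamma = F @ beta
        self.F = np.linalg.solve(B, D)
        S = D.T @ self.F
        self.S = (S + S.T) / 2.0  # symmetrize; S @ 1 == 0

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at ``x`` -> (n, n_coef) design matrix."""
        xv = np.asarray(x, dtype=float).ravel()
        xm = self.lower + np.mod(xv - self.lower, self.period)
        j = np.clip(
            np.searchsorted(self.knots, xm, side="right") - 1, 0, self.n_coef - 1
        )
        x0 = self.knots[j]
        hj = self._h[j]
        d0 = xm - x0  # distance from left knot
        d1 = hj - d0  # distance to right knot
        a_left = d1 / hj
        a_right = d0 / hj
        c_left = (d1**3 / hj - hj * d1) / 6.0
        c_right = (d0**3 / hj - hj * d0) / 6.0

        n = xv.size
        rows = np.arange(n)
        jp = (j + 1) % self.n_coef  # last knot identified with the first
        A = np.zeros((n, self.n_coef))
        C = np.zeros((n, self.n_coef))
        np.add.at(A, (rows, j), a_left)
        np.add.at(A, (rows, jp), a_right)
        np.add.at(C, (rows, j), c_left)
        np.add.at(C, (rows, jp), c_right)
        return A + C @ self.F
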