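"""Cyclic cubic regression spline basis on the day-of-year circle.

The basis is parameterized by the spline's values at K knots evenly
spaced over [1, 366), with the wrap constraint that the function and
its first two derivatives match at day 1 and day 366. Internally this
is the classic value/second-derivative construction: for knot values
beta, the knot second derivatives are gamma = B^{-1} D beta where B and
D are cyclic banded matrices, and the curve between knots is the cubic
Hermite-like interpolant. The roughness penalty int f''(x)^2 dx equals
beta' D' B^{-1} D beta, a symmetric PSD matrix whose null space is the
constant function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PERIOD = 365.0


class BasisError(ValueError):
    """Raised for invalid day inputs or degenerate basis requests."""


@dataclass(frozen=True)
class CyclicBasis:
    """A cyclic cubic regression spline basis with its roughness penalty."""

    knots: np.ndarray          # (K,) knot days, ascending, in [1, 366)
    penalty: np.ndarray        # (K, K) symmetric PSD
    _F: np.ndarray             # (K, K) maps knot values -> knot 2nd derivatives
    period: float = PERIOD

    @property
    def n_basis(self) -> int:
        return len(self.knots)

    def design_matrix(self, days, *, validate: bool = True) -> np.ndarray:
        """Evaluate all basis functions at ``days`` -> (n, K).

        Days are wrapped onto [1, 366), so row(day 366) == row(day 1).
        With ``validate`` the input must lie in [1, 365] (the model
        domain); evaluation at wrapped coordinates is always exact.
        """
        d = np.atleast_1d(np.asarray(days, dtype=float))
        if validate and (np.any(d < 1.0) or np.any(d > self.period + 1.0) or np.any(~np.isfinite(d))):
            raise BasisError("day-of-year values must lie in [1, 365]")
        K = self.n_basis
        h = self.period / K
        u = (d - 1.0) % self.period + 1.0
        j = np.minimum(((u - self.knots[0]) / h).astype(int), K - 1)
        x0 = self.knots[j]
        left = u - x0
        right = h - left
        a_m = right / h
        a_p = left / h
        c_m = (right ** 3 / h - h * right) / 6.0
        c_p = (left ** 3 / h - h * left) / 6.0
        X = np.zeros((len(u), K))
        rows = np.arange(len(u))
        X[rows, j] += a_m
        X[rows, (j + 1) % K] += a_p
        X += c_m[:, None] * self._F[j] + c_p[:, None] * self._F[(j + 1) % K]
        return X


def build_cyclic_basis(n_basis: int = 10, period: float = PERIOD) -> CyclicBasis:
    """Construct a K-knot cyclic cubic regression spline basis.

    Knots are evenly spaced over [1, 1 + period). The constant function
    is exactly representable (equal coefficients), and the penalty's
    null space is exactly that constant.
    """
    if n_basis < 4:
        raise BasisError("n_basis must be >= 4")
    K = int(n_basis)
    h = period / K
    knots = 1.0 + h * np.arange(K)
    idx = np.arange(K)
    B = np.zeros((K, K))
    D = np.zeros((K, K))
    B[idx, idx] = 2.0 * h / 3.0
    B[idx, (idx + 1) % K] = h / 6.0
    B[idx, (idx - 1) % K] = h / 6.0
    D[idx, idx] = -2.0 / h
    D[idx, (idx + 1) % K] = 1.0 / h
    D[idx, (idx - 1) % K] = 1.0 / h
    F = np.linalg.solve(B, D)
    S = D.T @ F
    S = 0.5 * (S + S.T)
    return CyclicBasis(knots=knots, penalty=S, _F=F, period=period)
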