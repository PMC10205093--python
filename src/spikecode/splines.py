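"""Cardinal-spline basis over linearized position.

The log place field is represented as a cardinal (Catmull-Rom family)
interpolating spline adapted to non-uniform control-point spacing: each
segment is a cubic Hermite with knot tangents estimated by scaled central
differences, ``m_j = 2 * tension * (p_{j+1} - p_{j-1}) / (x_{j+1} - x_{j-1})``
(one-sided at the duplicated endpoints).  At the default tension 0.5 the
tangents are exact central differences, so the basis reproduces quadratics
exactly on interior segments regardless of knot spacing — the log of a
Gaussian place field is a parabola, which this family represents without
bias.  One basis column per control point; at most four nonzero weights per
evaluation point; rows sum to one (partition of unity); control-point values
are interpolated exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SplineBasis", "spline_design"]


def _hermite(u: np.ndarray) -> tuple:
    """The four cubic Hermite basis polynomials h00, h10, h01, h11 at u."""
    u2 = u * u
    u3 = u2 * u
    h00 = 2 * u3 - 3 * u2 + 1
    h10 = u3 - 2 * u2 + u
    h01 = -2 * u3 + 3 * u2
    h11 = u3 - u2
    return h00, h10, h01, h11


@dataclass(frozen=True)
class SplineBasis:
    """Cardinal spline basis defined by control-point positions (cm)."""

    control_points: np.ndarray
    tension: float = 0.5

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 1 or len(cp) < 2:
            raise ValueError("need at least two control points")
        if np.any(np.diff(cp) <= 0):
            raise ValueError("control points must be strictly increasing")
        if not 0.0 <= self.tension <= 1.0:
            raise ValueError("tension must lie in [0, 1]")
        object.__setattr__(self, "control_points", cp)

    @property
    def n_basis(self) -> int:
        return len(self.control_points)

    def design(self, x: np.ndarray) -> np.ndarray:
        return spline_design(self, x)


def _tangent_weights(cp: np.ndarray, tension: float) -> np.ndarray:
    """Per-knot tangent coefficients over (p_{j-1}, p_j, p_{j+1}).

    Interior knots use the three-point derivative on a non-uniform grid
    (exact for quadratics); the duplicated-endpoint convention reduces to
    one-sided differences at the boundary knots.  Scaled by 2 * tension so
    tension 0.5 gives the exact derivative estimates.

    Returns an (n, 3) array ``c`` with m_j = c[j,0] p_{j-1} + c[j,1] p_j +
    c[j,2] p_{j+1} (out-of-range neighbor coefficients are zero).
    """
    n = len(cp)
    c = np.zeros((n, 3))
    h = np.diff(cp)
    for j in range(n):
        if j == 0:
            c[j, 1] = -1.0 / h[0]
            c[j, 2] = 1.0 / h[0]
        elif j == n - 1:
            c[j, 0] = -1.0 / h[-1]
            c[j, 1] = 1.0 / h[-1]
        else:
            hl, hr = h[j - 1], h[j]
            c[j, 0] = -hr / (hl * (hl + hr))
            c[j, 2] = hl / (hr * (hl + hr))
            c[j, 1] = -(c[j, 0] + c[j, 2])
    return 2.0 * tension * c


def spline_design(basis: SplineBasis, x: np.ndarray) -> np.ndarray:
    """Evaluate the cardinal-spline basis at positions x -> (T, n_basis) matrix.

    Positions outside the control-point span are clamped to the span with a
    warning.  Each row sums to 1 and has at most four nonzero entries.
    """
    cp = basis.control_points
    x = np.asarray(x, dtype=float)
    if np.any(x < cp[0]) or np.any(x > cp[-1]):
        warnings.warn(
            "positions outside the spline span were clamped to the span",
            RuntimeWarning,
            stacklevel=2,
        )
        x = np.clip(x, cp[0], cp[-1])
    n = len(cp)
    j = np.clip(np.searchsorted(cp, x, side="right") - 1, 0, n - 2)
    h = cp[j + 1] - cp[j]
    u = (x - cp[j]) / h
    h00, h10, h01, h11 = _hermite(u)
    c = _tangent_weights(cp, basis.tension)

    out = np.zeros((len(x), n))
    rows = np.arange(len(x))
    # value terms
    np.add.at(out, (rows, j), h00)
    np.add.at(out, (rows, j + 1), h01)
    # tangent terms: h * h1k(u) * m_k with m_k a three-point combination
    for hk, knot in ((h10, j), (h11, j + 1)):
        w = h * hk
        for off in (-1, 0, 1):
            nb = np.clip(knot + off, 0, n - 1)
            np.add.at(out, (rows, nb), w * c[knot, off + 1])
    return out
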