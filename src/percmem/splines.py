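"""Clamped cubic B-spline basis over segment index.

The additive models approximate the smooth average disambiguation sequence
as ``B @ w_spline`` where ``B`` is an ``n_points x n_splines`` basis matrix.
The basis is the standard clamped cubic B-spline construction: knot vector
with the boundary knots repeated four times and the interior knots evenly
spaced, evaluated at the segment indices ``1..n_points``.  Clamping gives
boundary functions that peak at the edges and a row-wise partition of unity,
so a constant weight vector synthesizes a constant curve and any straight
line is reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "build_basis", "synthesize_curve"]


@dataclass(frozen=True)
class SplineBasis:
    matrix: np.ndarray = field(repr=False)  # (n_points, n_splines)
    knots: np.ndarray = field(repr=False)
    degree: int = 3

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_splines(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self):
        """Basis as a table (segment_index, b1..bK) for CSV export/plotting."""
        import pandas as pd

        data = {"segment_index": np.arange(1, self.n_points + 1)}
        for j in range(self.n_splines):
            data[f"b{j + 1}"] = self.matrix[:, j]
        return pd.DataFrame(data)


def build_basis(n_points: int, n_splines: int = 6) -> SplineBasis:
    """Clamped cubic B-spline basis evaluated at segment indices 1..n_points."""
    degree = 3
    if n_splines < degree + 1:
        raise ValueError(f"need at least {degree + 1} splines, got {n_splines}")
    if n_points < n_splines:
        raise ValueError("need at least as many evaluation points as splines")
    x = np.arange(1, n_points + 1, dtype=float)
    n_interior = n_splines - degree - 1
    interior = np.linspace(x[0], x[-1], n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.repeat(x[0], degree + 1), interior, np.repeat(x[-1], degree + 1)]
    )
    matrix = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return SplineBasis(matrix=matrix, knots=knots, degree=degree)


def synthesize_curve(basis: SplineBasis, w: np.ndarray) -> np.ndarray:
    """Weighted sum of basis functions: ``B @ w``."""
    w = np.asarray(w, dtype=float)
    if w.shape != (basis.n_splines,):
        raise ValueError(
            f"expected {basis.n_splines} weights, got shape {w.shape}"
        )
    return basis.matrix @ w
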