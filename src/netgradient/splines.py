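"""Restricted cubic spline bases, tensor products, and curvature penalties.

One-dimensional smooths are restricted (natural) cubic splines in the
truncated-power parameterization: with knots ``k_1 < ... < k_K`` the basis is
``x`` plus ``K-2`` nonlinear functions that are cubic between the boundary
knots and exactly linear outside them.  The roughness penalty is the exact
integral of products of second derivatives, so a linear function always lies
in the penalty null space.

Tensor-product smooths use the row-wise Kronecker product of marginal bases
(each augmented with a constant column so marginal main effects are spanned)
and carry one Kronecker-structured penalty per margin.  Interaction-only
tensors ("tint") use grid-centered margins, the functional-ANOVA constraint
that removes every function of a single coordinate from the span.

Column ordering is fixed and documented: the FIRST margin varies fastest.
For a model term tensor(t, a) the column of index ``i + p_t * j`` is
``b_i(t) * c_j(a)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "KnotSet",
    "BasisBlock",
    "place_knots",
    "rcs_design",
    "rcs_second_derivative",
    "rcs_penalty",
    "rcs_grid_means",
    "rcs_basis",
    "tensor_basis",
    "interaction_tensor_basis",
]

N_CONSTRAINT_GRID = 101  # uniform grid used for centering constraints


@dataclass(frozen=True)
class KnotSet:
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 3:
            raise ValidationError(f"need >= 3 knots, got {v.size} ({self.label})")
        if np.any(np.diff(v) <= 0):
            raise ValidationError(f"knots must be strictly increasing ({self.label})")

    @property
    def k(self) -> int:
        return self.values.size

    def grid(self, n: int = N_CONSTRAINT_GRID) -> np.ndarray:
        return np.linspace(self.values[0], self.values[-1], n)


@dataclass
class BasisBlock:
    """A design matrix with its penalty matrices.

    ``penalties`` holds one symmetric PSD matrix per smoothing direction;
    ``centering`` (optional) records the constants subtracted from each
    column for identifiability.
    """

    design: np.ndarray
    penalties: list
    centering: np.ndarray | None = None

    @property
    def ncol(self) -> int:
        return self.design.shape[1]


def place_knots(values_among_deceased, k: int, label: str = "") -> KnotSet:
    """Knots at the k equally spaced percentiles of event-only values.

    Percentile levels are 0, 100/(k-1), ..., 100 with linear interpolation;
    duplicate knots are collapsed, and fewer than 3 surviving knots is an
    error (degenerate event-value distribution).
    """
    v = np.asarray(values_among_deceased, dtype=float)
    if k < 3:
        raise ValidationError("need at least 3 knots")
    if v.size < k:
        raise ValidationError(f"need >= {k} values among deceased, got {v.size}")
    q = np.percentile(v, np.linspace(0.0, 100.0, k))
    knots = np.unique(q)
    if knots.size < 3:
        raise ValidationError(
            f"degenerate knots: only {knots.size} distinct percentile values ({label})"
        )
    return KnotSet(knots, label)


def _truncated_cubes(x, knots):
    """Normalized truncated-cubic pieces of the natural-spline basis."""
    x = np.asarray(x, dtype=float)
    kn = knots.values
    K = knots.k
    tau = (kn[-1] - kn[0]) ** 2
    d = kn[-1] - kn[-2]
    cols = []
    for j in range(K - 2):
        term = (
            np.maximum(x - kn[j], 0.0) ** 3
            - np.maximum(x - kn[-2], 0.0) ** 3 * (kn[-1] - kn[j]) / d
            + np.maximum(x - kn[-1], 0.0) ** 3 * (kn[-2] - kn[j]) / d
        )
        cols.append(term / tau)
    return cols


def rcs_design(x, knots: KnotSet) -> np.ndarray:
    """Restricted cubic spline design: ``x`` plus K-2 nonlinear columns."""
    x = np.asarray(x, dtype=float)
    return np.column_stack([x] + _truncated_cubes(x, knots))


def rcs_second_derivative(x, knots: KnotSet) -> np.ndarray:
    """Second derivatives of every basis column (piecewise linear in x)."""
    x = np.asarray(x, dtype=float)
    kn = knots.values
    K = knots.k
    tau = (kn[-1] - kn[0]) ** 2
    d = kn[-1] - kn[-2]
    inside = x < kn[-1]  # curvature is exactly zero at and beyond the last knot
    cols = [np.zeros_like(x)]
    for j in range(K - 2):
        term = 6.0 * (
            np.maximum(x - kn[j], 0.0)
            - np.maximum(x - kn[-2], 0.0) * (kn[-1] - kn[j]) / d
            + np.maximum(x - kn[-1], 0.0) * (kn[-2] - kn[j]) / d
        )
        cols.append(np.where(inside, term / tau, 0.0))
    return np.column_stack(cols)


def rcs_penalty(knots: KnotSet) -> np.ndarray:
    """Exact curvature penalty S[i,j] = integral of b_i'' b_j''.

    Second derivatives are piecewise linear with breaks at the knots, so the
    products are piecewise quadratic and Simpson's rule per inter-knot
    interval is exact.  The linear column has a zero row and column.
    """
    kn = knots.values
    p = knots.k - 1
    S = np.zeros((p, p))
    for a, b in zip(kn[:-1], kn[1:]):
        pts = np.array([a, 0.5 * (a + b), b])
        D = rcs_second_derivative(pts, knots)  # (3, p)
        w = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        S += D.T @ (w[:, None] * D)
    return 0.5 * (S + S.T)


def rcs_grid_means(knots: KnotSet) -> np.ndarray:
    """Column means over the fixed uniform constraint grid on the knot span."""
    return rcs_design(knots.grid(), knots).mean(axis=0)


def rcs_basis(x, knots: KnotSet, centered: bool = False) -> BasisBlock:
    """One-dimensional restricted-cubic-spline block with curvature penalty."""
    X = rcs_design(x, knots)
    centering = None
    if centered:
        centering = rcs_grid_means(knots)
        X = X - centering
    return BasisBlock(X, [rcs_penalty(knots)], centering)


def _row_kron(mats):
    """Row-wise Kronecker product; FIRST matrix varies fastest in columns."""
    out = mats[0]
    for M in mats[1:]:
        # column (i + p_prev * j) = out[:, i] * M[:, j]
        out = (M[:, :, None] * out[:, None, :]).reshape(out.shape[0], -1)
    return out


def _kron_penalty(penalties_or_sizes, which):
    """Kronecker-embed the penalty of margin ``which``; identities elsewhere.

    Kron order mirrors the column ordering (first margin fastest).
    """
    mats = []
    for m, item in enumerate(penalties_or_sizes):
        if m == which:
            mats.append(item if isinstance(item, np.ndarray) else np.eye(item))
        else:
            size = item.shape[0] if isinstance(item, np.ndarray) else item
            mats.append(np.eye(size))
    # first margin fastest => reversed np.kron nesting
    out = mats[-1]
    for M in reversed(mats[:-1]):
        out = np.kron(out, M)
    return out


def tensor_basis(margins: list[BasisBlock]) -> BasisBlock:
    """Row-wise Kronecker tensor product of marginal blocks.

    One penalty per margin: the marginal roughness penalty Kronecker-embedded
    with identities on the other margins.  Margins that should span main
    effects must include their constant column before calling.
    """
    if not 2 <= len(margins) <= 3:
        raise ValidationError("tensor product needs 2 or 3 margins")
    ncols = int(np.prod([m.ncol for m in margins]))
    if ncols > 10_000:
        raise ValidationError(f"tensor would have {ncols} columns (> 10^4)")
    design = _row_kron([m.design for m in margins])
    sizes = [m.ncol for m in margins]
    penalties = []
    for which, m in enumerate(margins):
        items = list(sizes)
        items[which] = m.penalties[0]
        penalties.append(_kron_penalty(items, which))
    return BasisBlock(design, penalties)


def interaction_tensor_basis(margins: list[BasisBlock]) -> BasisBlock:
    """Interaction-only tensor of two grid-centered margins.

    Every column is a product of two functions each averaging to zero over
    the uniform constraint grid of its own coordinate, so the span contains
    no function of a single coordinate (nor a constant).  Carries one
    penalty per margin by default.
    """
    if len(margins) != 2:
        raise ValidationError("interaction tensor needs exactly 2 margins")
    for m in margins:
        if m.centering is None:
            raise ValidationError("interaction margins must be centered blocks")
    return tensor_basis(margins)
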