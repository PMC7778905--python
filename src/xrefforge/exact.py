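"""Exact rational linear algebra for small stoichiometric systems.

These routines decide flux questions in `fractions.Fraction` arithmetic
with no tolerance, and serve as independent verification oracles for the
LP-based status classifier: rank/nullspace tests for the everything-
reversible limit, and vertex enumeration of the bounded steady-state flux
polytope for exact min/max flux on networks of up to ~10 reactions.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product

__all__ = [
    "rational_rank",
    "nullspace_support",
    "vertex_flux_ranges",
]


def _to_fractions(rows) -> list[list[Fraction]]:
    return [[Fraction(x) for x in row] for row in rows]


def _row_echelon(mat: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Gaussian elimination; returns echelon rows and pivot column indices."""
    m = [row[:] for row in mat]
    pivots: list[int] = []
    r = 0
    ncols = len(m[0]) if m else 0
    for c in range(ncols):
        piv = next((i for i in range(r, len(m)) if m[i][c] != 0), None)
        if piv is None:
            continue
        m[r], m[piv] = m[piv], m[r]
        inv = m[r][c]
        m[r] = [x / inv for x in m[r]]
        for i in range(len(m)):
            if i != r and m[i][c] != 0:
                f = m[i][c]
                m[i] = [a - f * b for a, b in zip(m[i], m[r])]
        pivots.append(c)
        r += 1
        if r == len(m):
            break
    return m, pivots


def rational_rank(rows) -> int:
    """Exact rank of a matrix given as nested sequences of rationals."""
    mat = _to_fractions(rows)
    if not mat:
        return 0
    _, pivots = _row_echelon(mat)
    return len(pivots)


def nullspace_support(rows, n: int | None = None) -> set[int]:
    """Column indices j for which some v in null(S) has v_j != 0.

    A reaction can carry flux in the everything-reversible limit exactly
    when its index is in this set: e_j is then not in the row space of S,
    i.e. rank([S; e_j]) > rank(S).
    """
    mat = _to_fractions(rows)
    if not mat:
        return set(range(n or 0))
    ncols = len(mat[0])
    echelon, pivots = _row_echelon(mat)
    rank = len(pivots)
    support: set[int] = set()
    free = [c for c in range(ncols) if c not in pivots]
    # each free column generates a nullspace basis vector with a 1 there and
    # pivot entries read off the echelon form
    for f in free:
        support.add(f)
        for r, c in enumerate(pivots):
            if echelon[r][f] != 0:
                support.add(c)
    return support


def _solve_unique(a: list[list[Fraction]], b: list[Fraction]) -> list[Fraction] | None:
    """Solve A x = b exactly; None unless the solution exists and is unique."""
    n = len(a[0]) if a else 0
    aug = [row[:] + [bi] for row, bi in zip(a, b)]
    ech, pivots = _row_echelon(aug)
    # inconsistent?
    for row in ech:
        if all(x == 0 for x in row[:-1]) and row[-1] != 0:
            return None
    if len([p for p in pivots if p < n]) != n:
        return None  # underdetermined
    x = [Fraction(0)] * n
    for r, c in enumerate(pivots):
        if c < n:
            x[c] = ech[r][-1]
    return x


def vertex_flux_ranges(S, lb, ub) -> list[tuple[Fraction, Fraction]]:
    """Exact per-reaction (min, max) flux over {v : S v = 0, lb <= v <= ub}.

    Enumerates the polytope's vertices: every vertex has a basic
    representation with exactly n - rank(S) coordinates fixed at a finite
    bound and the remaining columns of S linearly independent.  Bounds must
    be finite (the caller substitutes big-M), so the polytope is bounded and
    the ranges are attained at vertices.  Intended for n <= ~10.
    """
    Sf = _to_fractions(S)
    lb = [Fraction(x) for x in lb]
    ub = [Fraction(x) for x in ub]
    n = len(lb)
    rank = rational_rank(Sf) if Sf else 0
    nfix = n - rank

    vertices: list[list[Fraction]] = []
    cols = list(range(n))
    for fixed in combinations(cols, nfix):
        free = [c for c in cols if c not in fixed]
        A = [[row[c] for c in free] for row in Sf] if Sf else []
        for choice in product((0, 1), repeat=nfix):
            vfix = {c: (ub[c] if pick else lb[c]) for c, pick in zip(fixed, choice)}
            b = [
                -sum(row[c] * vfix[c] for c in fixed) for row in Sf
            ] if Sf else []
            if free:
                x = _solve_unique(A, b)
                if x is None:
                    continue
            else:
                if any(bi != 0 for bi in b):
                    continue
                x = []
            v = [Fraction(0)] * n
            for c, xc in zip(free, x):
                v[c] = xc
            for c in fixed:
                v[c] = vfix[c]
            if all(lb[c] <= v[c] <= ub[c] for c in cols):
                vertices.append(v)

    if not vertices:
        # 0 is feasible whenever bounds contain it; empty polytope otherwise
        raise ValueError("flux polytope has no vertices (infeasible or empty problem)")
    ranges = []
    for c in cols:
        vals = [v[c] for v in vertices]
        ranges.append((min(vals), max(vals)))
    return ranges
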