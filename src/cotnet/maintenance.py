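"""Self-maintenance testing via linear programming.

A reaction set ``R`` is self-maintaining when a flux ``v`` exists with
``v_j >= 1`` on ``R``, ``v_j = 0`` elsewhere, and nonnegative net production
``(N v)_s >= 0`` for every reactive species touched by ``R``.  The lower
bound 1 is an arbitrary normalization of strict positivity: the feasible
cone is invariant under positive scaling.

Decisions are made in two stages: a fast floating-point screen with
``scipy.optimize.linprog`` followed by an authoritative exact check with a
rational two-phase simplex, so accepted witnesses are certified in exact
arithmetic and borderline LPs cannot produce false positives.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .network import FluxVector, ReactionNetwork

logger = logging.getLogger(__name__)

__all__ = ["self_maintenance_witness", "exact_feasible"]


# ---------------------------------------------------------------------------
# exact rational feasibility: find x >= 0 with A x >= b
# ---------------------------------------------------------------------------

def exact_feasible(A: Sequence[Sequence[Fraction]],
                   b: Sequence[Fraction]) -> Optional[list[Fraction]]:
    """Solve ``A x >= b, x >= 0`` exactly; return a witness or ``None``.

    Two-phase primal simplex over :class:`fractions.Fraction` with Bland's
    rule (anti-cycling).  Intended for the small systems arising here.
    """
    m = len(A)
    n = len(A[0]) if m else 0
    if m == 0:
        return [Fraction(0)] * n

    # Standard form:  A x - s = b  with surplus s >= 0.  Rows are negated
    # where needed so every right-hand side is nonnegative; artificials are
    # added where the surplus column cannot serve as the initial basis.
    ncols = n + m  # x then s
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    basis: list[int] = []
    art_cols: list[int] = []
    for i in range(m):
        row = [Fraction(x) for x in A[i]] + [Fraction(0)] * m
        bi = Fraction(b[i])
        if bi < 0:
            row = [-x for x in row]
            bi = -bi
            row[n + i] = Fraction(1)   # +s_i, usable as basis
            rows.append(row)
            rhs.append(bi)
            basis.append(n + i)
        else:
            row[n + i] = Fraction(-1)  # -s_i, need an artificial
            rows.append(row)
            rhs.append(bi)
            basis.append(-1)  # placeholder, artificial assigned below

    for i in range(m):
        if basis[i] == -1:
            col = ncols + len(art_cols)
            art_cols.append(col)
            basis[i] = col
    total = ncols + len(art_cols)
    T = [[Fraction(0)] * total for _ in range(m)]
    for i in range(m):
        for j, x in enumerate(rows[i]):
            T[i][j] = x
    for i, bi in enumerate(basis):
        if bi >= ncols:
            T[i][bi] = Fraction(1)

    # Phase-1 objective: minimize the sum of artificials.
    cost = [Fraction(0)] * total
    for c in art_cols:
        cost[c] = Fraction(1)
    # reduced costs z_j - c_j with the current (artificial) basis
    obj = [Fraction(0)] * total
    objval = Fraction(0)
    for i in range(m):
        if basis[i] in art_cols:
            for j in range(total):
                obj[j] += T[i][j]
            objval += rhs[i]
    for j in range(total):
        obj[j] -= cost[j]

    def pivot(pr: int, pc: int) -> None:
        piv = T[pr][pc]
        T[pr] = [x / piv for x in T[pr]]
        rhs[pr] /= piv
        for i in range(m):
            if i != pr and T[i][pc] != 0:
                f = T[i][pc]
                T[i] = [a - f * p for a, p in zip(T[i], T[pr])]
                rhs[i] -= f * rhs[pr]
        nonlocal objval
        f = obj[pc]
        if f != 0:
            for j in range(total):
                obj[j] -= f * T[pr][j]
            objval -= f * rhs[pr]
        basis[pr] = pc

    while True:
        # Bland: entering = smallest index with positive reduced cost
        pc = next((j for j in range(total) if obj[j] > 0), None)
        if pc is None:
            break
        # Bland: leaving = smallest basis index among minimum ratios
        pr = None
        best = None
        for i in range(m):
            if T[i][pc] > 0:
                ratio = rhs[i] / T[i][pc]
                if best is None or ratio < best or (
                        ratio == best and basis[i] < basis[pr]):
                    best, pr = ratio, i
        if pr is None:  # unbounded phase-1 cannot happen; defensive
            return None
        pivot(pr, pc)

    if objval != 0:
        return None  # infeasible
    x = [Fraction(0)] * n
    for i, bi in enumerate(basis):
        if bi < n:
            x[bi] = rhs[i]
    return x


# ---------------------------------------------------------------------------
# witness computation
# ---------------------------------------------------------------------------

def _system(net: ReactionNetwork, R: Sequence[str]):
    """Rows/cols of N restricted to R and the species R touches."""
    cols = [net.column(rid) for rid in R]
    species = sorted(net.species_of(R))
    rows = [net.row(sid) for sid in species]
    A = net.N[np.ix_(rows, cols)] if rows and cols else np.zeros((0, len(cols)), dtype=int)
    return A, rows, cols


def self_maintenance_witness(net: ReactionNetwork, R: Iterable[str],
                             tol: float = 1e-9,
                             float_screen: bool = True,
                             ) -> Optional[FluxVector]:
    """Return a certified self-maintenance flux for ``R``, or ``None``.

    The witness has ``v_j >= 1`` for reactions in ``R`` and ``v_j = 0``
    otherwise; ``None`` means no such flux exists.  Infeasibility is a
    value, not an error.
    """
    R = sorted(frozenset(R))
    for rid in R:
        if rid not in net.reactions_by_id:
            raise KeyError(f"unknown reaction id {rid!r}")
    if not R:
        return FluxVector.from_values(net, [0.0] * net.n, tol,
                                      exact=[Fraction(0)] * net.n)

    A, rows, cols = _system(net, R)
    ones = np.ones(len(cols), dtype=int)
    residual = A @ ones if A.size else np.zeros(len(rows), dtype=int)

    exact_u: Optional[list[Fraction]] = None
    if (residual >= 0).all():
        exact_u = [Fraction(0)] * len(cols)  # v = 1 already works
    else:
        if float_screen:
            # quick screen: minimize 0 s.t. -A u <= A 1, u >= 0
            res = linprog(c=np.zeros(len(cols)), A_ub=-A, b_ub=residual,
                          bounds=[(0, None)] * len(cols), method="highs")
            if not res.success:
                # authoritative exact confirmation of infeasibility
                confirm = exact_feasible(
                    [[Fraction(int(x)) for x in row] for row in A],
                    [Fraction(-int(r)) for r in residual])
                if confirm is None:
                    return None
                logger.warning("float LP screen disagreed with exact simplex "
                               "(screen: infeasible); using exact result")
                exact_u = confirm
        if exact_u is None:
            exact_u = exact_feasible(
                [[Fraction(int(x)) for x in row] for row in A],
                [Fraction(-int(r)) for r in residual])
            if exact_u is None:
                if float_screen:
                    logger.warning("float LP screen disagreed with exact "
                                   "simplex (screen: feasible); rejecting")
                return None

    exact_v = [Fraction(0)] * net.n
    for u_j, c in zip(exact_u, cols):
        exact_v[c] = u_j + 1
    # exact re-check of the certificate (cheap; guards the simplex itself)
    for row_idx, sid_row in enumerate(rows):
        total = sum(int(net.N[sid_row, c]) * exact_v[c] for c in cols)
        if total < 0:
            raise AssertionError("exact witness failed re-validation")
    return FluxVector.from_values(net, [float(x) for x in exact_v], tol,
                                  exact=exact_v)
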