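"""Dense two-phase primal simplex for small linear programs.

Solves  max c.x  subject to  A x = b, x >= 0  and reports the optimal
basic index set, which downstream basis-tracking code relies on.  An
external solver is deliberately not used here: the whole point of this
package is to reason about *which* optimal basis a solver lands on, so
the solver must expose its basis deterministically.  Bland's rule is
used throughout, trading speed for guaranteed termination and
reproducibility.  Problems in this package are small (tens to a few
hundred rows), so dense refactorisation each iteration is fine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimplexResult", "simplex_solve", "InfeasibleError", "UnboundedError"]


class InfeasibleError(ValueError):
    """The linear program has no feasible point."""

    def __init__(self, msg: str, violated_rows=None):
        super().__init__(msg)
        self.violated_rows = violated_rows or []


class UnboundedError(ValueError):
    """The objective is unbounded over the feasible region."""


@dataclass
class SimplexResult:
    x: np.ndarray          # primal solution, length = #columns of A
    basis: list            # basic column indices, length = #rows kept
    objective: float
    kept_rows: np.ndarray  # row indices of A retained (redundant rows dropped)
    iterations: int


def _bland_iterate(A, b, c, basis, *, tol, max_iter):
    """Run primal simplex iterations with Bland's rule; basis mutated in place."""
    m = A.shape[0]
    it = 0
    while True:
        it += 1
        if it > max_iter:
            raise RuntimeError("simplex iteration limit exceeded")
        B = A[:, basis]
        xB = np.linalg.solve(B, b)
        y = np.linalg.solve(B.T, c[basis])
        reduced = c - A.T @ y
        reduced[basis] = 0.0
        # Bland: smallest-index column with positive reduced cost enters
        candidates = np.flatnonzero(reduced > tol)
        if candidates.size == 0:
            return xB, it
        e = int(candidates[0])
        d = np.linalg.solve(B, A[:, e])
        pos = d > tol
        if not np.any(pos):
            raise UnboundedError("unbounded direction found in simplex")
        ratios = np.full(m, np.inf)
        ratios[pos] = xB[pos] / d[pos]
        theta = ratios.min()
        # Bland tie-break: among minimising rows, leave the smallest column index
        ties = np.flatnonzero(np.isclose(ratios, theta, rtol=0.0, atol=tol))
        leave = min(ties, key=lambda r: basis[r])
        basis[leave] = e


def simplex_solve(A, b, c, *, tol: float = 1e-9, max_iter: int = 50_000) -> SimplexResult:
    """Maximise ``c @ x`` subject to ``A x = b``, ``x >= 0``.

    Returns a basic optimal solution.  Rows of ``A`` found to be redundant
    in phase 1 are dropped (reported via ``kept_rows``).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).copy()
    c = np.asarray(c, dtype=float)
    m, n = A.shape
    if b.shape != (m,) or c.shape != (n,):
        raise ValueError("inconsistent LP dimensions")

    # normalise to b >= 0 so artificial variables start feasible
    A = A.copy()
    neg = b < 0
    A[neg] *= -1.0
    b[neg] *= -1.0

    # ---- phase 1: minimise sum of artificials -----------------------------
    A1 = np.hstack([A, np.eye(m)])
    c1 = np.concatenate([np.zeros(n), -np.ones(m)])
    basis = list(range(n, n + m))
    xB, it1 = _bland_iterate(A1, b, c1, basis, tol=tol, max_iter=max_iter)
    art_value = float(sum(xB[k] for k, j in enumerate(basis) if j >= n))
    if art_value > 1e-7 * (1.0 + np.abs(b).max(initial=0.0)):
        bad = [int(j - n) for j in basis if j >= n]
        raise InfeasibleError("phase-1 optimum positive: LP infeasible", violated_rows=bad)

    # drive remaining zero-valued artificials out of the basis
    keep = np.ones(m, dtype=bool)
    for k in range(m):
        if basis[k] < n:
            continue
        B = A1[:, basis]
        row = np.linalg.solve(B, A)[k]  # tableau row k over structural columns
        pivots = np.flatnonzero((np.abs(row) > 1e-8) & ~np.isin(np.arange(n), basis))
        if pivots.size:
            basis[k] = int(pivots[0])
        else:
            keep[k] = False  # structurally redundant constraint row

    kept_rows = np.flatnonzero(keep)
    A = A[keep]
    b = b[keep]
    basis = [basis[k] for k in range(m) if keep[k]]

    # ---- phase 2 ----------------------------------------------------------
    xB, it2 = _bland_iterate(A, b, c, basis, tol=tol, max_iter=max_iter)
    x = np.zeros(n)
    x[basis] = np.maximum(xB, 0.0)  # clip O(tol) negatives from degenerate pivots
    return SimplexResult(
        x=x,
        basis=list(basis),
        objective=float(c @ x),
        kept_rows=kept_rows,
        iterations=it1 + it2,
    )
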