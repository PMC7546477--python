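"""FBA linear program solving and forward-compatible basis selection.

The FBA problem for one organism is

    max gamma.phi   s.t.  A phi <= c(y, t),  Gamma_dagger phi = 0

As (y, t) drift, the optimal vertex moves but its *basis* — the set of
tight rows determining it — usually does not.  We therefore track a
d x d system B_J phi = c_J(y, t) and only return to an optimizer when
the tracked solution leaves the feasible region.  At that moment the
solution is degenerate (several bases describe the same optimum) and the
right basis to continue with is decided by a secondary linear program
over the solution's time derivative phi_dot: among all bases of the
current optimum, pick one whose forward motion stays feasible and grows
the objective fastest.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from ._simplex import InfeasibleError, UnboundedError, simplex_solve
from .model import ConstraintSystem

logger = logging.getLogger(__name__)

__all__ = [
    "StandardFormLP",
    "BasisState",
    "ForwardBasis",
    "FluxSolution",
    "ActiveSet",
    "DegenerateBasisError",
    "NotAVertexError",
    "build_standard_form",
    "solve_fba",
    "compute_basic_solution",
    "find_active_constraints",
    "select_forward_basis",
    "check_forward_feasibility",
    "enumerate_bases_of_solution",
]

#: relative tightness tolerance for active-constraint detection
ACTIVE_TOL = 1e-7
#: degeneracy tolerance on basic variables
DEGEN_TOL = 1e-9
#: feasibility tolerance
FEAS_TOL = 1e-8
#: box half-width applied to phi_dot when the secondary LP is under-constrained
PHIDOT_BOX = 1e6


class DegenerateBasisError(RuntimeError):
    """No basis with d independent tight rows could be reached."""


class NotAVertexError(RuntimeError):
    """The flux solution does not lie on a vertex of the feasible polytope."""


@dataclass
class StandardFormLP:
    """Equality form [A_tilde I](phi_tilde, s) = c with nonnegative variables.

    Free fluxes are split phi = phi+ - phi- unless the system is natively
    nonnegative.  Equality (steady-state) rows carry no slack and are
    appended after the n inequality rows.
    """

    A_full: np.ndarray          # (n + m_eq) x (n_var + n) column matrix
    gamma_tilde: np.ndarray     # objective over all columns (zeros on slacks)
    var_map: list               # per column: ("phi", j, +1/-1) or ("slack", row)
    n: int                      # inequality rows
    m_eq: int
    d: int
    split: bool
    system: ConstraintSystem

    @property
    def n_cols(self) -> int:
        return self.A_full.shape[1]

    def rhs(self, y, t) -> np.ndarray:
        c = np.asarray(self.system.c_of(y, t), dtype=float)
        return np.concatenate([c, np.zeros(self.m_eq)])

    def phi_from_w(self, w: np.ndarray) -> np.ndarray:
        phi = np.zeros(self.d)
        for j, (kind, *info) in enumerate(self.var_map):
            if kind == "phi":
                idx, sign = info
                phi[idx] += sign * w[j]
        return phi


def build_standard_form(system: ConstraintSystem, gamma) -> StandardFormLP:
    gamma = np.asarray(gamma, dtype=float)
    d, n, m_eq = system.d, system.n, system.m_eq
    split = not system.nonneg
    if split:
        var_cols = np.hstack([system.A, -system.A])
        eq_cols = np.hstack([system.Gamma_dagger, -system.Gamma_dagger])
        gamma_t = np.concatenate([gamma, -gamma])
        var_map = [("phi", j, +1) for j in range(d)] + [("phi", j, -1) for j in range(d)]
    else:
        var_cols = system.A.copy()
        eq_cols = system.Gamma_dagger.copy()
        gamma_t = gamma.copy()
        var_map = [("phi", j, +1) for j in range(d)]
    n_var = var_cols.shape[1]
    top = np.hstack([var_cols, np.eye(n)])
    bottom = np.hstack([eq_cols, np.zeros((m_eq, n))])
    A_full = np.vstack([top, bottom])
    gamma_full = np.concatenate([gamma_t, np.zeros(n)])
    var_map = var_map + [("slack", r) for r in range(n)]
    return StandardFormLP(
        A_full=A_full, gamma_tilde=gamma_full, var_map=var_map,
        n=n, m_eq=m_eq, d=d, split=split, system=system,
    )


@dataclass
class BasisState:
    """A basic index set I with its factorised basis matrix B_I."""

    index_set: tuple            # column indices into the standard-form matrix
    B: np.ndarray
    qr: tuple                   # (Q, R) factors of B
    objective_value: float
    std: StandardFormLP

    @classmethod
    def from_indices(cls, std: StandardFormLP, indices, objective_value=np.nan) -> "BasisState":
        B = std.A_full[:, list(indices)]
        Q, R = scipy.linalg.qr(B)
        return cls(index_set=tuple(indices), B=B, qr=(Q, R),
                   objective_value=float(objective_value), std=std)

    def solve(self, rhs: np.ndarray, *, singular_tol: float = 1e-10) -> np.ndarray:
        Q, R = self.qr
        if np.abs(np.diag(R)).min(initial=np.inf) <= singular_tol * max(1.0, np.abs(R).max()):
            raise DegenerateBasisError("basis lost: factorisation singular to tolerance")
        kept = getattr(self.std, "_kept_rows", None)
        if kept is not None and len(rhs) != self.B.shape[0]:
            rhs = np.asarray(rhs)[kept]
        return scipy.linalg.solve_triangular(R, Q.T @ rhs)


@dataclass
class FluxSolution:
    phi: np.ndarray
    psi: Optional[np.ndarray]   # exchange fluxes Gamma_star @ phi (None without a model)
    w: np.ndarray               # standard-form vector (variables then slacks)
    objective: float


def solve_fba(system: ConstraintSystem, gamma, y, t, *, tol: float = 1e-9):
    """Solve the FBA LP at (y, t), returning a basic (vertex) optimum.

    Uses the bundled simplex so the reported basic index set is
    deterministic.  Raises ``InfeasibleError`` (with the violated row
    set) or ``UnboundedError``.
    """
    std = build_standard_form(system, gamma)
    rhs = std.rhs(y, t)
    res = simplex_solve(std.A_full, rhs, std.gamma_tilde, tol=tol)
    if len(res.kept_rows) != std.A_full.shape[0]:
        # redundant rows were dropped in phase 1; rebuild a full-size basis by
        # re-solving on the reduced system is unnecessary — pad with slacks of
        # dropped rows is invalid, so keep the reduced basis but remember rows.
        logger.debug("simplex dropped %d redundant rows",
                     std.A_full.shape[0] - len(res.kept_rows))
    w = res.x
    phi = std.phi_from_w(w)
    psi = None if system.Gamma_star is None else system.Gamma_star @ phi
    sol = FluxSolution(phi=phi, psi=psi, w=w, objective=res.objective)
    basis = BasisState.from_indices(std, res.basis, res.objective) \
        if len(res.kept_rows) == std.A_full.shape[0] else \
        BasisState.from_indices(_drop_redundant(std, res.kept_rows), res.basis, res.objective)
    return sol, basis


def _drop_redundant(std: StandardFormLP, kept_rows) -> StandardFormLP:
    kept = np.asarray(kept_rows)
    sub = StandardFormLP(
        A_full=std.A_full[kept], gamma_tilde=std.gamma_tilde, var_map=std.var_map,
        n=std.n, m_eq=std.m_eq, d=std.d, split=std.split, system=std.system)
    # note: rhs() no longer matches row count; callers of a reduced basis must
    # subset the rhs themselves via kept rows.  Only used for degenerate GEMs
    # whose Gamma_dagger has dependent rows.
    sub._kept_rows = kept  # type: ignore[attr-defined]
    return sub


def compute_basic_solution(basis: BasisState, rhs: np.ndarray) -> np.ndarray:
    """Scatter B_I^{-1} rhs into a full standard-form vector (zeros off-basis)."""
    vals = basis.solve(rhs)
    w = np.zeros(basis.std.n_cols)
    w[list(basis.index_set)] = vals
    return w


@dataclass
class ActiveSet:
    """Tight rows of the extended row universe at a flux solution."""

    rows: list                  # global row ids, ascending
    system: ConstraintSystem
    phi: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return self.system.row_matrix(self.rows)


def find_active_constraints(phi, system: ConstraintSystem, y, t, *,
                            tol: float = ACTIVE_TOL,
                            require_vertex: bool = True) -> ActiveSet:
    """All rows with a.phi = c to tolerance, plus every steady-state row.

    With a vertex (basic) solution the active rows have rank d; if not,
    ``NotAVertexError`` asks the caller to re-solve with vertex
    enforcement.
    """
    phi = np.asarray(phi, dtype=float)
    c = np.asarray(system.c_of(y, t), dtype=float)
    resid = c - system.A @ phi
    rows = [int(r) for r in np.flatnonzero(np.abs(resid) <= tol * (1.0 + np.abs(c)))]
    rows += list(range(system.n, system.n + system.m_eq))
    if system.nonneg:
        base = system.n + system.m_eq
        rows += [base + j for j in range(system.d) if phi[j] <= tol]
    rows = sorted(rows)
    act = ActiveSet(rows=rows, system=system, phi=phi)
    if require_vertex:
        rank = np.linalg.matrix_rank(act.matrix, tol=1e-8) if rows else 0
        if rank < system.d:
            raise NotAVertexError(
                f"active set rank {rank} < d={system.d}: not a vertex solution")
    return act


@dataclass
class ForwardBasis:
    """The d x d reduced forward system B phi = c_J(y, t).

    ``row_subset`` (J) are global row ids whose constraints are held
    tight; steady-state and nonnegativity rows contribute zero right-hand
    sides for all time.
    """

    active_rows: list
    row_subset: list
    B_reduced: np.ndarray
    qr: tuple
    system: ConstraintSystem
    phi_dot: np.ndarray
    objective_rate: float
    boxed: bool = False         # secondary LP needed the phi_dot box

    @property
    def d(self) -> int:
        return self.B_reduced.shape[0]

    def rhs_selector(self, y, t) -> np.ndarray:
        return self.system.rhs_rows(self.row_subset, y, t)

    def phi_at(self, y, t) -> np.ndarray:
        Q, R = self.qr
        return scipy.linalg.solve_triangular(R, Q.T @ self.rhs_selector(y, t))


def _push_to_vertex(M_act, rhs_dot, eq_mask, gamma, u, tight, *, box: float, tol: float):
    """Move u along objective-neutral null directions until d tight rows.

    ``tight`` is a boolean mask over the active rows; returns the updated
    (u, tight).  Each move keeps all currently tight rows tight and the
    objective value unchanged, so optimality of the secondary LP is
    preserved while the solution slides to a vertex of its optimal face.
    This plays the role of manually pivoting non-slack variables into a
    degenerate solver basis.
    """
    d = M_act.shape[1]
    for _ in range(2 * d + 2):
        T = M_act[tight]
        if T.size and np.linalg.matrix_rank(T, tol=1e-9) >= d:
            return u, tight
        stack = np.vstack([T, gamma[None, :]]) if T.size else gamma[None, :]
        ns = scipy.linalg.null_space(stack, rcond=1e-10)
        if ns.shape[1] == 0:
            # gamma not in span(T) would contradict optimality; treat as done
            return u, tight
        z = ns[:, 0]
        moved = False
        for direction in (z, -z):
            Mz = M_act @ direction
            slack = np.maximum(rhs_dot - M_act @ u, 0.0)
            blocking = (~tight) & (Mz > tol)
            thetas = np.full(M_act.shape[0], np.inf)
            thetas[blocking] = slack[blocking] / Mz[blocking]
            theta = thetas.min(initial=np.inf)
            # distance to the |u_j| <= box safeguard along this direction
            box_theta = np.inf
            for j in np.flatnonzero(np.abs(direction) > tol):
                if direction[j] > 0:
                    box_theta = min(box_theta, (box - u[j]) / direction[j])
                else:
                    box_theta = min(box_theta, (u[j] + box) / -direction[j])
            if np.isfinite(theta) and theta <= box_theta:
                u = u + theta * direction
                newly = blocking & np.isclose(thetas, theta, rtol=0.0, atol=1e-9)
                tight = tight | newly
                moved = True
                break
            # blocked only by the box: no real row gained, try other direction
        if not moved:
            raise DegenerateBasisError(
                "secondary LP optimal face has no vertex within real constraint rows")
    raise DegenerateBasisError("failed to reach a vertex of the secondary LP optimum")


def select_forward_basis(solution, active: ActiveSet, dcdt, gamma, *,
                         box: float = PHIDOT_BOX,
                         tol: float = 1e-9) -> ForwardBasis:
    """Choose a forward-compatible basis for a (possibly degenerate) optimum.

    Solves the secondary LP  max gamma.phi_dot  s.t.
    a_j.phi_dot <= dc_j/dt over the active rows (steady-state rows as
    equalities with zero rate), then selects d linearly independent tight
    rows — the reduced matrix B.  The solution is pushed to a vertex of
    its optimal face if the optimizer returns a face-interior point, and
    ties among eligible row sets are broken lexicographically for
    reproducibility.
    """
    system = active.system
    d = system.d
    rows = list(active.rows)
    dcdt = np.asarray(dcdt, dtype=float)
    if dcdt.shape != (len(rows),):
        raise ValueError("dcdt must align with the active rows")
    gamma = np.asarray(gamma, dtype=float)
    M = system.row_matrix(rows)
    eq_mask = np.array([system.row_kind(r) == "eq" for r in rows])

    # standard form: u = u+ - u-, slack per inequality row, plus box rows
    n_act = len(rows)
    ineq_idx = np.flatnonzero(~eq_mask)
    eq_idx = np.flatnonzero(eq_mask)
    n_ineq = ineq_idx.size
    A_cols = np.hstack([M, -M])
    rows_ineq = np.hstack([A_cols[ineq_idx], np.eye(n_ineq)])
    rows_eq = np.hstack([A_cols[eq_idx], np.zeros((eq_idx.size, n_ineq))])
    box_block = np.hstack([np.eye(d), np.eye(d), np.zeros((d, n_ineq))])  # u+ + u- <= box... see note
    # |u_j| <= box is enforced as u+_j + u-_j <= box, which contains the box and
    # is tight only when the optimizer pushes a component to the artificial bound.
    box_slack = np.eye(d)
    A_std = np.vstack([
        np.hstack([rows_ineq, np.zeros((n_ineq, d))]),
        np.hstack([rows_eq, np.zeros((eq_idx.size, d))]),
        np.hstack([box_block, box_slack]),
    ])
    b_std = np.concatenate([dcdt[ineq_idx], dcdt[eq_idx] * 0.0, np.full(d, box)])
    c_std = np.concatenate([gamma, -gamma, np.zeros(n_ineq + d)])
    try:
        res = simplex_solve(A_std, b_std, c_std)
    except UnboundedError:  # pragma: no cover - box makes this unreachable
        raise
    u = res.x[:d] - res.x[d:2 * d]
    boxed = bool(np.any(np.abs(u) >= box * (1 - 1e-9)))
    if boxed:
        warnings.warn("secondary LP under-constrained: phi_dot limited by box bound",
                      RuntimeWarning, stacklevel=2)

    resid = dcdt - M @ u
    tight = np.abs(resid) <= max(tol, 1e-9) * (1.0 + np.abs(dcdt))
    tight = tight | eq_mask
    u, tight = _push_to_vertex(M, dcdt, eq_mask, gamma, u, tight, box=box, tol=tol)

    # lexicographically smallest independent subset of tight rows (greedy)
    J, rows_J = [], []
    for k in np.flatnonzero(tight):
        cand = rows_J + [M[k]]
        if np.linalg.matrix_rank(np.vstack(cand), tol=1e-9) == len(cand):
            J.append(rows[k])
            rows_J.append(M[k])
        if len(J) == d:
            break
    if len(J) < d:
        raise DegenerateBasisError(
            f"only {len(J)} independent tight rows at the secondary optimum "
            f"(need d={d}); tolerance failure")
    B = np.vstack(rows_J)
    Q, R = scipy.linalg.qr(B)
    return ForwardBasis(
        active_rows=rows, row_subset=J, B_reduced=B, qr=(Q, R),
        system=system, phi_dot=u, objective_rate=float(gamma @ u), boxed=boxed,
    )


def check_forward_feasibility(basis: ForwardBasis, system: ConstraintSystem, y, t,
                              *, feas_tol: float = FEAS_TOL):
    """Evaluate the tracked solution phi = B^{-1} c_J(y, t) on all rows.

    Returns ``(feasible, violated_rows)`` with global row ids; a pure
    predicate used by the event loop of the simulator.
    """
    phi = basis.phi_at(y, t)
    c = np.asarray(system.c_of(y, t), dtype=float)
    violated = [int(r) for r in np.flatnonzero(system.A @ phi - c > feas_tol * (1.0 + np.abs(c)))]
    if system.m_eq:
        eqres = system.Gamma_dagger @ phi
        violated += [system.n + int(r) for r in np.flatnonzero(np.abs(eqres) > feas_tol)]
    if system.nonneg:
        base = system.n + system.m_eq
        violated += [base + int(j) for j in np.flatnonzero(phi < -feas_tol)]
    return (len(violated) == 0), violated


def enumerate_bases_of_solution(std: StandardFormLP, w, rhs, *, tol: float = 1e-7):
    """Brute-force all basic index sets representing the solution ``w``.

    Exponential in problem size; intended for tiny instances (oracle
    checks and the fully-worked textbook system).
    """
    w = np.asarray(w, dtype=float)
    N = std.A_full.shape[0]
    ncols = std.n_cols
    support = set(np.flatnonzero(np.abs(w) > tol).tolist())
    bases = []
    for combo in itertools.combinations(range(ncols), N):
        if not support.issubset(combo):
            continue
        B = std.A_full[:, list(combo)]
        if abs(np.linalg.det(B)) < 1e-10:
            continue
        vals = np.linalg.solve(B, rhs)
        w_c = np.zeros(ncols)
        w_c[list(combo)] = vals
        if np.allclose(w_c, w, atol=tol):
            bases.append(tuple(combo))
    return bases
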