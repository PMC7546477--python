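"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's simplex/basis machinery: vertex
enumeration solves tiny LPs by checking every d-subset of constraint
rows, and the forward-basis oracle enumerates every basic index set of a
given optimum and scores each by hand.
"""

import itertools

import numpy as np


def enumerate_vertices(A, c, *, nonneg=True, tol=1e-9):
    """All vertices of {A v <= c (, v >= 0)} by d-row intersection."""
    n, d = A.shape
    rows = [A[i] for i in range(n)]
    rhs = list(c)
    if nonneg:
        for j in range(d):
            e = np.zeros(d)
            e[j] = -1.0
            rows.append(e)
            rhs.append(0.0)
    rows = np.array(rows)
    rhs = np.array(rhs)
    verts = []
    for combo in itertools.combinations(range(len(rows)), d):
        M = rows[list(combo)]
        if abs(np.linalg.det(M)) < 1e-10:
            continue
        v = np.linalg.solve(M, rhs[list(combo)])
        if np.all(rows @ v <= rhs + tol * (1 + np.abs(rhs))):
            verts.append(v)
    return verts


def brute_force_lp_max(A, c, gamma, *, nonneg=True):
    """Optimal objective by exhaustive vertex enumeration."""
    verts = enumerate_vertices(A, c, nonneg=nonneg)
    if not verts:
        raise ValueError("no vertices: infeasible or unbounded test instance")
    return max(float(np.asarray(gamma) @ v) for v in verts)


def forward_rates_of_basis(A_full, basis, cdot, d, w_star, *, tol=1e-8):
    """w_dot of a basic index set under bound drift cdot, plus feasibility.

    ``A_full`` is the standard-form column matrix, ``basis`` the column
    index set.  Returns (phi_dot, feasible_forward) where the forward
    condition asks every zero entry of w* to have a nonnegative rate.
    """
    B = A_full[:, list(basis)]
    vals = np.linalg.solve(B, cdot)
    wdot = np.zeros(A_full.shape[1])
    wdot[list(basis)] = vals
    feasible = all(wdot[j] >= -tol for j in range(len(wdot)) if abs(w_star[j]) <= tol)
    return wdot[:d], feasible


def make_degenerate_lp(seed, *, d=2, n_extra=2, n_tight=3):
    """Random native-nonneg LP whose optimum is degenerate by construction.

    A strictly positive vertex v* is given ``n_tight`` > d tight rows;
    the objective is a positive combination of their normals, so v* is
    optimal (KKT) and its standard-form solution has more zero entries
    than non-basic variables.  Returns (A, c_fun, cdot, gamma, v_star)
    with c(t) = c0 + t * cdot.
    """
    rng = np.random.default_rng(seed)
    for _ in range(50):
        v_star = rng.uniform(0.5, 2.0, size=d)
        At = rng.normal(size=(n_tight, d))
        if np.linalg.matrix_rank(At, tol=1e-6) < d:
            continue
        lam = rng.uniform(0.2, 1.0, size=n_tight)
        gamma = lam @ At
        if np.abs(gamma).max() < 1e-3:
            continue
        A_extra = rng.normal(size=(n_extra, d))
        c_tight = At @ v_star
        c_extra = A_extra @ v_star + rng.uniform(0.5, 2.0, size=n_extra)
        A = np.vstack([At, A_extra])
        c0 = np.concatenate([c_tight, c_extra])
        # drift must leave the LP feasible for small t > 0 (as coherent bound
        # motion does): give the tight rows rates compatible with a common
        # forward direction u0, slack on a random subset
        u0 = rng.normal(scale=0.5, size=d)
        eps = rng.uniform(0.0, 1.0, size=n_tight) * rng.integers(0, 2, size=n_tight)
        cdot_tight = At @ u0 + eps
        cdot = np.concatenate([cdot_tight, rng.uniform(-1.0, 1.0, size=n_extra)])
        return A, c0, cdot, gamma, v_star
    raise RuntimeError("could not build a degenerate instance")
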