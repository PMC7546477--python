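"""Genome-scale metabolic model representation and FBA constraint assembly.

A community dFBA simulation treats each organism as a linear program
over its *internal* fluxes phi.  The stoichiometric matrix is split into
blocks: exchange reactions have standard-basis stoichiometry, so the
full matrix can be written

    Gamma = [[ I, -Gamma_star ],
             [ 0,  Gamma_dagger ]]

with the external-metabolite rows on top.  Exchange fluxes are then a
linear image of the internal ones, psi = Gamma_star @ phi (uptake
positive), and the steady-state condition collapses to
Gamma_dagger @ phi = 0.  This module performs that partition and builds
the inequality system A phi <= c(y, t) whose right-hand side carries the
(possibly metabolite-dependent) flux bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicModel",
    "BoundSpec",
    "ConstraintSystem",
    "ModelError",
    "partition_stoichiometry",
    "build_constraint_system",
    "linear_uptake_bounds",
    "BIG_BOUND",
]

#: replacement for infinite bounds so the standard-form LP stays bounded
BIG_BOUND = 1.0e3


class ModelError(ValueError):
    """Raised for structurally invalid metabolic models."""


@dataclass
class MetabolicModel:
    """Partitioned stoichiometry of one organism.

    ``Gamma_star`` is m_ext x d (columns are internal reactions, rows the
    external metabolites; entry > 0 means the reaction consumes the
    metabolite under the uptake-positive sign convention).
    ``Gamma_dagger`` is m_int x d and its rows are steady-state equalities.
    ``gamma`` holds objective weights on the d internal fluxes.
    """

    species_id: str
    metabolite_ids: list          # external metabolite identifiers, length m_ext
    internal_metabolite_ids: list
    Gamma_star: np.ndarray
    Gamma_dagger: np.ndarray
    gamma: np.ndarray
    exchange_map: dict            # external metabolite index -> exchange reaction id
    reaction_ids: list            # internal reaction ids, length d
    sign_flipped: list = field(default_factory=list)  # exchange rxns flipped to uptake-positive

    def __post_init__(self):
        self.Gamma_star = np.atleast_2d(np.asarray(self.Gamma_star, dtype=float))
        self.Gamma_dagger = np.asarray(self.Gamma_dagger, dtype=float).reshape(-1, self.Gamma_star.shape[1])
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.Gamma_star.shape[1] != self.Gamma_dagger.shape[1]:
            raise ModelError("Gamma_star and Gamma_dagger must share a column count")
        if self.gamma.shape != (self.d,):
            raise ModelError("objective length must equal the internal flux count")
        if len(set(self.exchange_map.values())) != len(self.exchange_map):
            raise ModelError("exchange_map must be injective")

    @property
    def d(self) -> int:
        return self.Gamma_star.shape[1]

    @property
    def m_ext(self) -> int:
        return self.Gamma_star.shape[0]

    @property
    def m_int(self) -> int:
        return self.Gamma_dagger.shape[0]

    def reassemble(self) -> np.ndarray:
        """Rebuild the full stoichiometric matrix in partitioned order."""
        top = np.hstack([np.eye(self.m_ext), -self.Gamma_star])
        bottom = np.hstack([np.zeros((self.m_int, self.m_ext)), self.Gamma_dagger])
        return np.vstack([top, bottom])


@dataclass
class BoundSpec:
    """Flux bounds for one organism.

    Exchange bounds act on psi = Gamma_star @ phi (uptake positive); a
    dynamic row replaces its static upper bound with kappa_j * y_j, the
    mass-action-style uptake ceiling.  Internal bounds act on phi
    directly.  Infinite entries are replaced by ``big`` and logged so the
    standard-form LP stays bounded.
    """

    exchange_lower: np.ndarray
    exchange_upper: np.ndarray        # static upper bounds c2 per external metabolite
    internal_lower: np.ndarray
    internal_upper: np.ndarray
    kappa: Optional[np.ndarray] = None      # uptake rate per external metabolite (1/time)
    is_dynamic: Optional[np.ndarray] = None  # mask: rows whose upper bound is kappa*y
    big: float = BIG_BOUND

    def __post_init__(self):
        for name in ("exchange_lower", "exchange_upper", "internal_lower", "internal_upper"):
            arr = np.asarray(getattr(self, name), dtype=float).copy()
            inf = ~np.isfinite(arr)
            if inf.any():
                logger.info("replacing %d infinite entries of %s with +/-%g", inf.sum(), name, self.big)
                arr[inf] = np.sign(arr[inf]) * self.big
                # sign(inf)=+-1; sign(nan) would propagate, reject
                if np.isnan(arr).any():
                    raise ModelError(f"NaN bound in {name}")
            setattr(self, name, arr)
        m_ext = self.exchange_lower.shape[0]
        if self.is_dynamic is None:
            self.is_dynamic = np.zeros(m_ext, dtype=bool)
        self.is_dynamic = np.asarray(self.is_dynamic, dtype=bool)
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)
            if (self.kappa < 0).any():
                raise ModelError("kappa must be nonnegative")
        if self.is_dynamic.any() and self.kappa is None:
            raise ModelError("dynamic exchange rows require kappa")
        static = ~self.is_dynamic
        if np.any(self.exchange_lower[static] > self.exchange_upper[static] + 1e-12):
            raise ModelError("exchange lower bound exceeds upper bound")
        if np.any(self.internal_lower > self.internal_upper + 1e-12):
            raise ModelError("internal lower bound exceeds upper bound")

    @classmethod
    def default_static(cls, model: MetabolicModel, uptake_cap: float = 10.0) -> "BoundSpec":
        return cls(
            exchange_lower=np.zeros(model.m_ext),
            exchange_upper=np.full(model.m_ext, uptake_cap),
            internal_lower=np.zeros(model.d),
            internal_upper=np.full(model.d, BIG_BOUND),
        )

    @classmethod
    def linear_uptake(cls, model: MetabolicModel, kappa) -> "BoundSpec":
        kappa = np.broadcast_to(np.asarray(kappa, dtype=float), (model.m_ext,)).copy()
        return cls(
            exchange_lower=np.zeros(model.m_ext),
            exchange_upper=np.full(model.m_ext, BIG_BOUND),
            internal_lower=np.zeros(model.d),
            internal_upper=np.full(model.d, BIG_BOUND),
            kappa=kappa,
            is_dynamic=np.ones(model.m_ext, dtype=bool),
        )


@dataclass
class ConstraintSystem:
    """The inequality system A phi <= c(y, t) plus equality rows.

    ``A`` is stacked in the fixed block order [Gamma_star; -Gamma_star; I; -I]
    so row indices are reproducible; ``row_labels`` records the
    (bound kind, reaction/metabolite) meaning of each row.  Equality rows
    (Gamma_dagger) are held separately and never folded into ``A``.
    ``nonneg`` marks systems whose variables are natively nonnegative
    (phi >= 0 is part of the geometry rather than rows of A).
    """

    A: np.ndarray
    c_of: Callable
    n: int
    Gamma_dagger: np.ndarray
    row_labels: list
    dc_of: Optional[Callable] = None   # (y, t, ydot) -> dc/dt, length n
    nonneg: bool = False
    Gamma_star: Optional[np.ndarray] = None  # set when built from a MetabolicModel

    @property
    def d(self) -> int:
        return self.A.shape[1]

    @property
    def m_eq(self) -> int:
        return self.Gamma_dagger.shape[0]

    # ---- extended row universe -------------------------------------------
    # Global row ids: 0..n-1 inequality rows of A, then m_eq equality rows,
    # then (if nonneg) d variable-nonnegativity rows -e_j . phi <= 0.

    @property
    def n_rows_total(self) -> int:
        return self.n + self.m_eq + (self.d if self.nonneg else 0)

    def row_kind(self, row: int) -> str:
        if row < self.n:
            return "ineq"
        if row < self.n + self.m_eq:
            return "eq"
        return "nonneg"

    def row_matrix(self, rows: Sequence[int]) -> np.ndarray:
        out = np.empty((len(rows), self.d))
        for k, r in enumerate(rows):
            kind = self.row_kind(r)
            if kind == "ineq":
                out[k] = self.A[r]
            elif kind == "eq":
                out[k] = self.Gamma_dagger[r - self.n]
            else:
                out[k] = 0.0
                out[k, r - self.n - self.m_eq] = -1.0
        return out

    def rhs_rows(self, rows: Sequence[int], y, t) -> np.ndarray:
        c = None
        out = np.zeros(len(rows))
        for k, r in enumerate(rows):
            if self.row_kind(r) == "ineq":
                if c is None:
                    c = np.asarray(self.c_of(y, t), dtype=float)
                out[k] = c[r]
        return out

    def drhs_rows(self, rows: Sequence[int], y, t, ydot) -> np.ndarray:
        dc = None
        out = np.zeros(len(rows))
        for k, r in enumerate(rows):
            if self.row_kind(r) == "ineq":
                if dc is None:
                    if self.dc_of is None:
                        dc = np.zeros(self.n)
                    else:
                        dc = np.asarray(self.dc_of(y, t, ydot), dtype=float)
                out[k] = dc[r]
        return out

    def label(self, row: int) -> str:
        kind = self.row_kind(row)
        if kind == "ineq":
            return self.row_labels[row]
        if kind == "eq":
            return f"steady_state[{row - self.n}]"
        return f"nonneg[phi_{row - self.n - self.m_eq}]"


def partition_stoichiometry(full_matrix, exchange_reaction_flags, *,
                            external_metabolite_rows=None,
                            species_id: str = "organism",
                            reaction_ids=None,
                            metabolite_ids=None,
                            gamma=None) -> MetabolicModel:
    """Split a full stoichiometric matrix into (Gamma_star, Gamma_dagger).

    Flagged exchange columns must be signed unit vectors; the row each
    one hits is an external metabolite.  Columns are sign-normalised to
    the uptake-positive convention (unit entry +1) and any flip recorded.
    """
    G = np.atleast_2d(np.asarray(full_matrix, dtype=float)).copy()
    flags = np.asarray(exchange_reaction_flags, dtype=bool)
    m, r = G.shape
    if flags.shape != (r,):
        raise ModelError("exchange flag list must match the reaction count")
    exch_cols = np.flatnonzero(flags)
    int_cols = np.flatnonzero(~flags)
    d = int_cols.size
    if d == 0:
        raise ModelError("degenerate model: no internal fluxes to optimize (d = 0)")

    if reaction_ids is None:
        reaction_ids = [f"rxn_{j}" for j in range(r)]
    if metabolite_ids is None:
        metabolite_ids = [f"met_{i}" for i in range(m)]

    ext_rows = []
    exch_of_row = {}
    flipped = []
    for j in exch_cols:
        nz = np.flatnonzero(np.abs(G[:, j]) > 0)
        if nz.size != 1 or not np.isclose(abs(G[nz[0], j]), 1.0):
            raise ModelError(
                f"exchange column {reaction_ids[j]} is not a signed unit vector")
        row = int(nz[0])
        if row in exch_of_row:
            raise ModelError(
                f"metabolite {metabolite_ids[row]} has multiple exchange reactions")
        if G[row, j] < 0:  # secretion-positive source convention: flip
            G[:, j] *= -1.0
            flipped.append(reaction_ids[j])
        exch_of_row[row] = j
        ext_rows.append(row)

    if external_metabolite_rows is not None:
        declared = list(external_metabolite_rows)
        missing = set(declared) - set(ext_rows)
        if missing:
            names = [metabolite_ids[i] for i in sorted(missing)]
            raise ModelError(f"external metabolites without exchange reaction: {names}")
        ext_rows = declared
    ext_rows = sorted(ext_rows)
    int_rows = [i for i in range(m) if i not in ext_rows]

    # internal rows must not touch exchange columns (guaranteed by the unit test
    # above: each exchange column's single nonzero sits in an external row)
    Gamma_star = -G[np.ix_(ext_rows, int_cols)]
    Gamma_dagger = G[np.ix_(int_rows, int_cols)]
    if gamma is None:
        gamma = np.zeros(d)
    return MetabolicModel(
        species_id=species_id,
        metabolite_ids=[metabolite_ids[i] for i in ext_rows],
        internal_metabolite_ids=[metabolite_ids[i] for i in int_rows],
        Gamma_star=Gamma_star,
        Gamma_dagger=Gamma_dagger,
        gamma=np.asarray(gamma, dtype=float),
        exchange_map={k: reaction_ids[exch_of_row[row]] for k, row in enumerate(ext_rows)},
        reaction_ids=[reaction_ids[j] for j in int_cols],
        sign_flipped=flipped,
    )


def linear_uptake_bounds(kappa, y) -> np.ndarray:
    """Mass-action uptake ceilings c2_ij = kappa_ij * y_j.

    ``kappa`` may be a vector (one organism) or an organism x metabolite
    matrix; uptake ceases when a metabolite is exhausted (y_j = 0).
    """
    kappa = np.asarray(kappa, dtype=float)
    y = np.asarray(y, dtype=float)
    if (kappa < 0).any():
        raise ValueError("kappa must be nonnegative")
    if (y < 0).any():
        raise ValueError("metabolite concentrations must be nonnegative")
    return kappa * y


def build_constraint_system(model: MetabolicModel, bounds: BoundSpec) -> ConstraintSystem:
    """Stack A = [Gamma_star; -Gamma_star; I; -I] and its bound vector c(y, t)."""
    m_ext, d = model.m_ext, model.d
    if bounds.exchange_lower.shape != (m_ext,) or bounds.internal_lower.shape != (d,):
        raise ModelError("bound specification does not match model dimensions")
    A = np.vstack([model.Gamma_star, -model.Gamma_star, np.eye(d), -np.eye(d)])
    n = 2 * m_ext + 2 * d

    dyn = bounds.is_dynamic
    kappa = bounds.kappa
    ex_up = bounds.exchange_upper
    ex_lo = bounds.exchange_lower
    in_up = bounds.internal_upper
    in_lo = bounds.internal_lower

    def c_of(y, t):
        upper = ex_up.copy()
        if dyn.any():
            yv = np.maximum(np.asarray(y, dtype=float), 0.0)
            upper[dyn] = kappa[dyn] * yv[dyn]
        return np.concatenate([upper, -ex_lo, in_up, -in_lo])

    def dc_of(y, t, ydot):
        out = np.zeros(n)
        if dyn.any() and ydot is not None:
            yd = np.asarray(ydot, dtype=float)
            out[:m_ext][dyn] = kappa[dyn] * yd[dyn]
        return out

    labels = (
        [f"uptake_ub[{mid}]" for mid in model.metabolite_ids]
        + [f"uptake_lb[{mid}]" for mid in model.metabolite_ids]
        + [f"flux_ub[{rid}]" for rid in model.reaction_ids]
        + [f"flux_lb[{rid}]" for rid in model.reaction_ids]
    )
    return ConstraintSystem(
        A=A, c_of=c_of, n=n, Gamma_dagger=model.Gamma_dagger,
        row_labels=labels, dc_of=dc_of, nonneg=False, Gamma_star=model.Gamma_star,
    )
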