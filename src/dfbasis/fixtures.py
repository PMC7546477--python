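"""Self-contained test systems: the worked dynamic LP and synthetic toy GEMs.

Everything here is generated programmatically so the full test suite and
all desk-scale experiments run without network access or external model
files.  ``make_toy_model`` additionally returns closed-form growth and
depletion quantities so simulator output can be checked against pencil-
and-paper solutions.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .model import (
    BIG_BOUND,
    BoundSpec,
    ConstraintSystem,
    MetabolicModel,
)

__all__ = ["make_example1", "make_toy_model", "make_toy_community"]


def make_example1(slope: float = 1.0):
    """The fully worked degenerate dynamic LP.

        max (1,1).v   s.t.  [[1,0],[0,1],[1,2]] v <= (10, 10, 30 - slope*t),
        v >= 0 (native)

    At t = 0 the optimum w* = (10, 10, 0, 0, 0) is degenerate with three
    bases; only one of them tracks the shrinking third bound.  ``slope``
    scales the drift rate of that bound (default 1, the textbook case;
    other values move the re-optimization event off round time points).

    Returns ``(system, gamma)``.
    """
    A = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 2.0]])

    def c_of(y, t):
        return np.array([10.0, 10.0, 30.0 - slope * t])

    def dc_of(y, t, ydot):
        return np.array([0.0, 0.0, -slope])

    system = ConstraintSystem(
        A=A,
        c_of=c_of,
        n=3,
        Gamma_dagger=np.zeros((0, 2)),
        row_labels=["v1_ub", "v2_ub", "mix_ub"],
        dc_of=dc_of,
        nonneg=True,
    )
    return system, np.array([1.0, 1.0])


def make_toy_model(seed: int, n_metabolites: int = 2, n_internal: int = 2, *,
                   uptake: str = "static", kappa=None, uptake_cap: float = 2.0):
    """Generate a random feasible toy GEM with a known growth optimum.

    The architecture is a proportional chain: flux 0 consumes nutrient 0,
    and internal metabolites tie each further flux to flux 0 at a fixed
    ratio, so the FBA optimum is a single non-degenerate vertex whose
    growth rate and nutrient consumption have closed forms.  Nutrient 0
    is essential by construction: with it exhausted the optimum is zero
    growth.

    Parameters
    ----------
    uptake : "static" or "linear"
        Static uptake ceilings (closed-form depletion dynamics) or
        mass-action ceilings kappa_j * y_j.

    Returns ``(model, bounds, notes)`` where ``notes`` carries mu (growth
    rate at the reference medium), phi_star, sigma (consumption per unit
    biomass per nutrient), reference_medium, and for the static case a
    ``depletion_time(y0, x0)`` callable and ``final_biomass(y0, x0)``.
    """
    if n_metabolites < 1 or n_internal < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    d, m_ext = n_internal, n_metabolites

    consume = rng.uniform(0.5, 1.5, size=min(m_ext, d))
    Gamma_star = np.zeros((m_ext, d))
    for j in range(min(m_ext, d)):
        Gamma_star[j, j] = consume[j]

    # chain couplings: flux j proportional to flux j-1
    m_int = max(d - 1, 0)
    Gamma_dagger = np.zeros((m_int, d))
    ratio = np.ones(d)
    for k in range(m_int):
        a = rng.uniform(0.5, 1.5)
        b = rng.uniform(0.5, 1.5)
        Gamma_dagger[k, k] = a
        Gamma_dagger[k, k + 1] = -b
        ratio[k + 1] = ratio[k] * a / b

    gamma = rng.uniform(0.5, 1.5, size=d)

    model = MetabolicModel(
        species_id=f"toy_{seed}",
        metabolite_ids=[f"met{j}" for j in range(m_ext)],
        internal_metabolite_ids=[f"imet{k}" for k in range(m_int)],
        Gamma_star=Gamma_star,
        Gamma_dagger=Gamma_dagger,
        gamma=gamma,
        exchange_map={j: f"EX_met{j}" for j in range(m_ext)},
        reaction_ids=[f"v{j}" for j in range(d)],
    )

    # effective objective per unit of flux 0 along the chain
    gamma_eff = float(gamma @ ratio)
    # uptake of nutrient j per unit flux 0
    sigma_per_phi0 = np.array([Gamma_star[j] @ ratio for j in range(m_ext)])

    if uptake == "static":
        caps = np.full(m_ext, BIG_BOUND)
        caps[0] = uptake_cap  # nutrient 0 binding: unique vertex optimum
        bounds = BoundSpec(
            exchange_lower=np.zeros(m_ext),
            exchange_upper=caps,
            internal_lower=np.zeros(d),
            internal_upper=np.full(d, BIG_BOUND),
        )
        phi0 = uptake_cap / sigma_per_phi0[0]
    elif uptake == "linear":
        if kappa is None:
            kappa = rng.uniform(0.2, 1.0, size=m_ext)
        bounds = BoundSpec.linear_uptake(model, kappa)
        phi0 = None  # depends on y
    else:
        raise ValueError("uptake must be 'static' or 'linear'")

    reference_medium = {f"met{j}": 10.0 for j in range(m_ext)}
    notes = {
        "gamma_eff": gamma_eff,
        "ratio": ratio,
        "sigma_per_phi0": sigma_per_phi0,
        "reference_medium": reference_medium,
    }
    if uptake == "static":
        mu = gamma_eff * phi0
        sigma = sigma_per_phi0 * phi0  # nutrient consumption per unit biomass
        notes["phi_star"] = ratio * phi0
        notes["mu"] = mu
        notes["sigma"] = sigma

        def depletion_time(y0: float, x0: float) -> float:
            """Time at which nutrient 0 is exhausted, from x(t) = x0 e^{mu t}."""
            return math.log(1.0 + mu * y0 / (sigma[0] * x0)) / mu

        def final_biomass(y0: float, x0: float) -> float:
            return x0 + (mu / sigma[0]) * y0

        notes["depletion_time"] = depletion_time
        notes["final_biomass"] = final_biomass
    return model, bounds, notes


def make_toy_community(seed: int, n_organisms: int = 2, n_metabolites: int = 2,
                       n_internal: int = 2, *, uptake: str = "linear",
                       identical: bool = False):
    """A list of toy organisms sharing one metabolite namespace.

    With ``identical=True`` every organism is a copy of the seed-0 draw
    (used for symmetry properties); otherwise each organism gets its own
    substream of the master seed.
    """
    seeds = [seed] * n_organisms if identical else [seed + 1000 * i for i in range(n_organisms)]
    models, bounds = [], []
    for i, s in enumerate(seeds):
        m, b, _ = make_toy_model(s, n_metabolites, n_internal, uptake=uptake)
        m.species_id = f"org{i}" if not identical else f"org{i}_twin"
        models.append(m)
        bounds.append(b)
    medium = {f"met{j}": 10.0 for j in range(n_metabolites)}
    return models, bounds, medium
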