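"""Reading and writing genome-scale models, media, kinetics and configs.

SBML Level-3 FBC and the JSON GEM dialect of the common model
repositories are read through cobrapy; the cobra model is then reduced
to the partitioned form this package simulates (external metabolites,
Gamma_star/Gamma_dagger blocks, uptake-positive exchange fluxes).
Source models that follow the usual secretion-positive exchange
convention are sign-flipped at load time and the flips recorded on the
model object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import BIG_BOUND, BoundSpec, MetabolicModel, ModelError, partition_stoichiometry

logger = logging.getLogger(__name__)

__all__ = ["load_gem", "write_gem", "load_medium", "write_medium",
           "load_kappa", "SimulationConfig"]


def _to_cobra(model: MetabolicModel, bounds: BoundSpec):
    """Build a cobra.Model from the partitioned representation (round-trip aid)."""
    import cobra

    cm = cobra.Model(model.species_id)
    ext = [cobra.Metabolite(mid, compartment="e") for mid in model.metabolite_ids]
    internal = [cobra.Metabolite(mid, compartment="c") for mid in model.internal_metabolite_ids]
    cm.add_metabolites(ext + internal)

    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound = float(bounds.internal_lower[j])
        r.upper_bound = float(bounds.internal_upper[j])
        rxns.append(r)
    ex_rxns = []
    for k, mid in enumerate(model.metabolite_ids):
        r = cobra.Reaction(model.exchange_map[k])
        # cobra exchange convention: negative flux = uptake
        r.lower_bound = -float(bounds.exchange_upper[k]) if not bounds.is_dynamic[k] else -BIG_BOUND
        r.upper_bound = -float(bounds.exchange_lower[k])
        ex_rxns.append(r)
    cm.add_reactions(rxns + ex_rxns)

    for j, r in enumerate(rxns):
        stoich = {}
        for i, met in enumerate(ext):
            coef = -model.Gamma_star[i, j]
            if coef != 0:
                stoich[met] = coef
        for i, met in enumerate(internal):
            coef = model.Gamma_dagger[i, j]
            if coef != 0:
                stoich[met] = coef
        r.add_metabolites(stoich)
        r.objective_coefficient = float(model.gamma[j])
    for k, r in enumerate(ex_rxns):
        r.add_metabolites({ext[k]: -1.0})
    return cm


def write_gem(model: MetabolicModel, bounds: BoundSpec, path):
    """Write the model as SBML (.xml/.sbml) or JSON (.json)."""
    import cobra.io

    path = Path(path)
    cm = _to_cobra(model, bounds)
    if path.suffix in (".xml", ".sbml"):
        cobra.io.write_sbml_model(cm, str(path))
    elif path.suffix == ".json":
        cobra.io.save_json_model(cm, str(path))
    else:
        raise ValueError(f"unsupported model format: {path.suffix}")


def load_gem(path, *, big: float = BIG_BOUND):
    """Load an SBML-FBC or JSON GEM and partition it.

    Returns ``(model, bounds)``.  Exchange fluxes are converted to the
    uptake-positive convention; infinite or over-large bounds are capped
    at ``big`` and the substitutions logged.  Raises ``ModelError`` for a
    model with no objective or no exchange reactions.
    """
    import cobra.io
    from cobra.util.array import create_stoichiometric_matrix

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".xml", ".sbml"):
        cm = cobra.io.read_sbml_model(str(path))
    elif path.suffix == ".json":
        cm = cobra.io.load_json_model(str(path))
    else:
        raise ValueError(f"unsupported model format: {path.suffix}")

    S = create_stoichiometric_matrix(cm)
    rxn_ids = [r.id for r in cm.reactions]
    met_ids = [m.id for m in cm.metabolites]
    exch = np.array([len(r.metabolites) == 1 for r in cm.reactions])
    if not exch.any():
        raise ModelError("model has no exchange reactions")

    obj = np.array([r.objective_coefficient for r in cm.reactions])
    if not np.any(obj[~exch]):
        raise ModelError("model has no objective on internal reactions")

    model = partition_stoichiometry(
        S, exch, species_id=cm.id or path.stem,
        reaction_ids=rxn_ids, metabolite_ids=met_ids,
        gamma=obj[~exch],
    )

    # bounds: map cobra exchange bounds (secretion positive) to psi (uptake
    # positive): psi in [-ub, -lb]
    int_idx = np.flatnonzero(~exch)
    rid_to_rxn = {r.id: r for r in cm.reactions}
    ex_lo = np.empty(model.m_ext)
    ex_up = np.empty(model.m_ext)
    for k in range(model.m_ext):
        r = rid_to_rxn[model.exchange_map[k]]
        ex_up[k] = -r.lower_bound
        ex_lo[k] = -r.upper_bound
    in_lo = np.array([cm.reactions[int(j)].lower_bound for j in int_idx])
    in_up = np.array([cm.reactions[int(j)].upper_bound for j in int_idx])
    for name, arr in (("exchange", ex_lo), ("exchange", ex_up),
                      ("internal", in_lo), ("internal", in_up)):
        over = np.abs(arr) > big
        if over.any():
            logger.info("capping %d %s bounds at %g for %s", over.sum(), name, big, cm.id)
            arr[over] = np.sign(arr[over]) * big
    bounds = BoundSpec(exchange_lower=ex_lo, exchange_upper=ex_up,
                       internal_lower=in_lo, internal_upper=in_up, big=big)
    if model.sign_flipped:
        logger.info("flipped %d exchange reactions to uptake-positive in %s",
                    len(model.sign_flipped), cm.id)
    return model, bounds


def load_medium(path) -> dict:
    """Medium CSV with header ``metabolite_id,concentration``."""
    df = pd.read_csv(path)
    expected = {"metabolite_id", "concentration"}
    if not expected.issubset(df.columns):
        raise ValueError(f"medium file must have columns {sorted(expected)}")
    if (df["concentration"] < 0).any():
        raise ValueError("medium concentrations must be nonnegative")
    return dict(zip(df["metabolite_id"], df["concentration"].astype(float)))


def write_medium(medium: dict, path):
    pd.DataFrame({"metabolite_id": list(medium), "concentration": list(medium.values())}
                 ).to_csv(path, index=False)


def load_kappa(path) -> pd.DataFrame:
    """Uptake-rate CSV: rows organisms, columns metabolites, first column ids."""
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("kappa entries must be nonnegative")
    return df


@dataclass
class SimulationConfig:
    """Bundle of everything a simulation run needs, file-loadable."""

    model_paths: list = field(default_factory=list)
    medium_path: Optional[str] = None
    x0: list = field(default_factory=list)
    T: float = 5.0
    dt: float = 0.05
    feas_tol: float = 1e-8
    degen_tol: float = 1e-9
    opt_tol: float = 1e-6
    kappa_path: Optional[str] = None
    kappa_seed: Optional[int] = None
    kappa_range: tuple = (0.0, 1.0)
    alpha: float = 0.0              # nutrient inflow rate (default: none)
    output_timecourse: Optional[str] = None
    output_events: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")
        if min(self.feas_tol, self.degen_tol, self.opt_tol) <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
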