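"""Shared fixtures and an independent LP oracle.

The oracle solves the same flux polytopes with scipy's HiGHS interior
implementation of linprog, built from the raw stoichiometry — a solve path
fully disjoint from the package's COBRApy/GLPK engine — so agreement is a
genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.optimize

from gutflux import synthetic_data
from gutflux.model_core import MetabolicModel


# ---------------------------------------------------------------------------
# oracle

def _matrices(model: MetabolicModel, overrides=None):
    overrides = overrides or {}
    rids = list(model.reactions)
    mids = list(model.metabolites)
    midx = {m: i for i, m in enumerate(mids)}
    S = np.zeros((len(mids), len(rids)))
    for j, rid in enumerate(rids):
        for mid, c in model.reactions[rid].stoichiometry.items():
            S[midx[mid], j] = c
    bounds = []
    for rid in rids:
        if rid in overrides:
            bounds.append(overrides[rid])
        else:
            r = model.reactions[rid]
            bounds.append((r.lower_bound, r.upper_bound))
    return rids, S, bounds


def oracle_fba(model: MetabolicModel, objective: str | None = None,
               sense: str = "max", overrides=None):
    """Brute LP optimum of one reaction's flux; returns (value, flux dict)."""
    if objective is None:
        objective, sense = model.objective
    rids, S, bounds = _matrices(model, overrides)
    c = np.zeros(len(rids))
    c[rids.index(objective)] = -1.0 if sense == "max" else 1.0
    res = scipy.optimize.linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                                 bounds=bounds, method="highs")
    if not res.success:
        return None, None
    val = res.x[rids.index(objective)]
    return val, dict(zip(rids, res.x))


def oracle_fva(model: MetabolicModel, reaction_ids, overrides=None):
    """Per-reaction (min, max) via two brute LPs each."""
    out = {}
    for rid in reaction_ids:
        lo, _ = oracle_fba(model, rid, "min", overrides)
        hi, _ = oracle_fba(model, rid, "max", overrides)
        out[rid] = (lo, hi)
    return out


def oracle_min_total_flux(model: MetabolicModel, objective_value: float,
                          overrides=None):
    """Minimum of sum |v| with the objective flux pinned (split variables)."""
    objective = model.objective[0]
    rids, S, bounds = _matrices(model, overrides)
    n = len(rids)
    j = rids.index(objective)
    bounds = list(bounds)
    bounds[j] = (objective_value, objective_value)
    # v = f - b with f, b >= 0; minimize sum(f + b)
    S2 = np.hstack([S, -S])
    split_bounds = []
    for lo, hi in bounds:
        split_bounds.append((max(lo, 0.0), max(hi, 0.0)))
    for lo, hi in bounds:
        split_bounds.append((max(-hi, 0.0), max(-lo, 0.0)))
    res = scipy.optimize.linprog(np.ones(2 * n), A_eq=S2,
                                 b_eq=np.zeros(S.shape[0]),
                                 bounds=split_bounds, method="highs")
    if not res.success:
        return None
    return res.fun


@pytest.fixture
def lp_oracle():
    return {"fba": oracle_fba, "fva": oracle_fva,
            "min_total_flux": oracle_min_total_flux}


# ---------------------------------------------------------------------------
# models

@pytest.fixture
def chain_model():
    return synthetic_data.make_toy_gem(
        synthetic_data.ToyNetworkSpec(template="chain", uptake=10.0))


@pytest.fixture
def diamond_model():
    return synthetic_data.make_toy_gem(
        synthetic_data.ToyNetworkSpec(template="diamond", uptake=10.0))


@pytest.fixture
def futile_cycle_model():
    return synthetic_data.make_toy_gem(
        synthetic_data.ToyNetworkSpec(template="futile_cycle", uptake=10.0))


@pytest.fixture
def epithelium_model():
    return synthetic_data.make_toy_gem(
        synthetic_data.ToyNetworkSpec(template="epithelium"))


@pytest.fixture
def crossfeed_pair():
    return synthetic_data.make_crossfeed_pair(seed=0)
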