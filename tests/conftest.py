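"""Shared fixtures: the toy dataset and derived pipeline stages.

Session-scoped where the object is read-only for the tests (analysis
entry points operate on copies or inside reverting contexts).
"""

from __future__ import annotations

import sys
from pathlib import Path

import cobra
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from ecgem.emoment import EnzymeConstraintSet, build_emoment
from ecgem.kcat_assignment import assign_kcats
from ecgem.model_core import apply_medium, split_reversible
from ecgem.synthetic_data import generate_toy_model


@pytest.fixture(scope="session")
def toy():
    return generate_toy_model()


@pytest.fixture(scope="session")
def toy_with_loop():
    return generate_toy_model(with_sbc_loop=True)


@pytest.fixture(scope="session")
def medium_model(toy):
    """Toy model with the default medium applied (glucose + palmitate + NH4)."""
    return apply_medium(toy.model, toy.default_medium)


@pytest.fixture(scope="session")
def split_setup(medium_model, toy):
    """Split-irreversible medium model plus its kcat assignment."""
    split = split_reversible(medium_model)
    assignment = assign_kcats(split.model, toy.kcat_table)
    return split, assignment


@pytest.fixture(scope="session")
def emoment_problem(split_setup, toy):
    """eMOMENT MILP at an enzyme-limited protein content (C = 0.03 g/gDW)."""
    split, assignment = split_setup
    enz = EnzymeConstraintSet(kcat=assignment.values, mw=toy.mw, C=0.03)
    return build_emoment(split.model, enz)


def chain_model(uptake: float = 10.0, substrate_per_biomass: float = 2.0) -> cobra.Model:
    """Minimal linear chain: uptake -> transport -> biomass.

    With ``uptake=10`` and two substrate units per biomass unit, the FBA
    optimum is 5 by hand.
    """
    model = cobra.Model("chain")
    s_e = cobra.Metabolite("s_e", compartment="e")
    s_c = cobra.Metabolite("s_c", compartment="c")
    model.add_metabolites([s_e, s_c])
    ex = cobra.Reaction("EX_s_e", lower_bound=-uptake, upper_bound=1000.0)
    t = cobra.Reaction("T_S", lower_bound=0.0, upper_bound=1000.0)
    bio = cobra.Reaction("BIO", lower_bound=0.0, upper_bound=1000.0)
    model.add_reactions([ex, t, bio])
    ex.add_metabolites({s_e: -1})
    t.add_metabolites({s_e: -1, s_c: 1})
    bio.add_metabolites({s_c: -substrate_per_biomass})
    for rxn in (ex, t, bio):
        rxn.subsystem = "Chain"
    model.objective = "BIO"
    return model
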