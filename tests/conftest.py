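"""Shared fixtures: the reduced central-carbon model in several states,
plus a cobra/GLPK conversion used as an independent LP oracle."""

from __future__ import annotations

import pytest

from glyc3hp import (
    Condition,
    add_3hp_pathway,
    build_core_model,
    set_condition,
)
from glyc3hp.core import Model, formula_to_string

# the reference microaerobic condition: GUR 15, OUR 10 mmol/(gDC*h)
GUR = 15.0
OUR = 10.0

# deletable genes of the fixture model's screening surface
FIXTURE_GENES = ("tpiA", "zwf", "pgi", "edd", "gldA", "fsaB", "yqhD", "mgsA")


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def producer_model(core_model):
    """Core model with the 3HP/1,3-PDO pathway grafted."""
    return add_3hp_pathway(core_model)


@pytest.fixture(scope="session")
def conditioned_model(producer_model):
    """Producer model under the microaerobic glycerol condition."""
    return set_condition(producer_model, Condition(GUR, OUR))


def to_cobra(model: Model):
    """Convert to a cobra model solved with GLPK — the independent oracle.

    cobra is never the implementation: it re-solves the same network
    through an entirely separate LP stack so objective values can be
    cross-checked.
    """
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(
            m.id,
            formula=formula_to_string(m.formula),
            charge=m.charge,
            compartment=m.compartment or "c",
        )
        for m in model.metabolites
    }
    reactions = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        reactions.append(cr)
    cm.add_reactions(reactions)
    for r in model.reactions:
        if r.gpr_string:
            cm.reactions.get_by_id(r.id).gene_reaction_rule = r.gpr_string
    cm.objective = model.biomass_reaction_id
    cm.solver = "glpk"
    return cm
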