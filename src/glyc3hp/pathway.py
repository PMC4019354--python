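"""Grafting the heterologous 3HP/1,3-PDO pathway and imposing the culture
condition.

E. coli has no native route from glycerol to 3-hydroxypropionic acid.
Expression of glycerol dehydratase (dhaB/gdrAB) and an aldehyde
dehydrogenase (aldH) adds one: glycerol is dehydrated to
3-hydroxypropionaldehyde (3HPA) and oxidised to 3HP.  The shared
intermediate 3HPA is also reduced to 1,3-propanediol by the host
NADPH-dependent oxidoreductase YqhD, which makes 1,3-PDO the canonical
byproduct.  Seven reactions — the two pathway steps, the competing
reduction, and transport/exchange for both products — are grafted onto
the host model; 3HP export is a proton symporter (by analogy with
D-lactate transport), 1,3-PDO export is passive diffusion.

The culture condition is microaerobic growth on glycerol as sole carbon
source: a glycerol uptake bound (GUR), an oxygen uptake bound (OUR), all
other carbon exchanges closed to uptake, and inorganic exchanges left
free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import FrozenSet, Optional, Set

from .core import Metabolite, Model, ModelValidationError, Reaction, parse_formula
from .gpr import parse_gpr

__all__ = [
    "Condition",
    "add_3hp_pathway",
    "set_condition",
    "PATHWAY_GENES",
    "HETEROLOGOUS_GENES",
]

# pseudo-genes carried by the grafted reactions; the oxidoreductase gene
# yqhD is a host gene and remains a legitimate knockout candidate
HETEROLOGOUS_GENES = frozenset({"dhaB", "gdrAB", "aldH"})
PATHWAY_GENES = HETEROLOGOUS_GENES | frozenset({"yqhD"})

GLYCEROL_EXCHANGE = "EX_glyc_e"
OXYGEN_EXCHANGE = "EX_o2_e"

# exchanges left open in both directions regardless of carbon content;
# CO2 (and bicarbonate, its hydrated form) transport freely across the
# membrane, as do water, protons and the inorganic nutrient ions
DEFAULT_FREE_EXCHANGES = frozenset(
    {
        "EX_co2_e",
        "EX_hco3_e",
        "EX_h2o_e",
        "EX_h_e",
        "EX_nh4_e",
        "EX_pi_e",
        "EX_so4_e",
        "EX_k_e",
        "EX_na1_e",
        "EX_cl_e",
        "EX_mg2_e",
        "EX_ca2_e",
        "EX_fe2_e",
        "EX_fe3_e",
    }
)


def _pathway_spec() -> dict:
    data = resources.files("glyc3hp.data").joinpath("pathway_3hp.json")
    return json.loads(data.read_text())


@dataclass(frozen=True)
class Condition:
    """Uptake condition: GUR and OUR in mmol/(gDC*h).

    OUR/GUR sets the aerobiosis regime; the reference microaerobic
    condition is GUR 15, OUR 10 (OUR/GUR = 0.67).
    """

    glycerol_uptake_rate: float = 15.0
    oxygen_uptake_rate: float = 10.0
    free_exchanges: FrozenSet[str] = DEFAULT_FREE_EXCHANGES

    def __post_init__(self):
        if self.glycerol_uptake_rate <= 0:
            raise ValueError(
                f"glycerol uptake rate must be positive, got {self.glycerol_uptake_rate}"
            )
        if self.oxygen_uptake_rate < 0:
            raise ValueError(
                f"oxygen uptake rate must be non-negative, got {self.oxygen_uptake_rate}"
            )


def add_3hp_pathway(model: Model, pathway_spec: Optional[dict] = None) -> Model:
    """Return a copy of ``model`` extended with the 3HP/1,3-PDO pathway.

    Exactly seven reactions and five metabolites are added, all
    irreversible in the written direction except the 1,3-PDO diffusion
    transporter.  The operation is deliberately not idempotent: grafting
    onto a model that already carries any of the reaction ids raises.
    """
    spec = pathway_spec if pathway_spec is not None else _pathway_spec()
    for met_id in ("glyc_c", "nad_c", "nadh_c", "nadp_c", "nadph_c", "h_c", "h2o_c"):
        if not model.has_metabolite(met_id):
            raise ModelValidationError(
                f"host model lacks required metabolite {met_id!r}"
            )
    out = model.copy()
    out.id = f"{model.id}-3HP"
    for m in spec["metabolites"]:
        if out.has_metabolite(m["id"]):
            continue  # re-grafting different pathway variants may share species
        out.add_metabolite(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=parse_formula(m.get("formula", "")),
                charge=int(m.get("charge", 0)),
                compartment=m.get("compartment", ""),
            )
        )
    for r in spec["reactions"]:
        if out.has_reaction(r["id"]):
            raise ModelValidationError(
                f"pathway reaction {r['id']!r} already present in {model.id}; "
                "the pathway has already been grafted"
            )
        out.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""),
            )
        )
    out.validate()
    return out


def set_condition(model: Model, condition: Condition) -> Model:
    """Return a copy of ``model`` constrained to the culture condition.

    Glycerol uptake is a bound, not an equality: -GUR <= v_EX_glyc <= ub.
    The LP saturates it when beneficial, and yields are computed on the
    actual consumed flux, so the distinction does not affect C-mol%.
    Every other carbon-containing exchange is closed to uptake (lower
    bound raised to 0) unless listed in ``condition.free_exchanges``;
    secretion arms are left as the model defines them.  Inorganic
    exchanges keep the model's default bounds.
    """
    for rxn_id in (GLYCEROL_EXCHANGE, OXYGEN_EXCHANGE):
        if not model.has_reaction(rxn_id):
            raise ModelValidationError(
                f"model {model.id} lacks exchange reaction {rxn_id!r}"
            )
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id == GLYCEROL_EXCHANGE:
            rxn.lower_bound = -condition.glycerol_uptake_rate
            continue
        if rxn.id == OXYGEN_EXCHANGE:
            rxn.lower_bound = -condition.oxygen_uptake_rate
            continue
        if rxn.id in condition.free_exchanges:
            continue
        met = out.metabolite(next(iter(rxn.stoichiometry)))
        if met.carbons > 0 and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    return out
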