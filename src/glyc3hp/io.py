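"""Readers and writers for metabolic models.

Three dialects are supported:

* ``bigg-json`` — the JSON schema used by the BiGG database (iAF1260 and
  friends circulate in this form);
* ``sbml-fbc`` — SBML Level 3 with the FBC v2 package, formulas taken
  from ``fbc:chemicalFormula`` first and legacy ``FORMULA:`` notes lines
  second;
* ``native-json`` — this package's own dump, a loss-less round-trip of
  the in-memory model.

The biomass/objective reaction is taken from the file's declared
objective; if none is declared the loader refuses to guess and raises an
error listing candidate reactions (anything with "biomass" in its id or
name).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Optional

from .core import (
    Metabolite,
    Model,
    ModelValidationError,
    Reaction,
    MassBalanceResult,
    parse_formula,
    formula_to_string,
)
from .gpr import parse_gpr

__all__ = ["load_model", "save_model", "write_mass_balance_report"]

DIALECTS = ("bigg-json", "sbml-fbc", "native-json")


class ModelReadError(ValueError):
    """Raised when a model file cannot be parsed into a valid Model."""


def _biomass_candidates(reactions: List[Reaction]) -> List[str]:
    return [
        r.id
        for r in reactions
        if "biomass" in r.id.lower() or "biomass" in r.name.lower()
    ]


def _require_biomass(biomass_id: Optional[str], reactions: List[Reaction]) -> str:
    if biomass_id is not None:
        return biomass_id
    candidates = _biomass_candidates(reactions)
    raise ModelReadError(
        "no objective/biomass reaction declared in model file; "
        f"candidate objective reactions: {candidates or 'none found'}"
    )


# ---------------------------------------------------------------------------
# BiGG JSON
# ---------------------------------------------------------------------------

def _load_bigg_json(path: Path) -> Model:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelReadError(f"cannot parse {path} as JSON: {exc}") from exc
    metabolites = []
    for m in doc.get("metabolites", []):
        formula = m.get("formula") or ""
        met_id = m["id"]
        compartment = m.get("compartment") or (
            met_id.rsplit("_", 1)[1] if "_" in met_id else ""
        )
        metabolites.append(
            Metabolite(
                id=met_id,
                name=m.get("name", ""),
                formula=parse_formula(formula) if isinstance(formula, str) else {},
                charge=int(m.get("charge") or 0),
                compartment=compartment,
            )
        )
    reactions = []
    biomass_id = None
    for r in doc.get("reactions", []):
        rxn = Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=parse_gpr(r.get("gene_reaction_rule", "")),
            subsystem=r.get("subsystem", "") or "",
        )
        reactions.append(rxn)
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            biomass_id = r["id"]
    model = Model(
        id=doc.get("id", path.stem),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=_require_biomass(biomass_id, reactions),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

_NOTES_FORMULA = re.compile(r"FORMULA:\s*([A-Za-z0-9]*)")
_NOTES_CHARGE = re.compile(r"CHARGE:\s*(-?\d+)")


def _load_sbml_fbc(path: Path) -> Model:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelReadError(f"SBML parse error in {path}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelReadError(f"{path} contains no SBML model")
    fbc = sbml_model.getPlugin("fbc")

    def strip(sid: str) -> str:
        # SBML ids are prefixed (M_, R_, G_) relative to BiGG ids
        return re.sub(r"^[MRG]_", "", sid)

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        formula_str = ""
        charge = 0
        sp_fbc = sp.getPlugin("fbc")
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula_str = sp_fbc.getChemicalFormula() or ""
        if sp_fbc is not None and sp_fbc.isSetCharge():
            charge = sp_fbc.getCharge()
        if not formula_str and sp.isSetNotes():
            notes = sp.getNotesString()
            m = _NOTES_FORMULA.search(notes)
            if m:
                formula_str = m.group(1)
            mc = _NOTES_CHARGE.search(notes)
            if mc and charge == 0:
                charge = int(mc.group(1))
        metabolites.append(
            Metabolite(
                id=strip(sp.getId()),
                name=sp.getName() or "",
                formula=parse_formula(formula_str),
                charge=charge,
                compartment=sp.getCompartment() or "",
            )
        )

    # map fbc gene product ids to labels so GPRs use gene names
    gene_labels: Dict[str, str] = {}
    if fbc is not None:
        for gp in fbc.getListOfGeneProducts():
            gene_labels[gp.getId()] = strip(gp.getLabel() or gp.getId())

    def association_to_string(assoc) -> str:
        import libsbml as _ls

        if assoc is None:
            return ""
        if isinstance(assoc, _ls.GeneProductRef):
            return gene_labels.get(assoc.getGeneProduct(), assoc.getGeneProduct())
        if isinstance(assoc, _ls.FbcAnd):
            parts = [
                association_to_string(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())
            ]
            return "(" + " and ".join(parts) + ")"
        if isinstance(assoc, _ls.FbcOr):
            parts = [
                association_to_string(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())
            ]
            return "(" + " or ".join(parts) + ")"
        return ""

    def parameter_value(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    reactions = []
    for rx in sbml_model.getListOfReactions():
        stoich: Dict[str, float] = {}
        for i in range(rx.getNumReactants()):
            sr = rx.getReactant(i)
            sid = strip(sr.getSpecies())
            stoich[sid] = stoich.get(sid, 0.0) - sr.getStoichiometry()
        for i in range(rx.getNumProducts()):
            sr = rx.getProduct(i)
            sid = strip(sr.getSpecies())
            stoich[sid] = stoich.get(sid, 0.0) + sr.getStoichiometry()
        rx_fbc = rx.getPlugin("fbc")
        if rx_fbc is not None and rx_fbc.isSetLowerFluxBound():
            lb = parameter_value(rx_fbc.getLowerFluxBound(), -1000.0)
            ub = parameter_value(rx_fbc.getUpperFluxBound(), 1000.0)
        else:
            lb = -1000.0 if rx.getReversible() else 0.0
            ub = 1000.0
        gpr_str = ""
        if rx_fbc is not None and rx_fbc.isSetGeneProductAssociation():
            gpr_str = association_to_string(
                rx_fbc.getGeneProductAssociation().getAssociation()
            )
        reactions.append(
            Reaction(
                id=strip(rx.getId()),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(gpr_str),
            )
        )

    biomass_id = None
    if fbc is not None:
        obj = fbc.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass_id = strip(obj.getFluxObjective(0).getReaction())
    model = Model(
        id=sbml_model.getId() or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=_require_biomass(biomass_id, reactions),
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Native JSON
# ---------------------------------------------------------------------------

def _load_native_json(path: Path) -> Model:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelReadError(f"cannot parse {path} as JSON: {exc}") from exc
    metabolites = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            formula=parse_formula(m.get("formula", "")),
            charge=int(m.get("charge", 0)),
            compartment=m.get("compartment", ""),
        )
        for m in doc["metabolites"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            gpr=parse_gpr(r.get("gpr", "")),
            subsystem=r.get("subsystem", ""),
        )
        for r in doc["reactions"]
    ]
    model = Model(
        id=doc.get("id", path.stem),
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=_require_biomass(doc.get("biomass_reaction_id"), reactions),
    )
    model.validate()
    return model


def model_to_dict(model: Model) -> dict:
    """Native JSON-serialisable representation (deterministic key order)."""
    return {
        "id": model.id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": formula_to_string(m.formula),
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in r.stoichiometry},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr_string,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def save_model(model: Model, path) -> None:
    """Write the native JSON dump (byte-identical for identical models)."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def load_model(path, dialect: str = "native-json") -> Model:
    """Load a metabolic model from ``path`` in the given dialect.

    Raises :class:`ModelReadError` on malformed input — never a partially
    populated model — and ``ValueError`` for an unknown dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    if dialect == "bigg-json":
        return _load_bigg_json(path)
    if dialect == "sbml-fbc":
        return _load_sbml_fbc(path)
    if dialect == "native-json":
        return _load_native_json(path)
    raise ValueError(f"unknown model dialect {dialect!r}; expected one of {DIALECTS}")


def write_mass_balance_report(result: MassBalanceResult, path) -> None:
    """TSV report: one row per elemental imbalance, then skipped/missing."""
    lines = ["reaction_id\telement\timbalance\tstatus"]
    for rxn_id, element, imbalance in result.imbalances:
        lines.append(f"{rxn_id}\t{element}\t{imbalance:.6g}\timbalanced")
    for rxn_id in result.skipped:
        lines.append(f"{rxn_id}\t\t\tskipped_exempt")
    for rxn_id, met_id in result.missing:
        lines.append(f"{rxn_id}\t{met_id}\t\tmissing_formula")
    Path(path).write_text("\n".join(lines) + "\n")
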