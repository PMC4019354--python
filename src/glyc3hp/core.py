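"""Core data model for constraint-based metabolic networks.

Metabolites carry chemical formulas so that elemental bookkeeping — mass
balance of reactions and carbon-molar yield accounting — falls out of the
model itself rather than from hard-coded carbon numbers.  A :class:`Model`
compiles to a sparse stoichiometric matrix S (rows = metabolites, columns =
reactions) in deterministic input order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse

from .gpr import GPR, gpr_to_string, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "Model",
    "StoichiometricMatrix",
    "FormulaError",
    "ModelValidationError",
    "parse_formula",
    "formula_to_string",
    "build_stoichiometric_matrix",
    "check_mass_balance",
    "MassBalanceResult",
    "net_biomass_carbon",
]

# An element symbol is one uppercase letter optionally followed by one
# lowercase letter, then an optional integer count ("C3H8O3", "Fe2").
_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed chemical formula strings."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-style chemical formula into an element->count map.

    Empty strings parse to an empty map (metabolite of unknown
    composition).  Malformed input — a lowercase-first symbol, a stray
    digit, any unrecognised character — raises :class:`FormulaError`
    naming the offset of the offending token.
    """
    counts: Dict[str, int] = {}
    pos = 0
    formula = formula or ""
    while pos < len(formula):
        m = _ELEMENT.match(formula, pos)
        if m is None or m.start() != pos:
            raise FormulaError(
                f"malformed formula {formula!r}: unexpected character "
                f"{formula[pos]!r} at offset {pos}"
            )
        element, digits = m.groups()
        count = int(digits) if digits else 1
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return counts


def formula_to_string(counts: Dict[str, int]) -> str:
    """Serialise an element map back to Hill-ish order (C, H, then alphabetic)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    parts = []
    for element in order:
        n = counts[element]
        if n == 0:
            continue
        parts.append(element + (str(n) if n != 1 else ""))
    return "".join(parts)


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``id`` is compartment-suffixed in the BiGG style ("glyc_c", "3hp_e").
    ``formula`` maps element symbol to count; the carbon number used in
    C-mol yield accounting is ``formula.get("C", 0)``.
    """

    id: str
    name: str = ""
    formula: Dict[str, int] = field(default_factory=dict)
    charge: int = 0
    compartment: str = ""

    @property
    def carbons(self) -> int:
        return self.formula.get("C", 0)

    def copy(self) -> "Metabolite":
        return replace(self, formula=dict(self.formula))


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed).  Bounds are in mmol/(gDC*h); the biomass
    reaction's flux is the specific growth rate in 1/h.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GPR] = None
    subsystem: str = ""

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        self.stoichiometry = {k: float(v) for k, v in self.stoichiometry.items()}
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def gpr_string(self) -> str:
        return gpr_to_string(self.gpr)

    @property
    def genes(self) -> Set[str]:
        return set() if self.gpr is None else set(self.gpr.genes())

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction: one metabolite, extracellular."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


class Model:
    """Metabolites + reactions + genes + a designated biomass reaction."""

    def __init__(
        self,
        id: str = "model",
        metabolites: Sequence[Metabolite] = (),
        reactions: Sequence[Reaction] = (),
        biomass_reaction_id: Optional[str] = None,
    ):
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.biomass_reaction_id = biomass_reaction_id
        self._reindex()

    # -- bookkeeping ---------------------------------------------------
    def _reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")

    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return out

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def biomass_reaction(self) -> Reaction:
        if self.biomass_reaction_id is None:
            raise ModelValidationError(f"model {self.id} has no biomass reaction")
        return self.reaction(self.biomass_reaction_id)

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = len(self.metabolites) - 1

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelValidationError(
                    f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                )
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = len(self.reactions) - 1

    def copy(self) -> "Model":
        return Model(
            id=self.id,
            metabolites=[m.copy() for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def validate(self) -> None:
        """Check structural invariants, raising on the first violation."""
        for r in self.reactions:
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id} has empty stoichiometry")
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id} references unknown metabolite {met_id!r}"
                    )
            if r.is_exchange:
                met = self.metabolite(next(iter(r.stoichiometry)))
                if met.compartment not in ("e", ""):
                    raise ModelValidationError(
                        f"exchange reaction {r.id} acts on non-extracellular "
                        f"metabolite {met.id!r}"
                    )
        if self.biomass_reaction_id is not None and not self.has_reaction(
            self.biomass_reaction_id
        ):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    def __repr__(self) -> str:
        return (
            f"<Model {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


@dataclass
class StoichiometricMatrix:
    """Sparse S with id->position maps, in deterministic input order."""

    S: sparse.csc_matrix
    row_index: Dict[str, int]
    col_index: Dict[str, int]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.S.shape


def build_stoichiometric_matrix(model: Model) -> StoichiometricMatrix:
    """Compile a model to its stoichiometric matrix.

    Rows follow metabolite input order, columns reaction input order, so
    repeated builds of the same model are identical — which keeps solver
    behaviour reproducible across runs.
    """
    row_index = {m.id: i for i, m in enumerate(model.metabolites)}
    col_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(row_index[met_id])
            cols.append(j)
            vals.append(float(coef))
    S = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return StoichiometricMatrix(S=S, row_index=row_index, col_index=col_index)


DEFAULT_BALANCE_ELEMENTS = ("C", "H", "O", "N", "P", "S")


@dataclass
class MassBalanceResult:
    """Outcome of an elemental mass-balance check.

    ``imbalances`` lists (reaction_id, element, imbalance) for every
    non-exempt reaction that fails to conserve an element; ``skipped``
    names the exempt reactions (exchanges, demands, biomass); ``missing``
    lists (reaction_id, metabolite_id) where a formula was absent so the
    reaction could not be checked.
    """

    imbalances: List[Tuple[str, str, float]]
    skipped: List[str]
    missing: List[Tuple[str, str]]

    def __iter__(self):
        return iter(self.imbalances)

    def __len__(self):
        return len(self.imbalances)

    @property
    def balanced(self) -> bool:
        return not self.imbalances


def check_mass_balance(
    model: Model,
    elements: Iterable[str] = DEFAULT_BALANCE_ELEMENTS,
    tol: float = 1e-6,
) -> MassBalanceResult:
    """Verify element conservation for every non-exempt reaction.

    Exchange/demand reactions (single metabolite) and the biomass
    reaction are exempt by construction — they are deliberately
    unbalanced drains — and are reported in ``skipped``.  A metabolite
    lacking a formula in a checked reaction is reported in ``missing``
    rather than raising.
    """
    elements = list(elements)
    imbalances: List[Tuple[str, str, float]] = []
    skipped: List[str] = []
    missing: List[Tuple[str, str]] = []
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id == model.biomass_reaction_id:
            skipped.append(rxn.id)
            continue
        formulas = {}
        ok = True
        for met_id in rxn.stoichiometry:
            met = model.metabolite(met_id)
            if not met.formula:
                missing.append((rxn.id, met_id))
                ok = False
            formulas[met_id] = met.formula
        if not ok:
            continue
        for element in elements:
            total = sum(
                coef * formulas[met_id].get(element, 0)
                for met_id, coef in rxn.stoichiometry.items()
            )
            if abs(total) > tol:
                imbalances.append((rxn.id, element, total))
    return MassBalanceResult(imbalances=imbalances, skipped=skipped, missing=missing)


def net_biomass_carbon(model: Model) -> float:
    """Net carbon drained by one unit of biomass flux, in mmol C per gDC.

    Computed as carbon consumed minus carbon produced by the biomass
    reaction; cofactor pairs that appear on both sides (ATP/ADP) cancel.
    The result converts a growth rate mu (1/h) into a biomass carbon flux
    mu * net_biomass_carbon, the numerator of the biomass C-mol yield.
    """
    rxn = model.biomass_reaction
    net = 0.0
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolite(met_id)
        if not met.formula:
            raise ModelValidationError(
                f"biomass participant {met_id!r} has no chemical formula"
            )
        net += -coef * met.carbons
    if net <= 0:
        raise ModelValidationError(
            f"biomass reaction {rxn.id} has non-positive net carbon ({net:.4g})"
        )
    return net
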