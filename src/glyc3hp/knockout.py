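"""GPR-mediated gene deletion and exhaustive single/double knockout screens.

Deleting a gene set disables every reaction whose GPR evaluates False
under the deletion; disabled reactions have both flux bounds set to
zero.  Screens run one lexicographic FBA (growth first, 3HP production
second) per deletion and rank records by 3HP yield, then relative
growth, then gene ids, which makes the ranking deterministic.

Distinct gene pairs often disable identical reaction sets; such
deletions are provably equivalent LPs, so the screen solves each
equivalence class once and shares the result — this cuts genome-scale
pair screens by an order of magnitude with identical output.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .core import Model
from .fba import FluxSolution, ZERO_FLUX_TOL, solve_lexicographic
from .gpr import evaluate_gpr

__all__ = [
    "ScreenRecord",
    "disabled_reactions",
    "apply_knockout",
    "single_knockout_screen",
    "double_knockout_screen",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreenRecord:
    """Outcome of one knockout evaluated under lexicographic FBA."""

    genes: FrozenSet[str]
    growth_rate: float  # 1/h
    threehp_flux: float  # mmol/(gDC*h)
    threehp_yield: float  # C-mol% on consumed substrate
    relative_growth: float  # percent of wild-type growth
    disabled_reactions: FrozenSet[str]

    @property
    def lethal(self) -> bool:
        return self.growth_rate <= ZERO_FLUX_TOL

    def sort_key(self):
        return (-self.threehp_yield, -self.relative_growth, tuple(sorted(self.genes)))


def _check_genes(model: Model, genes: Iterable[str]) -> None:
    known = model.genes
    for g in genes:
        if g not in known:
            near = difflib.get_close_matches(g, sorted(known), n=3)
            raise KeyError(
                f"unknown gene {g!r}; close matches: {near or 'none'}"
            )


def disabled_reactions(model: Model, genes: Iterable[str]) -> FrozenSet[str]:
    """Reaction ids disabled by deleting ``genes`` (GPR evaluates False)."""
    deleted = set(genes)
    _check_genes(model, deleted)
    return frozenset(
        r.id for r in model.reactions if not evaluate_gpr(r.gpr, deleted)
    )


def apply_knockout(model: Model, genes: Iterable[str]) -> Model:
    """Return a copy of ``model`` with the gene set deleted.

    Both bounds of every reaction whose GPR fails under the deletion are
    set to zero; the input model is untouched.
    """
    dead = disabled_reactions(model, genes)
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id in dead:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def _evaluate_deletion(
    model: Model,
    dead: FrozenSet[str],
    primary: str,
    secondary: str,
    mu_wt: float,
    substrate_exchange: str,
    substrate_carbons: int,
    product_carbons: int,
) -> Tuple[float, float, float, float]:
    """Solve one deletion; lethal/infeasible deletions report zeros."""
    ko = model.copy()
    for rxn in ko.reactions:
        if rxn.id in dead:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    sol = solve_lexicographic(ko, primary=primary, secondary=secondary)
    if not sol.optimal:
        return 0.0, 0.0, 0.0, 0.0
    mu = max(sol.primary_value, 0.0) + 0.0
    if mu <= ZERO_FLUX_TOL:
        # lethal: a strain that cannot grow produces nothing, whatever
        # the degenerate zero-growth LP would allow
        return 0.0, 0.0, 0.0, 0.0
    flux = max(sol.objective_value, 0.0)
    if flux < ZERO_FLUX_TOL:
        flux = 0.0
    uptake = -sol.fluxes.get(substrate_exchange, 0.0)
    if uptake > ZERO_FLUX_TOL and flux > 0.0:
        yld = 100.0 * flux * product_carbons / (uptake * substrate_carbons)
    else:
        yld = 0.0
    rel = 100.0 * mu / mu_wt if mu_wt > 0 else 0.0
    # knockouts cannot out-grow the wild type under identical constraints;
    # clip the solver's rounding noise
    rel = min(max(rel, 0.0), 100.0)
    return mu, flux, yld, rel


def _screen(
    model: Model,
    deletions: Sequence[FrozenSet[str]],
    primary: str,
    secondary: str,
    substrate_exchange: str,
    progress_every: int = 0,
) -> List[ScreenRecord]:
    wt = solve_lexicographic(model, primary=primary, secondary=secondary)
    if not wt.optimal:
        raise RuntimeError(
            f"wild-type model {model.id} does not solve to optimality ({wt.status})"
        )
    mu_wt = wt.primary_value
    sub_met = next(iter(model.reaction(substrate_exchange).stoichiometry))
    substrate_carbons = model.metabolite(sub_met).carbons
    prod_met = next(iter(model.reaction(secondary).stoichiometry))
    product_carbons = model.metabolite(prod_met).carbons

    # equivalence classes: deletions sharing a disabled-reaction set share one LP
    classes: Dict[FrozenSet[str], List[FrozenSet[str]]] = {}
    for genes in deletions:
        dead = disabled_reactions(model, genes)
        classes.setdefault(dead, []).append(genes)

    records: List[ScreenRecord] = []
    for i, (dead, members) in enumerate(classes.items()):
        mu, flux, yld, rel = _evaluate_deletion(
            model, dead, primary, secondary, mu_wt,
            substrate_exchange, substrate_carbons, product_carbons,
        )
        for genes in members:
            records.append(
                ScreenRecord(
                    genes=genes,
                    growth_rate=mu,
                    threehp_flux=flux,
                    threehp_yield=yld,
                    relative_growth=rel,
                    disabled_reactions=dead,
                )
            )
        if progress_every and (i + 1) % progress_every == 0:
            logger.info(
                "screen: %d/%d equivalence classes solved", i + 1, len(classes)
            )
    return records


def single_knockout_screen(
    model: Model,
    genes: Sequence[str],
    primary: Optional[str] = None,
    secondary: str = "EX_3hp_e",
    substrate_exchange: str = "EX_glyc_e",
    progress_every: int = 0,
) -> List[ScreenRecord]:
    """Evaluate every single-gene deletion; one record per gene, input order.

    Lethal deletions are recorded with growth 0 and yield 0, never raised.
    """
    if primary is None:
        primary = model.biomass_reaction.id
    _check_genes(model, genes)
    deletions = [frozenset((g,)) for g in genes]
    return _screen(model, deletions, primary, secondary, substrate_exchange,
                   progress_every)


def double_knockout_screen(
    model: Model,
    genes: Sequence[str],
    primary: Optional[str] = None,
    secondary: str = "EX_3hp_e",
    substrate_exchange: str = "EX_glyc_e",
    top_k: Optional[int] = None,
    progress_every: int = 0,
) -> List[ScreenRecord]:
    """Evaluate all unordered gene pairs, ranked by 3HP yield.

    Records are sorted by yield descending, then relative growth
    descending, then gene ids; ``top_k`` truncates the ranked table.
    """
    if primary is None:
        primary = model.biomass_reaction.id
    _check_genes(model, genes)
    unique = sorted(set(genes))
    deletions = [
        frozenset((a, b))
        for i, a in enumerate(unique)
        for b in unique[i + 1:]
    ]
    records = _screen(model, deletions, primary, secondary, substrate_exchange,
                      progress_every)
    records.sort(key=ScreenRecord.sort_key)
    return records[:top_k] if top_k is not None else records
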