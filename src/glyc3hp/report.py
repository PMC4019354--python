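"""Carbon-molar yield accounting, summary tables, normalized flux maps and
the oxygen-uptake sweep.

The carbon-molar yield of a product on consumed glycerol is

    C-mol% = 100 * (v_product * n_C,product) / (v_glycerol * n_C,glycerol)

with carbon numbers taken from metabolite formulas, never hard-coded.
The biomass yield uses the net carbon drained by one unit of biomass
flux, so for an optimal solution all product yields, the CO2 yield and
the biomass yield close the carbon balance at 100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import Model, net_biomass_carbon
from .fba import FluxSolution, ZERO_FLUX_TOL, solve_lexicographic

__all__ = [
    "YieldReport",
    "cmol_yield",
    "yield_table",
    "relative_growth",
    "normalize_flux_map",
    "our_sweep",
    "write_yield_json",
    "write_flux_tsv",
]

GLYCEROL_EXCHANGE = "EX_glyc_e"

# products reported in the human-readable summary, in table order;
# CO2 is kept in the machine-readable report but omitted from the
# printed summary (it is the balance closer, not a product of interest)
DEFAULT_PRODUCTS = {
    "3hp": "EX_3hp_e",
    "13pdo": "EX_13pdo_e",
    "acetate": "EX_ac_e",
    "succinate": "EX_succ_e",
    "lactate": "EX_lac__D_e",
    "ethanol": "EX_etoh_e",
    "formate": "EX_for_e",
    "co2": "EX_co2_e",
}


@dataclass
class YieldReport:
    """C-mol% yields of one optimal solution, on consumed glycerol."""

    consumed_glycerol_flux: float  # mmol/(gDC*h)
    growth_rate: float  # 1/h
    product_yields: Dict[str, float]  # product key -> C-mol%
    biomass_yield: float  # C-mol%

    @property
    def total_carbon_recovery(self) -> float:
        """Sum of all product yields plus biomass yield (C-mol%)."""
        return sum(self.product_yields.values()) + self.biomass_yield

    def summary(self) -> str:
        lines = [
            f"consumed glycerol     {self.consumed_glycerol_flux:8.3f} mmol/(gDC*h)",
            f"growth rate           {self.growth_rate:8.4f} 1/h",
            f"biomass               {self.biomass_yield:8.1f} C-mol%",
        ]
        for key, value in self.product_yields.items():
            if key == "co2":
                continue
            lines.append(f"{key:<22}{value:8.1f} C-mol%")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "consumed_glycerol_flux": self.consumed_glycerol_flux,
            "growth_rate": self.growth_rate,
            "biomass_yield_cmol_pct": self.biomass_yield,
            "product_yields_cmol_pct": dict(self.product_yields),
            "total_carbon_recovery_cmol_pct": self.total_carbon_recovery,
        }


def cmol_yield(
    product_flux: float,
    product_carbons: int,
    substrate_flux: float,
    substrate_carbons: int,
) -> float:
    """Carbon-molar yield in percent of consumed substrate carbon."""
    if substrate_flux <= 0:
        raise ValueError(
            f"substrate flux must be positive, got {substrate_flux}"
        )
    if product_flux < 0:
        raise ValueError(f"product flux must be non-negative, got {product_flux}")
    return 100.0 * product_flux * product_carbons / (substrate_flux * substrate_carbons)


def relative_growth(mu_ko: float, mu_wt: float) -> float:
    """Knockout growth rate as a percentage of the wild-type rate."""
    if mu_wt <= 0:
        raise ValueError(f"wild-type growth rate must be positive, got {mu_wt}")
    return 100.0 * mu_ko / mu_wt


def yield_table(
    solution: FluxSolution,
    model: Model,
    products: Optional[Dict[str, str]] = None,
    substrate_exchange: str = GLYCEROL_EXCHANGE,
) -> YieldReport:
    """Build a yield report from an optimal solution.

    Substrate consumption is the actual (negative) exchange flux of the
    solution, not the bound.  Product secretion below the zero-flux
    reporting threshold is reported as exactly 0.
    """
    if not solution.optimal:
        raise ValueError(f"cannot report yields of a {solution.status} solution")
    products = products if products is not None else DEFAULT_PRODUCTS
    uptake = -solution.fluxes.get(substrate_exchange, 0.0)
    if uptake <= ZERO_FLUX_TOL:
        raise ValueError(
            f"no substrate consumed through {substrate_exchange}; no yield basis"
        )
    sub_met = next(iter(model.reaction(substrate_exchange).stoichiometry))
    sub_carbons = model.metabolite(sub_met).carbons

    yields: Dict[str, float] = {}
    for key, ex_id in products.items():
        if not model.has_reaction(ex_id):
            yields[key] = 0.0
            continue
        flux = solution.fluxes.get(ex_id, 0.0)
        if flux <= ZERO_FLUX_TOL:  # uptake or noise: not a product
            yields[key] = 0.0
            continue
        met = model.metabolite(next(iter(model.reaction(ex_id).stoichiometry)))
        yields[key] = cmol_yield(flux, met.carbons, uptake, sub_carbons)

    mu = solution.fluxes.get(model.biomass_reaction.id, 0.0)
    biomass_yield = 100.0 * mu * net_biomass_carbon(model) / (uptake * sub_carbons)
    return YieldReport(
        consumed_glycerol_flux=uptake,
        growth_rate=mu,
        product_yields=yields,
        biomass_yield=max(biomass_yield, 0.0),
    )


def normalize_flux_map(
    solution: FluxSolution,
    reaction_subset: Sequence[str],
    substrate_exchange: str = GLYCEROL_EXCHANGE,
) -> Dict[str, float]:
    """Fluxes of ``reaction_subset`` as signed percentages of glycerol uptake."""
    uptake = -solution.fluxes.get(substrate_exchange, 0.0)
    if uptake <= 0:
        raise ValueError("glycerol uptake is zero; cannot normalize flux map")
    out = {}
    for rxn_id in reaction_subset:
        if rxn_id not in solution.fluxes:
            raise KeyError(f"reaction {rxn_id!r} not in solution")
        out[rxn_id] = 100.0 * solution.fluxes[rxn_id] / uptake
    return out


def our_sweep(
    model: Model,
    gur: float,
    our_values: Iterable[float],
    primary: Optional[str] = None,
    secondary: str = "EX_3hp_e",
) -> List[Tuple[float, float, float]]:
    """Lexicographic solve across oxygen uptake rates.

    Returns (OUR, growth rate, 3HP C-mol yield) rows in input order.
    The model passed in should already carry the pathway; the condition
    is re-imposed per OUR value.
    """
    from .pathway import Condition, set_condition

    if primary is None:
        primary = model.biomass_reaction.id
    rows: List[Tuple[float, float, float]] = []
    for our in our_values:
        conditioned = set_condition(model, Condition(gur, our))
        sol = solve_lexicographic(conditioned, primary=primary, secondary=secondary)
        if not sol.optimal:
            raise RuntimeError(f"solve at OUR={our} reported {sol.status}")
        report = yield_table(sol, conditioned)
        rows.append((our, sol.primary_value, report.product_yields.get("3hp", 0.0)))
    return rows


def write_yield_json(report: YieldReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1) + "\n")


def write_flux_tsv(solution: FluxSolution, model: Model, path) -> None:
    """Flux table: reaction_id, flux, subsystem; tiny fluxes written as 0."""
    lines = ["reaction_id\tflux\tsubsystem"]
    for rxn in model.reactions:
        flux = solution.fluxes.get(rxn.id, 0.0)
        if abs(flux) < ZERO_FLUX_TOL:
            flux = 0.0
        lines.append(f"{rxn.id}\t{flux:.6g}\t{rxn.subsystem}")
    Path(path).write_text("\n".join(lines) + "\n")
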