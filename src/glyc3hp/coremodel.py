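"""A reduced, fully-specified central-carbon E. coli model.

This generator builds a ~40-reaction network that carries every feature
the 3HP strain-design pipeline exercises, with real chemical formulas so
elemental bookkeeping is meaningful:

* two glycerol entry routes — glycerol kinase + quinone-linked G3P
  dehydrogenase, and glycerol dehydrogenase + PEP-dependent DHA kinase;
* triosephosphate isomerase (tpiA) bridging DHAP and GAP, lumped lower
  glycolysis to PEP/pyruvate, and a gluconeogenic FBP/F6P/G6P arm;
* the oxidative pentose phosphate branch (zwf, gnd) with a lumped
  non-oxidative return, and the Entner-Doudoroff pathway (edd, eda);
* the methylglyoxal shunt (mgsA -> glyoxalase -> respiratory D-lactate
  dehydrogenase), normally latent, which becomes the only catabolic
  route when both triosephosphate isomerase and the G6P entry into
  ED/PPP are deleted;
* fructose-6-phosphate aldolase (fsaB) joining DHA and GAP;
* fermentation branches (acetate, ethanol, formate, D-lactate,
  reductive succinate), a lumped TCA cycle, a lumped respiratory chain
  with a tunable P/O ratio, transhydrogenase, ATP maintenance, and a
  single-precursor biomass drain with a declared carbon content.

The generator is deterministic: the same spec always yields the same
model, byte-identical in the native JSON dump.  It does not try to
reproduce genome-scale numerics — its purpose is to make every pipeline
stage testable and to reproduce the *mechanisms* (e.g. knockout of
tpiA plus zwf rerouting carbon through methylglyoxal) qualitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .core import Metabolite, Model, ModelValidationError, Reaction, parse_formula

__all__ = ["CoreModelSpec", "build_core_model"]


@dataclass(frozen=True)
class CoreModelSpec:
    """Tunable knobs of the generated core model.

    ``po_ratio`` is the ATP yield per electron pair entering the lumped
    respiratory chain (mol ATP / mol quinol oxidised); ``gam`` is the
    non-growth-associated ATP maintenance flux in mmol/(gDC*h);
    ``biomass_carbon`` is the carbon drained by one unit of biomass flux
    in mmol C/gDC, i.e. the carbon content of a gram of dry cells.
    """

    include_ed_pathway: bool = True
    include_methylglyoxal: bool = True
    include_ppp: bool = True
    po_ratio: float = 1.5
    gam: float = 8.39
    biomass_carbon: float = 40.0

    def __post_init__(self):
        if self.po_ratio <= 0:
            raise ValueError(f"po_ratio must be positive, got {self.po_ratio}")
        if self.biomass_carbon <= 0:
            raise ValueError(
                f"biomass_carbon must be positive, got {self.biomass_carbon}"
            )


# id -> (name, formula, charge, compartment)
_METABOLITES: Dict[str, Tuple[str, str, int, str]] = {
    # extracellular
    "glyc_e": ("Glycerol", "C3H8O3", 0, "e"),
    "o2_e": ("Oxygen", "O2", 0, "e"),
    "co2_e": ("Carbon dioxide", "CO2", 0, "e"),
    "h2o_e": ("Water", "H2O", 0, "e"),
    "h_e": ("Proton", "H", 1, "e"),
    "pi_e": ("Phosphate", "HO4P", -2, "e"),
    "nh4_e": ("Ammonium", "H4N", 1, "e"),
    "ac_e": ("Acetate", "C2H3O2", -1, "e"),
    "etoh_e": ("Ethanol", "C2H6O", 0, "e"),
    "for_e": ("Formate", "CHO2", -1, "e"),
    "succ_e": ("Succinate", "C4H4O4", -2, "e"),
    "lac__D_e": ("D-Lactate", "C3H5O3", -1, "e"),
    # cytosolic carbon skeletons
    "glyc_c": ("Glycerol", "C3H8O3", 0, "c"),
    "glyc3p_c": ("Glycerol 3-phosphate", "C3H7O6P", -2, "c"),
    "dha_c": ("Dihydroxyacetone", "C3H6O3", 0, "c"),
    "dhap_c": ("Dihydroxyacetone phosphate", "C3H5O6P", -2, "c"),
    "g3p_c": ("Glyceraldehyde 3-phosphate", "C3H5O6P", -2, "c"),
    "fdp_c": ("Fructose 1,6-bisphosphate", "C6H10O12P2", -4, "c"),
    "f6p_c": ("Fructose 6-phosphate", "C6H11O9P", -2, "c"),
    "g6p_c": ("Glucose 6-phosphate", "C6H11O9P", -2, "c"),
    "6pgl_c": ("6-phospho-glucono-1,5-lactone", "C6H9O9P", -2, "c"),
    "6pgc_c": ("6-phospho-gluconate", "C6H10O10P", -3, "c"),
    "ru5p__D_c": ("Ribulose 5-phosphate", "C5H9O8P", -2, "c"),
    "2ddg6p_c": ("2-dehydro-3-deoxy-gluconate 6-phosphate", "C6H8O9P", -3, "c"),
    "mthgxl_c": ("Methylglyoxal", "C3H4O2", 0, "c"),
    "lac__D_c": ("D-Lactate", "C3H5O3", -1, "c"),
    "pep_c": ("Phosphoenolpyruvate", "C3H2O6P", -3, "c"),
    "pyr_c": ("Pyruvate", "C3H3O3", -1, "c"),
    "accoa_c": ("Acetyl-CoA", "C23H34N7O17P3S", -4, "c"),
    "coa_c": ("Coenzyme A", "C21H32N7O16P3S", -4, "c"),
    "actp_c": ("Acetyl phosphate", "C2H3O5P", -2, "c"),
    "ac_c": ("Acetate", "C2H3O2", -1, "c"),
    "etoh_c": ("Ethanol", "C2H6O", 0, "c"),
    "for_c": ("Formate", "CHO2", -1, "c"),
    "oaa_c": ("Oxaloacetate", "C4H2O5", -2, "c"),
    "succ_c": ("Succinate", "C4H4O4", -2, "c"),
    # cofactors and small species
    "atp_c": ("ATP", "C10H12N5O13P3", -4, "c"),
    "adp_c": ("ADP", "C10H12N5O10P2", -3, "c"),
    "nad_c": ("NAD+", "C21H26N7O14P2", -1, "c"),
    "nadh_c": ("NADH", "C21H27N7O14P2", -2, "c"),
    "nadp_c": ("NADP+", "C21H25N7O17P3", -3, "c"),
    "nadph_c": ("NADPH", "C21H26N7O17P3", -4, "c"),
    "q8_c": ("Ubiquinone-8", "C49H74O4", 0, "c"),
    "q8h2_c": ("Ubiquinol-8", "C49H76O4", 0, "c"),
    "o2_c": ("Oxygen", "O2", 0, "c"),
    "co2_c": ("Carbon dioxide", "CO2", 0, "c"),
    "h2o_c": ("Water", "H2O", 0, "c"),
    "h_c": ("Proton", "H", 1, "c"),
    "pi_c": ("Phosphate", "HO4P", -2, "c"),
    "nh4_c": ("Ammonium", "H4N", 1, "c"),
}

_FREE = (-1000.0, 1000.0)
_FWD = (0.0, 1000.0)


def _exchange(met_id: str, lb: float = 0.0, ub: float = 1000.0) -> Reaction:
    name = _METABOLITES[met_id][0]
    return Reaction(
        id=f"EX_{met_id}",
        name=f"{name} exchange",
        stoichiometry={met_id: -1.0},
        lower_bound=lb,
        upper_bound=ub,
        subsystem="Exchange",
    )


def build_core_model(spec: CoreModelSpec = CoreModelSpec()) -> Model:
    """Build the reduced central-carbon model for the given spec.

    Raises at build time if the flags leave no catabolic route from
    glycerol at all (all three of ED, PPP and methylglyoxal disabled
    would still leave glycolysis via tpiA, so only degenerate parameter
    combinations fail).
    """
    mets = [
        Metabolite(id=mid, name=name, formula=parse_formula(formula),
                   charge=charge, compartment=comp)
        for mid, (name, formula, charge, comp) in _METABOLITES.items()
    ]

    po = spec.po_ratio
    bc3 = spec.biomass_carbon / 3.0  # pyruvate (C3) is the single precursor

    rxns: List[Reaction] = []

    # --- exchanges: inorganics free, organics secretion-only, glycerol
    #     closed until a Condition is imposed
    rxns += [
        _exchange("glyc_e", 0.0, 1000.0),
        _exchange("o2_e", -1000.0, 1000.0),
        _exchange("co2_e", -1000.0, 1000.0),
        _exchange("h2o_e", -1000.0, 1000.0),
        _exchange("h_e", -1000.0, 1000.0),
        _exchange("pi_e", -1000.0, 1000.0),
        _exchange("nh4_e", -1000.0, 1000.0),
        _exchange("ac_e"),
        _exchange("etoh_e"),
        _exchange("for_e"),
        _exchange("succ_e"),
        _exchange("lac__D_e"),
    ]

    def rxn(rid, name, stoich, bounds=_FWD, gpr="", subsystem=""):
        rxns.append(
            Reaction(
                id=rid, name=name, stoichiometry=stoich,
                lower_bound=bounds[0], upper_bound=bounds[1],
                gpr=gpr, subsystem=subsystem,
            )
        )

    # --- transport
    rxn("GLYCt", "Glycerol transport (diffusion)",
        {"glyc_e": -1, "glyc_c": 1}, _FREE, subsystem="Transport")
    rxn("O2t", "Oxygen transport", {"o2_e": -1, "o2_c": 1}, _FREE,
        subsystem="Transport")
    rxn("CO2t", "CO2 transport", {"co2_e": -1, "co2_c": 1}, _FREE,
        subsystem="Transport")
    rxn("H2Ot", "Water transport", {"h2o_e": -1, "h2o_c": 1}, _FREE,
        subsystem="Transport")
    rxn("Ht", "Proton transport", {"h_e": -1, "h_c": 1}, _FREE,
        subsystem="Transport")
    rxn("PIt", "Phosphate transport (proton symport)",
        {"pi_e": -1, "h_e": -1, "pi_c": 1, "h_c": 1}, _FREE, subsystem="Transport")
    rxn("NH4t", "Ammonium transport", {"nh4_e": -1, "nh4_c": 1}, _FREE,
        subsystem="Transport")
    rxn("ACt", "Acetate transport (proton symport)",
        {"ac_c": -1, "h_c": -1, "ac_e": 1, "h_e": 1}, _FREE, subsystem="Transport")
    rxn("ETOHt", "Ethanol transport (diffusion)",
        {"etoh_c": -1, "etoh_e": 1}, _FREE, subsystem="Transport")
    rxn("FORt", "Formate transport (proton symport, export)",
        {"for_c": -1, "h_c": -1, "for_e": 1, "h_e": 1}, _FWD, subsystem="Transport")
    rxn("SUCCt", "Succinate transport (proton symport, export)",
        {"succ_c": -1, "h_c": -2, "succ_e": 1, "h_e": 2}, _FWD,
        subsystem="Transport")
    rxn("LAC_Dt", "D-lactate transport (proton symport)",
        {"lac__D_c": -1, "h_c": -1, "lac__D_e": 1, "h_e": 1}, _FREE,
        subsystem="Transport")

    # --- glycerol entry routes
    rxn("GLYK", "Glycerol kinase",
        {"glyc_c": -1, "atp_c": -1, "glyc3p_c": 1, "adp_c": 1, "h_c": 1},
        gpr="glpK", subsystem="Glycerol catabolism")
    rxn("G3PD5", "Glycerol-3-phosphate dehydrogenase (quinone)",
        {"glyc3p_c": -1, "q8_c": -1, "dhap_c": 1, "q8h2_c": 1},
        gpr="glpD", subsystem="Glycerol catabolism")
    rxn("GLYCDx", "Glycerol dehydrogenase (NAD)",
        {"glyc_c": -1, "nad_c": -1, "dha_c": 1, "nadh_c": 1, "h_c": 1},
        gpr="gldA", subsystem="Glycerol catabolism")
    # PTS-like DHA kinase: PEP is the phosphoryl donor; the two-subunit
    # GPR exercises AND (complex) semantics
    rxn("DHAPT", "Dihydroxyacetone kinase (PEP-dependent)",
        {"dha_c": -1, "pep_c": -1, "dhap_c": 1, "pyr_c": 1},
        gpr="(dhaK and dhaL)", subsystem="Glycerol catabolism")

    # --- glycolysis / gluconeogenesis
    rxn("TPI", "Triosephosphate isomerase",
        {"dhap_c": -1, "g3p_c": 1}, _FREE, gpr="tpiA", subsystem="Glycolysis")
    rxn("FBA", "Fructose-bisphosphate aldolase",
        {"dhap_c": -1, "g3p_c": -1, "fdp_c": 1}, _FREE, gpr="fbaA",
        subsystem="Glycolysis")
    rxn("FBP", "Fructose-1,6-bisphosphatase",
        {"fdp_c": -1, "h2o_c": -1, "f6p_c": 1, "pi_c": 1},
        gpr="fbp", subsystem="Gluconeogenesis")
    rxn("PGI", "Glucose-6-phosphate isomerase",
        {"g6p_c": -1, "f6p_c": 1}, _FREE, gpr="pgi", subsystem="Glycolysis")
    # lumped GAPDH + PGK + PGM + enolase
    rxn("GAPPEP", "GAP to PEP (lumped lower glycolysis)",
        {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "adp_c": -1,
         "pep_c": 1, "nadh_c": 1, "atp_c": 1, "h2o_c": 1, "h_c": 1},
        gpr="gapA", subsystem="Glycolysis")
    rxn("PYK", "Pyruvate kinase",
        {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
        gpr="pykF", subsystem="Glycolysis")
    # fructose-6-phosphate aldolase: joins DHA and GAP
    rxn("F6PA", "Fructose-6-phosphate aldolase",
        {"f6p_c": -1, "dha_c": 1, "g3p_c": 1}, _FREE, gpr="fsaB",
        subsystem="Glycolysis")

    # --- pentose phosphate (oxidative + lumped non-oxidative return)
    if spec.include_ppp or spec.include_ed_pathway:
        rxn("G6PDH2r", "Glucose-6-phosphate dehydrogenase",
            {"g6p_c": -1, "nadp_c": -1, "6pgl_c": 1, "nadph_c": 1, "h_c": 1},
            gpr="zwf", subsystem="Pentose phosphate pathway")
        rxn("PGL", "6-phosphogluconolactonase",
            {"6pgl_c": -1, "h2o_c": -1, "6pgc_c": 1, "h_c": 1},
            gpr="pgl", subsystem="Pentose phosphate pathway")
    if spec.include_ppp:
        rxn("GND", "Phosphogluconate dehydrogenase",
            {"6pgc_c": -1, "nadp_c": -1, "ru5p__D_c": 1, "co2_c": 1, "nadph_c": 1},
            gpr="gnd", subsystem="Pentose phosphate pathway")
        # lumped transketolase/transaldolase; the OR-pair exercises
        # isozyme semantics
        rxn("PPPNOX", "Non-oxidative PPP (lumped)",
            {"ru5p__D_c": -3, "f6p_c": 2, "g3p_c": 1}, _FREE,
            gpr="(tktA or tktB)", subsystem="Pentose phosphate pathway")

    # --- Entner-Doudoroff
    if spec.include_ed_pathway:
        rxn("EDD", "6-phosphogluconate dehydratase",
            {"6pgc_c": -1, "2ddg6p_c": 1, "h2o_c": 1},
            gpr="edd", subsystem="Entner-Doudoroff pathway")
        rxn("EDA", "KDPG aldolase",
            {"2ddg6p_c": -1, "pyr_c": 1, "g3p_c": 1},
            gpr="eda", subsystem="Entner-Doudoroff pathway")

    # --- methylglyoxal shunt
    if spec.include_methylglyoxal:
        rxn("MGSA", "Methylglyoxal synthase",
            {"dhap_c": -1, "mthgxl_c": 1, "pi_c": 1},
            gpr="mgsA", subsystem="Methylglyoxal shunt")
        rxn("GLYOX", "Glyoxalase system (lumped)",
            {"mthgxl_c": -1, "h2o_c": -1, "lac__D_c": 1, "h_c": 1},
            gpr="gloA", subsystem="Methylglyoxal shunt")
        rxn("LDH_D", "D-lactate dehydrogenase (quinone)",
            {"lac__D_c": -1, "q8_c": -1, "pyr_c": 1, "q8h2_c": 1},
            gpr="dld", subsystem="Methylglyoxal shunt")

    # --- pyruvate metabolism and fermentation branches
    rxn("PDH", "Pyruvate dehydrogenase",
        {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
         "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
        gpr="aceE", subsystem="Pyruvate metabolism")
    rxn("PFL", "Pyruvate formate-lyase",
        {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1},
        gpr="pflB", subsystem="Pyruvate metabolism")
    rxn("PTAr", "Phosphotransacetylase",
        {"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1}, _FREE,
        gpr="pta", subsystem="Pyruvate metabolism")
    rxn("ACKr", "Acetate kinase",
        {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1}, _FREE,
        gpr="ackA", subsystem="Pyruvate metabolism")
    rxn("ALCD", "Acetaldehyde/alcohol dehydrogenase (lumped)",
        {"accoa_c": -1, "nadh_c": -2, "h_c": -2,
         "etoh_c": 1, "coa_c": 1, "nad_c": 2},
        gpr="adhE", subsystem="Pyruvate metabolism")

    # --- TCA (lumped oxidative turn) and anaplerotic/reductive branch
    rxn("TCA", "TCA cycle (lumped oxidative turn)",
        {"accoa_c": -1, "nad_c": -3, "q8_c": -1, "adp_c": -1, "pi_c": -1,
         "h2o_c": -2, "coa_c": 1, "co2_c": 2, "nadh_c": 3, "q8h2_c": 1,
         "atp_c": 1, "h_c": 2},
        gpr="gltA", subsystem="TCA cycle")
    rxn("PPC", "PEP carboxylase",
        {"pep_c": -1, "co2_c": -1, "h2o_c": -1, "oaa_c": 1, "pi_c": 1, "h_c": 1},
        gpr="ppc", subsystem="Anaplerosis")
    rxn("FRDlump", "Reductive succinate branch (lumped)",
        {"oaa_c": -1, "nadh_c": -1, "q8h2_c": -1, "h_c": -1,
         "succ_c": 1, "nad_c": 1, "q8_c": 1, "h2o_c": 1},
        gpr="frdA", subsystem="Fermentation")

    # --- respiration and redox
    rxn("NADHDH", "NADH dehydrogenase (quinone)",
        {"nadh_c": -1, "h_c": -1, "q8_c": -1, "nad_c": 1, "q8h2_c": 1},
        gpr="ndh", subsystem="Respiration")
    rxn("CYTBO", "Quinol oxidase + oxidative phosphorylation (lumped)",
        {"q8h2_c": -1, "o2_c": -0.5, "adp_c": -po, "pi_c": -po, "h_c": -po,
         "q8_c": 1, "atp_c": po, "h2o_c": 1 + po},
        gpr="cyoA", subsystem="Respiration")
    rxn("THD", "Transhydrogenase (soluble)",
        {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1}, _FREE,
        gpr="sthA", subsystem="Redox")

    # --- maintenance and biomass
    rxn("ATPM", "ATP maintenance requirement",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        (spec.gam, 1000.0), subsystem="Maintenance")
    # growth-associated ATP demand of ~60 mmol/gDC and an NADPH demand of
    # 10 mmol/gDC are in the physiological range for E. coli
    rxn("BIOMASS", "Biomass (single-precursor drain)",
        {"pyr_c": -bc3, "atp_c": -60.0, "h2o_c": -60.0, "nadph_c": -10.0,
         "nh4_c": -6.0, "adp_c": 60.0, "pi_c": 60.0, "nadp_c": 10.0, "h_c": 66.0},
        subsystem="Biomass")

    model = Model(
        id="ecoli_core_glyc",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )
    model.validate()

    # a catabolic route from glycerol must exist: glycerol kinase always
    # does, so only a degenerate future edit can trip this
    if not (model.has_reaction("GLYK") or model.has_reaction("GLYCDx")):
        raise ModelValidationError("core model has no glycerol catabolic route")
    return model
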