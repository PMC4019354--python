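"""Normalized flux maps: wild type versus the tpiA+zwf double knockout.

Fluxes are expressed as signed percentages of the glycerol uptake rate,
the convention used for drawing central-metabolism flux maps.
"""

from glyc3hp import (
    Condition,
    add_3hp_pathway,
    apply_knockout,
    build_core_model,
    normalize_flux_map,
    set_condition,
    solve_lexicographic,
)

strain = set_condition(add_3hp_pathway(build_core_model()), Condition(15, 10))
double = apply_knockout(strain, ["tpiA", "zwf"])

watch = ["GLYK", "GLYCDx", "TPI", "EDD", "MGSA", "GLYCDHT", "EX_3hp_e", "EX_ac_e"]
maps = {}
for label, model in (("wild-type", strain), ("DtpiA Dzwf", double)):
    sol = solve_lexicographic(model, secondary="EX_3hp_e")
    maps[label] = normalize_flux_map(sol, watch)

print(f"{'reaction':<10}" + "".join(f"{label:>14}" for label in maps))
for rxn_id in watch:
    row = "".join(f"{maps[label][rxn_id]:>13.1f}%" for label in maps)
    print(f"{rxn_id:<10}{row}")

# In the wild type glycerol enters through glycerol kinase and lower
# glycolysis (TPI carries flux); the knockout zeroes TPI and the
# Entner-Doudoroff entry (EDD), so carbon detours through methylglyoxal
# synthase (MGSA) and most of it leaves as 3HP (EX_3hp_e) instead of
# acetate (EX_ac_e).
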