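{
 "id": "3hp",
 "description": "Heterologous 3-hydroxypropionic acid / 1,3-propanediol pathway from glycerol: glycerol dehydratase (dhaB/gdrAB), 3HPA dehydrogenase (aldH), 3HP proton-symport export and exchange, NADPH-dependent 1,3-PDO oxidoreductase (yqhD), 1,3-PDO diffusion and exchange. 3HP is modelled as the -1 anion, matching the lactate convention.",
 "metabolites": [
  {"id": "3hpa_c", "name": "3-hydroxypropionaldehyde", "formula": "C3H6O2", "charge": 0, "compartment": "c"},
  {"id": "3hp_c", "name": "3-hydroxypropionate", "formula": "C3H5O3", "charge": -1, "compartment": "c"},
  {"id": "3hp_e", "name": "3-hydroxypropionate (extracellular)", "formula": "C3H5O3", "charge": -1, "compartment": "e"},
  {"id": "13pdo_c", "name": "1,3-propanediol", "formula": "C3H8O2", "charge": 0, "compartment": "c"},
  {"id": "13pdo_e", "name": "1,3-propanediol (extracellular)", "formula": "C3H8O2", "charge": 0, "compartment": "e"}
 ],
 "reactions": [
  {
   "id": "GLYCDHT",
   "name": "Glycerol dehydratase",
   "stoichiometry": {"glyc_c": -1, "3hpa_c": 1, "h2o_c": 1},
   "lower_bound": 0, "upper_bound": 1000,
   "gpr": "(dhaB and gdrAB)",
   "subsystem": "3HP pathway (heterologous)"
  },
  {
   "id": "ALDD3HPA",
   "name": "3HPA dehydrogenase (NAD)",
   "stoichiometry": {"3hpa_c": -1, "nad_c": -1, "h2o_c": -1, "3hp_c": 1, "nadh_c": 1, "h_c": 2},
   "lower_bound": 0, "upper_bound": 1000,
   "gpr": "aldH",
   "subsystem": "3HP pathway (heterologous)"
  },
  {
   "id": "3HPt",
   "name": "3HP transport via proton symport (export)",
   "stoichiometry": {"3hp_c": -1, "h_c": -1, "3hp_e": 1, "h_e": 1},
   "lower_bound": 0, "upper_bound": 1000,
   "gpr": "",
   "subsystem": "Transport"
  },
  {
   "id": "EX_3hp_e",
   "name": "3HP exchange",
   "stoichiometry": {"3hp_e": -1},
   "lower_bound": 0, "upper_bound": 1000,
   "gpr": "",
   "subsystem": "Exchange"
  },
  {
   "id": "PDOR13",
   "name": "1,3-propanediol oxidoreductase (NADPH)",
   "stoichiometry": {"3hpa_c": -1, "nadph_c": -1, "h_c": -1, "13pdo_c": 1, "nadp_c": 1},
   "lower_bound": 0, "upper_bound": 1000,
   "gpr": "yqhD",
   "subsystem": "3HP pathway (heterologous)"
  },
  {
   "id": "13PDOt",
   "name": "1,3-propanediol transport via diffusion",
   "stoichiometry": {"13pdo_c": -1, "13pdo_e": 1},
   "lower_bound": -1000, "upper_bound": 1000,
   "gpr": "",
   "subsystem": "Transport"
  },
  {
   "id": "EX_13pdo_e",
   "name": "1,3-propanediol exchange",
   "stoichiometry": {"13pdo_e": -1},
   "lower_bound": 0, "upper_bound": 1000,
   "gpr": "",
   "subsystem": "Exchange"
  }
 ]
}
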