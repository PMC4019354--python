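# Methods

## Model and optimisation

The package works on constraint-based metabolic models: metabolites
with chemical formulas and charges, reactions with stoichiometry, flux
bounds in mmol/(gDC·h) and boolean gene–protein–reaction (GPR) rules,
and one designated biomass reaction whose flux is the specific growth
rate μ (1/h). A model compiles to a sparse stoichiometric matrix *S*
(rows = metabolites, columns = reactions) in input order, so repeated
runs present the LP to the solver identically and return identical
basic solutions.

Flux balance analysis solves `max cᵀv  s.t.  Sv = 0, v_min ≤ v ≤ v_max`.
The assumptions are the standard ones: pseudo-steady state of internal
metabolites, growth-rate maximisation as the cellular objective, and no
kinetic or regulatory constraints. Production fluxes at a growth
optimum are generally degenerate, so production is evaluated
lexicographically: stage 1 maximises biomass to μ\*, stage 2 maximises
the product exchange subject to `v_biomass ≥ μ*(1 − 1e-6)`. The
relative relaxation (rather than an equality) keeps stage 2 feasible
across solvers at negligible cost: it frees at most a 1e-6 fraction of
the growth optimum, which propagates to yield errors orders of
magnitude below the reporting precision.

The LP backend is scipy's HiGHS dual simplex behind a single
matrix/bounds/objective contract, so another simplex or interior-point
implementation can be swapped in. Numerical hygiene: solver
feasibility tolerance 1e-9; steady-state and bound checks on returned
solutions at 1e-6; fluxes below 1e-7 are reported as zero in tables so
degenerate vertices do not print phantom byproducts. Infeasible or
unbounded problems are reported through the solution status, never as
silent zeros.

## The 3HP pathway graft and the culture condition

Seven reactions are grafted onto the host model, shipped as a JSON data
file so alternative stoichiometries can be swapped without code
changes: glycerol dehydratase (glycerol → 3HPA + H₂O, GPR
dhaB·gdrAB), NAD⁺-dependent 3HPA dehydrogenase (3HPA + NAD⁺ + H₂O →
3HP + NADH + 2H⁺, aldH), 3HP export as a proton symporter (modelled on
D-lactate transport, since 3HP is its structural analogue), the 3HP
exchange, the NADPH-dependent 1,3-PDO oxidoreductase (yqhD), 1,3-PDO
export as passive diffusion, and the 1,3-PDO exchange. All are
irreversible as written except the diffusion transporter. 3HP is
modelled as the −1 anion with explicit proton bookkeeping, matching
the lactate convention; all grafted reactions pass C/H/O mass-balance
checks. Grafting is deliberately not idempotent — a second graft
raises — and the heterologous pseudo-genes (dhaB, gdrAB, aldH) are
excluded from knockout screens by default, while yqhD, a host gene,
remains a candidate.

The culture condition sets the glycerol exchange lower bound to −GUR
and the oxygen exchange lower bound to −OUR (defaults 15 and 10
mmol/(gDC·h), OUR/GUR = 0.67, a microaerobic regime), closes every
other carbon-containing exchange to uptake, and leaves inorganic
exchanges at the model's defaults. CO₂ is treated as freely
exchanged in both directions — it crosses the membrane passively and
fixing it is never carbon-profitable in these networks — as are water,
protons, ammonium, phosphate and the mineral ions. Uptake is a bound,
not an equality: yields are computed on the *consumed* flux, so the
distinction cannot affect C-mol%.

## Knockouts and screening

Deleting a gene set disables every reaction whose GPR evaluates false
with those genes removed (AND = complex subunits, OR = isozymes; an
empty rule means the reaction cannot be disabled). Disabled reactions
get both bounds set to zero on a copy of the model. Screens evaluate
every single deletion or every unordered pair with one lexicographic
solve each. Two economies keep this exact but cheap: deletions that
disable identical reaction sets are provably the same LP, so each
equivalence class is solved once and the result shared; and the
wild-type solve is done once up front. Records are ranked by 3HP
yield, then relative growth, then gene ids — a total order, so the
table is deterministic. A deletion whose LP is infeasible, or whose
maximal growth is below the zero-flux threshold, is recorded as lethal
with growth 0 *and* yield 0: a strain that cannot grow produces
nothing, whatever a degenerate zero-growth optimum would allow.
Relative growth is clipped to [0, 100] to absorb solver rounding; the
underlying LP guarantees a knockout cannot out-grow its parent.

## Carbon accounting

Carbon numbers come from metabolite formulas, never from constants, so
glycerol = 3, acetate = 2, succinate = 4 fall out of the model file.
The biomass carbon drain is computed from the biomass equation itself:
net carbon = Σ consumed coefficients × C-counts − Σ produced ones
(cofactor pairs cancel), in mmol C per gDC. For any optimal solution
the product yields, the CO₂ yield and the biomass yield then close the
carbon balance at 100 C-mol% — an invariant the tests enforce at
±0.1. The printed summary omits CO₂ (it is the balance closer, not a
product of interest); the machine-readable report keeps it. Flux maps
normalise fluxes to percent of the glycerol uptake, signed.

## The generated central-carbon model

`build_core_model` emits a deterministic ~57-reaction, 50-metabolite
network with real chemistry (every non-exempt reaction balances C, H,
O and charge): two glycerol entry routes (ATP-dependent kinase +
quinone-linked G3P dehydrogenase; NAD-linked dehydrogenase +
PEP-dependent DHA kinase), triosephosphate isomerase, lumped lower
glycolysis, a gluconeogenic FBP/F6P/G6P arm, oxidative PPP with a
lumped non-oxidative return, Entner–Doudoroff, the methylglyoxal
shunt, fructose-6-phosphate aldolase, pyruvate dehydrogenase and
formate lyase, acetate/ethanol/lactate/succinate fermentation
branches, a lumped TCA turn, a lumped respiratory chain with P/O ratio
1.5, soluble transhydrogenase, ATP maintenance at 8.39 mmol/(gDC·h)
and a single-precursor biomass drain. The biomass consumes 13⅓ mmol
pyruvate (40 mmol C/gDC, the carbon content of a gram of dry *E.
coli*), 60 mmol ATP and 10 mmol NADPH per gram — round figures in the
physiological range chosen so that microaerobic growth is
energy-limited rather than carbon-limited, which is what makes
overflow metabolism and the knockout logic appear. Deletable
single-gene GPRs cover the screening surface (tpiA, zwf, pgi, edd,
gldA, fsaB, mgsA, plus yqhD on the grafted oxidoreductase); one
AND-pair (dhaK·dhaL) and one OR-pair (tktA/tktB) exist specifically to
exercise GPR semantics.

What the fixture reproduces is the *mechanism*, quantitatively
self-consistent but not genome-scale numerics: under GUR 15/OUR 10 the
wild type grows at 0.68 1/h with acetate overflow and zero 3HP; no
single deletion yields 3HP; deleting tpiA alone reroutes catabolism
through Entner–Doudoroff; deleting tpiA together with any G6P-entry
gene forces the methylglyoxal shunt and 3HP appears at ~69 C-mol% with
growth at 43% of wild type; with growth forced to zero and oxygen free
the 3HP yield ceiling is exactly 100 C-mol%. What it does not emulate:
the ~2,000-reaction redundancy of a genome-scale reconstruction
(isozyme-rich GPRs, alternative cofactor routes, maintenance split
into growth-associated and non-growth-associated terms), periplasmic
transport chemistry, or any kinetic/regulatory effect — notably
methylglyoxal toxicity and 1,3-PDO overflow, which are kinetic
phenomena a stoichiometric model cannot show. Passing fixture tests
therefore certify the machinery and the qualitative design logic, not
genome-scale yield predictions.

## Degenerate inputs and tie-breaks

Formula parsing rejects malformed tokens with the offending offset;
loading never returns a partially populated model; a model file with
no declared objective raises and lists candidate biomass reactions
rather than guessing. Exchange reactions are recognised structurally
(single metabolite) and are exempt, with the biomass drain, from
elemental balancing. Unknown gene ids in a knockout raise with
close-match suggestions. Screen ties (e.g. the five top pairs of the
fixture all reach the same yield) are broken by relative growth and
then lexicographic gene order.

## Problem sizes used in the checks

The shipped test suite and the acceptance script run entirely on the
generated model: single-knockout screens over 8 genes, double screens
over 6–8 genes (15–28 pairs), and a 31-point oxygen sweep — a few
hundred LPs of ~64 columns, a couple of seconds end to end. The
genome-scale checks (iAF1260, 2,077 reactions) run the identical code
path when the published model file is supplied; the full all-pairs
screen of a genome-scale model (~10⁵–10⁶ LPs) is supported by the same
screen function via the gene-subset option but is not part of the
routine checks.

## Known limitations

Steady-state, growth-optimal FBA only: no flux variability analysis,
no MOMA/ROOM knockout phenotypes, no kinetics, no regulation, no
thermodynamic feasibility beyond irreversibility assignments. The
3HPA dehydrogenase is modelled strictly NAD⁺-dependent and the
oxidoreductase strictly NADPH-dependent; cofactor promiscuity of the
real enzymes is not represented. Charge imbalance is reported but
non-fatal when checking third-party models, which are known to contain
legacy charge errors.
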