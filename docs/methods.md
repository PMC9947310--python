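# Methods

## Model representation

A `MetabolicModel` holds metabolites (with compartment, optional elemental
composition map, external ids), reactions (signed stoichiometry, flux
bounds in mmol/mouse/day, gene-reaction rule, subsystem label), genes, and
a biomass objective reaction. Reversibility is carried solely by the bounds
(lower < 0); the default unconstrained bound magnitude is 1000
mmol/mouse/day, the usual COBRA convention. Exchange reactions are
single-metabolite boundary pseudo-reactions with the *secrete-positive*
sign convention: flux +v exports v mmol/day, −v takes it up. A reaction may
override the structural single-metabolite heuristic with an explicit
`exchange` flag (needed for net-autocatalytic test reactions like X → 2X).

An elemental composition distinguishes *unknown* (`None`) from *known and
empty* (`{}`); balance checks report reactions touching unknown-formula
metabolites as "undetermined", never "balanced". Through SBML, a known
empty composition is encoded as the zero-count formula string `H0`, since
an empty string would be dropped by the writer.

GPR rules use parenthesized infix `and`/`or` (case-insensitive) over bare
gene tokens, `and` binding tighter than `or`, as in SBML-FBC practice.

SBML Level 3 (fbc) reading and writing delegates to cobrapy; subsystems are
carried in reaction notes so they survive the round trip. The tabular
dialect is three TSVs plus a JSON header (schema in `sydicos/io.py`);
equation strings render compartments in brackets (`glc[c]`).

## Linear programming

All LPs are solved with the deterministic HiGHS solver through
`scipy.optimize.linprog`. FBA maximizes the objective flux subject to
S·v = 0 and bounds. The parsimonious second stage fixes the objective at
its stage-1 optimum *exactly* (a relative band of `objective_fix_tolerance`,
default 1e−6, is used only as a numerical fallback) and minimizes Σ|vⱼ| via
auxiliary variables tⱼ ≥ |vⱼ|. Exact fixing keeps the parsimonious
objective equal to the FBA optimum to solver precision, which downstream
distance comparisons rely on. Default primal/dual tolerances are 1e−9.
Residual degeneracy after L1 minimization can in principle remain; with a
fixed deterministic solver the returned vertex is reproducible, which is
what pairwise distances require. No flux variability analysis, MILP or
sampling is provided.

## Constraint layers

* **Diet** (`diet_bounds`): b = (P/100 · W/M) · 1000 caps the *uptake*
  direction only (exchange lower bound = −b); the secretion side is left
  open, so diet metabolites may also be produced, and the model may always
  take up less than offered. P is % w/w, W defaults to 3 g food/mouse/day,
  M is g/mol. `split_pooled_components` divides a pooled entry's % w/w
  equally among its member metabolites, which inherit the pool's class.
* **Gas exchange** (`gas_bounds`): b = p·V/M · 1000 is a *minimum* on the
  measured direction — uptake (exchange flux ≤ −b, O₂ consumption) or
  production (flux ≥ +b, CO₂) — selectable per model variant, since which
  gas constrains which model depends on the experimental design.
* **Adapted E-flux** (`eflux_bounds`): bound magnitude = GPR fold over mean
  per-gene expression; OR = sum (isozymes add capacity), AND = min (a
  complex is limited by its scarcest subunit; the single-gene and OR cases
  are the documented ones, min is the standard complex rule). Reversible
  reactions get (−b, +b), irreversible (0, b). Orphan reactions and
  exchanges receive no entry. Raw expression values (FPKM-like) are used as
  bounds without rescaling to flux units; the two layers therefore
  interact only through whichever is smaller per reaction. Unmeasured
  genes contribute 0 at their leaf, so a reaction whose only catalyst is
  unmeasured is blocked — deliberate, and visible in the bound map.
* `apply_constraints` applies ordered layers to a copy, later layers
  winning per reaction side; structural irreversibility is never widened
  (an irreversible reaction cannot receive a negative lower bound), and a
  final lower > upper conflict raises.

FPKM classification bins: high ≥ 50, medium [10, 50), low [1, 10),
none < 1. `expression_gate_extraction` is a deliberately simple
extraction heuristic — drop reactions whose every gene is in the "none"
bin, then greedily reinstate (id-sorted) until tasks and biomass recover.
It is documented as *not* the task-driven MILP (tINIT) used for published
tissue models, which is out of scope.

## Curation

* `map_metabolite_ids` renames onto a target namespace (e.g. KEGG) as
  `<target>_<compartment>`; same-compartment collisions merge, re-pointed
  stoichiometry is summed, and a net-zero coefficient drops the metabolite
  from that reaction with a flag.
* `remove_duplicates` canonicalizes stoichiometry (sorted terms,
  coefficients rounded at 1e−9; reversible reactions are
  direction-normalized so reverse duplicates collapse). The first reaction
  in model order is kept, GPRs are OR-joined, widest orientation-adjusted
  bounds retained. Only stoichiometric identity is tested, not bounds or
  GPRs.
* `elemental_balance` checks {C, N, O, S, P} by default; exchanges report
  status "exchange" (imbalanced by construction).
* `prune_imbalanced` visits imbalanced reactions in id-sorted order
  (deterministic; the order is otherwise unspecified in the protocol this
  mirrors) and keeps a removal only if the biomass optimum stays within a
  relative `biomass_tolerance` (default 1e−6 — the strictest reading of
  "consistent biomass flux") and every originally passing task still
  passes; otherwise the reaction is reinstated and flagged for manual
  curation. The biomass drain itself is a pseudo-reaction, imbalanced by
  design, and is skipped.
* `check_tasks` is feasibility-only: all exchanges closed, allowed inputs
  opened up to their maxima, required outputs imposed as minimum
  production, steady-state LP solved with a zero objective. Task
  metabolites without an exchange get a temporary one, so intracellular
  products can be demanded directly.
* `stoichiometric_consistency` solves max Σzᵢ s.t. S_intᵀ·m = 0,
  0 ≤ z ≤ 1, z ≤ m, m ≥ 0 over internal reactions (exchanges *and* the
  biomass sink excluded — a drain can never conserve positive mass) and
  reports metabolites with z < 1 − 1e−6. On small models it agrees with an
  independent per-metabolite formulation (maximize each mᵢ separately),
  which the tests exercise.

## SyDiCoS

A `SwapPlan` names a base diet, a reference diet, the component classes to
swap, and an optional sugar restriction. The swap operates at the
metabolite level: every base-diet metabolite of a swapped class takes the
reference diet's % w/w (0 if absent), swapped-class metabolites present
only in the reference are added, everything else keeps base values, and
daily intake stays the base diet's. Class-level carbon totals swap as a
consequence; the metabolite-level rule is the only unambiguous realization
of a class-level swap. `restrict_sugars` zeroes all carbohydrates except a
kept set.

`run_sydicos` solves parsimonious FBA for every (model, plan) cell,
applying the plan's diet bounds on top of the model's existing
(expression/gas) bounds; per-cell failures are recorded and the batch
continues. Comparisons:

* Euclidean `flux_distance` over the shared reaction set, id-sorted, with
  exchange reactions included by default (flag to exclude); no per-reaction
  normalization is applied since none is defined for this comparison.
* `distance_matrix` optionally divides by the maximum entry ("relative to
  the maximum distance").
* `flux_ratio` reports |a|/|b| with categorical codes (`new`, `off`) below
  an epsilon (default 1e−9) instead of infinities, keeping reports
  serializable.
* `efflux_influx_summary` converts exchange fluxes into carbon influx and
  efflux totals (C_moles = Σ Cⱼ·vⱼ) and reports carbons drained by the
  biomass reaction separately; on a fully carbon-balanced model,
  influx = efflux + biomass-sunk carbons to solver precision.
* `subsystem_reaction_ratio` restricts to subsystems with at least one
  reaction carrying |v| > flux_epsilon (default 1e−6 mmol/day, a value the
  protocol leaves unspecified) and reports the fraction of carried
  reactions with higher |flux| in condition a.
* `differential_subnetwork` collects reactions (optionally filtered by
  subsystem) whose fluxes differ beyond flux_epsilon, builds a
  reaction-metabolite bipartite graph excluding a configurable currency
  list (H₂O, H⁺, ATP/ADP, NAD(H), CO₂, Pi by default, matched on
  compartment-stripped base names), and returns the connected component
  containing biomass. The published differential networks were manually
  curated; the currency list and epsilon are the knobs this automation
  exposes.

## Synthetic fixtures

The toy hepatic model (34 metabolites, 41 reactions, 3 compartments)
implements: glucose/fructose uptake, lumped glycolysis with a reversible
aldolase step (so gluconeogenesis from trioses works), fructolysis through
fructose 1-phosphate, a glycerol-production branch (DHAP → G3P → glycerol
efflux), serine synthesis from 3-phosphoglycerate, fatty-acid activation
and the branch point between carnitine-shuttle β-oxidation and
G3P-acyltransferase acylglycerol synthesis, an O₂-coupled TCA cycle with
succinate efflux and pyruvate-carboxylase anaplerosis, amino-acid
catabolism, and a biomass drain of 0.3 G6P + 2 AA + 0.2 Ser + 0.1 TAG per
unit flux. Every metabolite composition tracks the carbon skeleton only
(gases have known zero-carbon compositions), so each internal reaction is
exactly carbon-balanced and the {C,N,O,S,P} balance check passes with all
non-carbon imbalances trivially zero; full CHONSP bookkeeping is not
attempted. Gas transport is orphan (free diffusion), so expression never
caps respiration transport. A strictly positive mass vector exists for the
network (verified by the consistency LP), so consistency flaws are
attributable to injections alone.

Diet fixtures are fixed constants, not sampled, so swap identities are
exact: CD-like 60% glucose / 0% fructose / 5% fatty acid / 18% amino acid,
WD-like 30/25/20/15, both at 3 g/day — WD has more lipid, less
carbohydrate, contains fructose, and offers ~107.5 vs ~87.5 mmol C/day.
Molecular weights and carbon counts use glucose/fructose 180.156 (C6),
palmitate 256.42 (C16), alanine-like pool 89.09 (C3).

Expression profiles are seeded per-gene log-normal factors (σ = 0.3)
around pathway base levels (transport/glycolysis/TCA 50, fructolysis 30,
amino-acid 30, glycerol 20, lipid and serine synthesis 10, β-oxidation 4,
FPKM-like units); the tumor-like profile scales the *same* draw by
pathway factors (β-oxidation ×0.25, lipid + serine synthesis ×4), so T/PT
ratios are exact by construction. The study-like scenario
(`make_scenario`) additionally forces CO₂ production ≥ 30 mmol/mouse/day,
standing in for a metabolic-cage respiration measurement; this is what
obliges the models to oxidize substrate, so the β-oxidation expression gap
becomes a flux gap. The base levels were chosen once so that, at
diet-scale fluxes, the β-oxidation cap binds in the tumor-like model while
transport/glycolysis/TCA caps do not.

What the fixture does and does not emulate: it reproduces the *structure*
of the study conditions — two diets differing in lipid/carbohydrate/carbon
content, two expression states differing in fatty-acid routing, demand- not
availability-limited uptake, and divergence that collapses under a full
swap to control. It does not attempt real nutrient compositions, real FPKM
distributions, genome-scale network size, or the specific glycerol/
succinate effluxes of the tissue models; passing tests therefore validate
the machinery and its contracts, not tissue-scale biology. In this toy the
divergence is entirely lipid-driven (the lipid-only swap already collapses
it); the qualitative acceptance property is deliberately the weaker,
design-guaranteed contrast WD > full swap.

## Problem sizes and determinism

All LPs have ≤ ~90 variables; a full 2×5 batch solves in well under a
second. The acceptance checks use 50 random ≤12-reaction networks for
solver cross-validation, 20 seeds for flaw recovery and for the swap
contrast, and 1000 random triples for the metric properties. Every source
of randomness flows through an explicit integer seed
(`numpy.random.default_rng`); diet fixtures and the toy network are
seed-independent constants.

## Known limitations

* No digestion/absorption or microbiome layer: diet components are assumed
  directly available to the tissue boundary.
* Raw expression units as flux bounds (no scaling calibration).
* The extraction heuristic is not a faithful tissue-model extraction
  algorithm.
* Duplicate detection ignores bounds/GPR differences by design.
* Charge balance is not checked (mass only).
* Single-tissue models only; no whole-body exchange.
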