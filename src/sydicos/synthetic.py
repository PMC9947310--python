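"""Seeded generators for toy hepatic models, diets, and expression profiles.

The toy model is a ~40-reaction carbon-balanced caricature of hepatic
central metabolism: glucose and fructose uptake feeding glycolysis and
fructolysis, a glycerol-production branch, a serine-synthesis branch, a TCA
cycle with succinate efflux and O2/CO2 exchange, fatty-acid uptake routed
either to mitochondrial beta-oxidation (through a carnitine shuttle) or to
acylglycerol synthesis (through a glycerol-3-phosphate acyltransferase), and
a biomass reaction draining lipid, protein and carbohydrate precursors.
Metabolite formulas track carbon skeletons (gases have known zero-carbon
compositions), so every internal reaction is exactly elementally balanced by
construction.

The diet fixtures are fixed constants: the western-style diet (WD-like) has
more lipid, less carbohydrate, contains fructose, and carries more total
dietary carbon than the control diet (CD-like); both assume 3 g food per
mouse per day.  Expression fixtures are seeded log-normal profiles in which
the tumor-like (T) condition scales beta-oxidation genes x0.25 and
lipid-synthesis plus serine-synthesis genes x4 relative to the
peritumoral-like (PT) condition.

``perturb_model`` injects a known number of carbon-imbalanced reactions,
exact duplicate reactions, and self-amplifying stoichiometrically
inconsistent reactions, returning machine-readable ground truth for
benchmarking the curation detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import BoundMap, DietEntry, DietSpec, apply_constraints, eflux_bounds
from .constraints import ExpressionProfile
from .core_model import Gene, MetabolicModel, Metabolite, Reaction
from .curation import MetabolicTask
from .swap import SwapPlan

#: forced minimum CO2 production (mmol/mouse/day) in the study-like scenario,
#: standing in for a metabolic-cage respiration measurement
CO2_FORCED_PRODUCTION = 30.0

_PATHWAY_BASE_EXPRESSION = {
    "transport": 50.0,
    "glycolysis": 50.0,
    "fructolysis": 30.0,
    "tca": 50.0,
    "amino_acid": 30.0,
    "glycerol_production": 20.0,
    "lipid_synthesis": 10.0,
    "serine_synthesis": 10.0,
    "beta_oxidation": 4.0,
    "other": 10.0,
}

_T_SCALING = {"beta_oxidation": 0.25, "lipid_synthesis": 4.0, "serine_synthesis": 4.0}

_EXPRESSION_SIGMA = 0.3


@dataclass
class ToySpec:
    seed: int = 0
    n_extra_reactions: int = 0
    flaw_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_extra_reactions < 0 or any(v < 0 for v in self.flaw_counts.values()):
            raise ValueError("counts must be non-negative")


def _met(mid, name, comp, carbons):
    return Metabolite(id=mid, name=name, compartment=comp, formula={"C": carbons} if carbons else {})


def make_toy_hepatic_model(spec: ToySpec | None = None) -> MetabolicModel:
    """Deterministic toy hepatic model; see the module docstring."""
    spec = spec or ToySpec()
    m = MetabolicModel(id="toy_hepatic")

    mets = [
        # extracellular
        ("glc_e", "glucose", "e", 6), ("fru_e", "fructose", "e", 6),
        ("fa_e", "fatty acid", "e", 16), ("aa_e", "amino acid pool", "e", 3),
        ("glyc_e", "glycerol", "e", 3), ("succ_e", "succinate", "e", 4),
        ("o2_e", "oxygen", "e", 0), ("co2_e", "carbon dioxide", "e", 1),
        # cytosol
        ("glc_c", "glucose", "c", 6), ("fru_c", "fructose", "c", 6),
        ("g6p_c", "glucose 6-phosphate", "c", 6), ("f1p_c", "fructose 1-phosphate", "c", 6),
        ("gap_c", "glyceraldehyde 3-phosphate", "c", 3),
        ("dhap_c", "dihydroxyacetone phosphate", "c", 3),
        ("pg3_c", "3-phosphoglycerate", "c", 3), ("pyr_c", "pyruvate", "c", 3),
        ("ser_c", "serine", "c", 3), ("aa_c", "amino acid pool", "c", 3),
        ("g3p_c", "glycerol 3-phosphate", "c", 3), ("glyc_c", "glycerol", "c", 3),
        ("fa_c", "fatty acid", "c", 16), ("facoa_c", "fatty acyl-CoA", "c", 16),
        ("tag_c", "triacylglycerol", "c", 51),
        ("o2_c", "oxygen", "c", 0), ("co2_c", "carbon dioxide", "c", 1),
        # mitochondria
        ("pyr_m", "pyruvate", "m", 3), ("accoa_m", "acetyl-CoA", "m", 2),
        ("oaa_m", "oxaloacetate", "m", 4), ("cit_m", "citrate", "m", 6),
        ("akg_m", "alpha-ketoglutarate", "m", 5), ("succ_m", "succinate", "m", 4),
        ("facoa_m", "fatty acyl-CoA", "m", 16),
        ("o2_m", "oxygen", "m", 0), ("co2_m", "carbon dioxide", "m", 1),
    ]
    for mid, name, comp, c in mets:
        m.add_metabolite(_met(mid, name, comp, c))

    genes = [
        ("Slc2a2", "transport"), ("Slc2a5", "transport"), ("Cd36", "transport"),
        ("Slc7a5", "transport"), ("Aqp9", "transport"), ("Slc25a10", "transport"),
        ("Mpc1", "transport"),
        ("Gck", "glycolysis"), ("Aldoa", "glycolysis"), ("Tpi1", "glycolysis"),
        ("Gapdh", "glycolysis"), ("Pkm", "glycolysis"),
        ("Khk", "fructolysis"), ("Aldob", "fructolysis"),
        ("Gpd1", "glycerol_production"), ("Pgp", "glycerol_production"),
        ("Gpam", "lipid_synthesis"), ("Gpat2", "lipid_synthesis"),
        ("Phgdh", "serine_synthesis"), ("Psat1", "serine_synthesis"),
        ("Acsl1", "lipid_synthesis"),
        ("Cpt1a", "beta_oxidation"), ("Cpt2", "beta_oxidation"),
        ("Acadl", "beta_oxidation"), ("Hadha", "beta_oxidation"),
        ("Pdha1", "tca"), ("Cs", "tca"), ("Idh2", "tca"),
        ("Ogdh", "tca"), ("Dld", "tca"), ("Sdha", "tca"), ("Sdhb", "tca"),
        ("Pcx", "tca"), ("Gpt", "amino_acid"),
    ]
    for gid, pathway in genes:
        m.add_gene(Gene(id=gid, name=pathway))

    B = 1000.0

    def rxn(rid, stoich, lb, ub, gr, subsystem, name=""):
        m.add_reaction(Reaction(id=rid, name=name or rid, stoichiometry=stoich,
                                lower_bound=lb, upper_bound=ub, gr_rule=gr,
                                subsystem=subsystem))

    # boundary exchanges (secrete-positive convention)
    rxn("EX_glc", {"glc_e": -1}, -B, B, "", "Exchange")
    rxn("EX_fru", {"fru_e": -1}, -B, B, "", "Exchange")
    rxn("EX_fa", {"fa_e": -1}, -B, B, "", "Exchange")
    rxn("EX_aa", {"aa_e": -1}, -B, B, "", "Exchange")
    rxn("EX_glyc", {"glyc_e": -1}, 0, B, "", "Exchange")
    rxn("EX_succ", {"succ_e": -1}, 0, B, "", "Exchange")
    rxn("EX_o2", {"o2_e": -1}, -B, 0, "", "Exchange")
    rxn("EX_co2", {"co2_e": -1}, 0, B, "", "Exchange")

    # transport (gas diffusion is orphan)
    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, B, "Slc2a2", "Transport")
    rxn("FRUt", {"fru_e": -1, "fru_c": 1}, 0, B, "Slc2a5", "Transport")
    rxn("FAt", {"fa_e": -1, "fa_c": 1}, 0, B, "Cd36", "Transport")
    rxn("AAt", {"aa_e": -1, "aa_c": 1}, 0, B, "Slc7a5", "Transport")
    rxn("GLYCt", {"glyc_c": -1, "glyc_e": 1}, 0, B, "Aqp9", "Transport")
    rxn("SUCCt", {"succ_m": -1, "succ_e": 1}, 0, B, "Slc25a10", "Transport")
    rxn("PYRt", {"pyr_c": -1, "pyr_m": 1}, 0, B, "Mpc1", "Transport")
    rxn("O2tc", {"o2_e": -1, "o2_c": 1}, 0, B, "", "Transport")
    rxn("O2tm", {"o2_c": -1, "o2_m": 1}, 0, B, "", "Transport")
    rxn("CO2tm", {"co2_m": -1, "co2_c": 1}, 0, B, "", "Transport")
    rxn("CO2te", {"co2_c": -1, "co2_e": 1}, 0, B, "", "Transport")

    # glycolysis (ALDO lumps PFK/aldolase and runs both ways = gluconeogenic)
    rxn("HEX", {"glc_c": -1, "g6p_c": 1}, 0, B, "Gck", "Glycolysis")
    rxn("ALDO", {"g6p_c": -1, "gap_c": 1, "dhap_c": 1}, -B, B, "Aldoa", "Glycolysis")
    rxn("TPI", {"dhap_c": -1, "gap_c": 1}, -B, B, "Tpi1", "Glycolysis")
    rxn("GAPD", {"gap_c": -1, "pg3_c": 1}, 0, B, "Gapdh", "Glycolysis")
    rxn("PYK", {"pg3_c": -1, "pyr_c": 1}, 0, B, "Pkm", "Glycolysis")

    # fructolysis
    rxn("KHK", {"fru_c": -1, "f1p_c": 1}, 0, B, "Khk", "Fructolysis")
    rxn("ALDOB", {"f1p_c": -1, "gap_c": 1, "dhap_c": 1}, 0, B, "Aldob", "Fructolysis")

    # glycerolipid branch
    rxn("G3PD", {"dhap_c": -1, "g3p_c": 1}, 0, B, "Gpd1", "Glycerolipid metabolism")
    rxn("GPP", {"g3p_c": -1, "glyc_c": 1}, 0, B, "Pgp", "Glycerolipid metabolism")
    rxn("FACOA", {"fa_c": -1, "facoa_c": 1}, 0, B, "Acsl1", "Glycerolipid metabolism")
    rxn("GPAT", {"g3p_c": -1, "facoa_c": -3, "tag_c": 1}, 0, B,
        "Gpam or Gpat2", "Glycerolipid metabolism")

    # serine synthesis
    rxn("SERS", {"pg3_c": -1, "ser_c": 1}, 0, B, "Phgdh and Psat1", "Serine biosynthesis")

    # beta-oxidation (carnitine shuttle + lumped spiral)
    rxn("CPT", {"facoa_c": -1, "facoa_m": 1}, 0, B, "Cpt1a and Cpt2", "Beta oxidation")
    rxn("BOX", {"facoa_m": -1, "accoa_m": 8}, 0, B, "Acadl and Hadha", "Beta oxidation")

    # TCA cycle with O2-coupled oxidation
    rxn("PDH", {"pyr_m": -1, "o2_m": -0.5, "accoa_m": 1, "co2_m": 1}, 0, B, "Pdha1", "TCA cycle")
    rxn("CS", {"accoa_m": -1, "oaa_m": -1, "cit_m": 1}, 0, B, "Cs", "TCA cycle")
    rxn("IDH", {"cit_m": -1, "o2_m": -0.5, "akg_m": 1, "co2_m": 1}, 0, B, "Idh2", "TCA cycle")
    rxn("AKGDH", {"akg_m": -1, "o2_m": -0.5, "succ_m": 1, "co2_m": 1}, 0, B,
        "Ogdh and Dld", "TCA cycle")
    rxn("SUCOX", {"succ_m": -1, "o2_m": -1, "oaa_m": 1}, 0, B, "Sdha or Sdhb", "TCA cycle")
    rxn("PC", {"pyr_m": -1, "co2_m": -1, "oaa_m": 1}, 0, B, "Pcx", "TCA cycle")

    # amino acid catabolism
    rxn("AADA", {"aa_c": -1, "pyr_c": 1}, 0, B, "Gpt", "Amino acid metabolism")

    # biomass: drains carbohydrate, protein and lipid precursors (orphan)
    rxn("BIOMASS", {"g6p_c": -0.3, "aa_c": -2.0, "ser_c": -0.2, "tag_c": -0.1},
        0, B, "", "Biomass")
    m.objective = "BIOMASS"

    # optional blocked filler reactions, for size scaling only
    rng = np.random.default_rng(spec.seed)
    for i in range(spec.n_extra_reactions):
        c = int(rng.integers(1, 7))
        a_id, b_id = f"xm{i}a_c", f"xm{i}b_c"
        m.add_metabolite(_met(a_id, f"filler {i}a", "c", c))
        m.add_metabolite(_met(b_id, f"filler {i}b", "c", c))
        gid = f"Gx{i}"
        m.add_gene(Gene(id=gid, name="other"))
        rxn(f"XR{i}", {a_id: -1, b_id: 1}, -B, B, gid, "Miscellaneous")
    return m


def make_synthetic_diets() -> tuple[DietSpec, DietSpec]:
    """Fixed CD-like and WD-like diet fixtures (returned in that order)."""

    def entry(mid, pct, cls, mw, carbons):
        return DietEntry(metabolite_id=mid, percent_w_w=pct, component_class=cls,
                         molecular_weight=mw, carbons=carbons)

    cd = DietSpec(
        name="CD",
        entries=[
            entry("glc_e", 60.0, "carbohydrate", 180.156, 6),
            entry("fru_e", 0.0, "carbohydrate", 180.156, 6),
            entry("fa_e", 5.0, "lipid", 256.42, 16),
            entry("aa_e", 18.0, "amino_acid", 89.09, 3),
        ],
    )
    wd = DietSpec(
        name="WD",
        entries=[
            entry("glc_e", 30.0, "carbohydrate", 180.156, 6),
            entry("fru_e", 25.0, "carbohydrate", 180.156, 6),
            entry("fa_e", 20.0, "lipid", 256.42, 16),
            entry("aa_e", 15.0, "amino_acid", 89.09, 3),
        ],
    )
    return cd, wd


def make_synthetic_expression(
    model: MetabolicModel, seed: int = 0
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Seeded (T-like, PT-like) expression profiles for a pathway-tagged model.

    Per gene, the PT value is the pathway's base level times a log-normal
    factor; the T value is the PT value scaled by the pathway's tumor
    factor (beta-oxidation x0.25, lipid and serine synthesis x4), so the
    T/PT ratio is exact by construction.
    """
    rng = np.random.default_rng(seed)
    pt: dict[str, float] = {}
    t: dict[str, float] = {}
    for gid in sorted(model.genes):
        pathway = model.genes[gid].name or "other"
        base = _PATHWAY_BASE_EXPRESSION.get(pathway, _PATHWAY_BASE_EXPRESSION["other"])
        value = base * float(rng.lognormal(mean=0.0, sigma=_EXPRESSION_SIGMA))
        pt[gid] = value
        t[gid] = value * _T_SCALING.get(pathway, 1.0)
    return (
        ExpressionProfile(condition="T", values=t, unit="FPKM"),
        ExpressionProfile(condition="PT", values=pt, unit="FPKM"),
    )


def make_scenario(seed: int = 0) -> dict:
    """Assemble the full study-like synthetic scenario.

    Returns a dict with the toy model, CD/WD diets, T/PT expression
    profiles, the two expression-constrained models (with the forced CO2
    production standing in for respiration measurements), and the five
    standard diet plans of a composition-swap experiment.
    """
    model = make_toy_hepatic_model()
    cd, wd = make_synthetic_diets()
    expr_t, expr_pt = make_synthetic_expression(model, seed)
    co2_force: BoundMap = {"EX_co2": (CO2_FORCED_PRODUCTION, None)}
    model_t = apply_constraints(model, [eflux_bounds(model, expr_t), co2_force])
    model_t.id = "T"
    model_pt = apply_constraints(model, [eflux_bounds(model, expr_pt), co2_force])
    model_pt.id = "PT"
    return {
        "model": model,
        "cd": cd,
        "wd": wd,
        "expr_t": expr_t,
        "expr_pt": expr_pt,
        "model_t": model_t,
        "model_pt": model_pt,
        "plans": standard_plans(cd, wd),
    }


def standard_plans(cd: DietSpec, wd: DietSpec) -> list[SwapPlan]:
    """CD, WD, and the three canonical WD->CD component swaps."""
    return [
        SwapPlan(name="CD", base_diet=cd, reference_diet=cd),
        SwapPlan(name="WD", base_diet=wd, reference_diet=cd),
        SwapPlan(name="WD^lipid(CD)", base_diet=wd, reference_diet=cd,
                 swap_classes=("lipid",)),
        SwapPlan(name="WD^carbs(CD)", base_diet=wd, reference_diet=cd,
                 swap_classes=("carbohydrate",)),
        SwapPlan(name="WD^lipid,carbs(CD)", base_diet=wd, reference_diet=cd,
                 swap_classes=("lipid", "carbohydrate")),
    ]


def make_random_network(seed: int, max_reactions: int = 12) -> MetabolicModel:
    """Small random flux network for solver benchmarking.

    Metabolites carry no formulas; a few exchanges straddle zero so the
    all-zero flux vector is always feasible, every bound is finite so the
    LP is bounded, and a random internal reaction is the objective.
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(3, 7))
    model = MetabolicModel(id=f"random_{seed}")
    for i in range(n_mets):
        model.add_metabolite(Metabolite(id=f"m{i}", compartment="c", formula=None))
    n_exch = int(rng.integers(2, n_mets + 1))
    for i in range(n_exch):
        ub = float(rng.integers(1, 11))
        lb = -float(rng.integers(0, 11))
        model.add_reaction(Reaction(id=f"EX_m{i}", stoichiometry={f"m{i}": -1.0},
                                    lower_bound=lb, upper_bound=ub))
    n_internal = int(rng.integers(2, max(3, max_reactions - n_exch + 1)))
    for j in range(n_internal):
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        while n_sub + n_prod > n_mets:
            n_prod = max(1, n_prod - 1) if n_prod > 1 else n_prod
            n_sub = max(1, n_sub - 1)
        picks = rng.choice(n_mets, size=n_sub + n_prod, replace=False)
        stoich = {}
        for k, mi in enumerate(picks):
            coeff = float(rng.integers(1, 3))
            stoich[f"m{mi}"] = -coeff if k < n_sub else coeff
        reversible = rng.random() < 0.4
        model.add_reaction(Reaction(
            id=f"R{j}", stoichiometry=stoich,
            lower_bound=-10.0 if reversible else 0.0, upper_bound=10.0))
    obj = f"R{int(rng.integers(0, n_internal))}"
    model.objective = obj
    return model


def make_default_tasks() -> list[MetabolicTask]:
    """A small growth-task set for the toy hepatic model.

    Feasibility-only tasks in the usual style: each opens a few uptakes and
    demands a minimum production.  Fatty-acid oxidation needs a little
    glucose for anaplerotic oxaloacetate, as in the real liver.
    """
    return [
        MetabolicTask("glucose_oxidation",
                      [("glc_e", 10.0), ("o2_e", 100.0)], [("co2_e", 1.0)]),
        MetabolicTask("fructose_to_glycerol",
                      [("fru_e", 10.0)], [("glyc_e", 0.5)]),
        MetabolicTask("fatty_acid_oxidation",
                      [("fa_e", 5.0), ("glc_e", 1.0), ("o2_e", 100.0)],
                      [("co2_e", 20.0)]),
        MetabolicTask("succinate_production",
                      [("fa_e", 5.0), ("glc_e", 5.0), ("o2_e", 100.0)],
                      [("succ_e", 0.5), ("co2_e", 1.0)]),
        MetabolicTask("serine_synthesis", [("glc_e", 5.0)], [("ser_c", 1.0)]),
        MetabolicTask("lipid_precursor_synthesis",
                      [("fa_e", 5.0), ("glc_e", 5.0)], [("tag_c", 0.1)]),
    ]


def perturb_model(
    model: MetabolicModel, spec: ToySpec
) -> tuple[MetabolicModel, dict]:
    """Inject known curation flaws; returns (model, ground truth).

    * ``imbalanced``: dead-end conversions between fresh metabolites with
      unequal carbon counts.
    * ``duplicate``: exact copies of randomly chosen internal reactions
      under new ids (with their own isozyme gene).
    * ``inconsistent``: self-amplifying reactions X -> 2 X on a fresh
      zero-carbon metabolite, which no positive mass assignment satisfies.

    Flaw ids sort after the original reaction ids, so duplicate removal
    keeps the originals.
    """
    rng = np.random.default_rng(spec.seed)
    out = model.copy()
    truth = {"imbalanced": [], "duplicates": [], "inconsistent_metabolites": [],
             "inconsistent_reactions": []}

    n_imb = spec.flaw_counts.get("imbalanced", 0)
    for i in range(n_imb):
        ca = int(rng.integers(1, 7))
        cb = ca + int(rng.integers(1, 4))
        a_id, b_id = f"zflaw_imb{i}a_c", f"zflaw_imb{i}b_c"
        out.add_metabolite(_met(a_id, f"imbalance probe {i}a", "c", ca))
        out.add_metabolite(_met(b_id, f"imbalance probe {i}b", "c", cb))
        rid = f"ZFLAW_IMB_{i}"
        out.add_reaction(Reaction(id=rid, stoichiometry={a_id: -1, b_id: 1},
                                  lower_bound=0, upper_bound=1000,
                                  subsystem="Injected"))
        truth["imbalanced"].append(rid)

    internal = [
        r.id for r in model.reactions.values()
        if not r.is_exchange and r.id != model.objective
    ]
    n_dup = spec.flaw_counts.get("duplicate", 0)
    if n_dup > len(internal):
        raise ValueError("more duplicates requested than internal reactions")
    chosen = rng.choice(np.array(sorted(internal)), size=n_dup, replace=False)
    for i, src_id in enumerate(chosen):
        src = out.reactions[str(src_id)]
        dup = src.copy()
        dup.id = f"ZFLAW_DUP_{i}"
        gid = f"Gdup{i}"
        out.add_gene(Gene(id=gid, name="other"))
        dup.gr_rule = gid
        out.add_reaction(dup)
        truth["duplicates"].append((dup.id, str(src_id)))

    for i in range(spec.flaw_counts.get("inconsistent", 0)):
        x_id = f"zflaw_inc{i}_c"
        out.add_metabolite(_met(x_id, f"inconsistency probe {i}", "c", 0))
        rid = f"ZFLAW_INC_{i}"
        # X -> 2 X, written as its net stoichiometry with an explicit
        # internal flag so the consistency check does not treat it as an
        # exchange
        out.add_reaction(Reaction(id=rid, stoichiometry={x_id: 1.0},
                                  lower_bound=0, upper_bound=1000,
                                  subsystem="Injected", exchange=False))
        truth["inconsistent_metabolites"].append(x_id)
        truth["inconsistent_reactions"].append(rid)
    return out, truth
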