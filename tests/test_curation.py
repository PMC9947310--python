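"""ID mapping, merging, dedup, mass balance, pruning, consistency."""

import itertools

import numpy as np
import pytest

from sydicos import (
    MappingTable,
    MetabolicModel,
    MetabolicTask,
    Metabolite,
    Reaction,
    check_tasks,
    elemental_balance,
    fba,
    make_default_tasks,
    map_metabolite_ids,
    merge_models,
    prune_imbalanced,
    remove_duplicates,
    stoichiometric_consistency,
)
from sydicos.core_model import parse_formula


def _model(mets, rxns, objective=None):
    m = MetabolicModel(id="m")
    for mid, comp, formula in mets:
        m.add_metabolite(Metabolite(
            id=mid, compartment=comp,
            formula=None if formula is None else parse_formula(formula)))
    for rid, stoich, lb, ub in rxns:
        m.add_reaction(Reaction(id=rid, stoichiometry=stoich,
                                lower_bound=lb, upper_bound=ub))
    m.objective = objective
    return m


# ---------------------------------------------------------------------- mapping

def test_mapping_merges_same_compartment_collisions():
    m = _model(
        [("glcA_c", "c", "C6H12O6"), ("glcB_c", "c", "C6H12O6"), ("pyr_c", "c", "C3H4O3")],
        [("R1", {"glcA_c": -1, "pyr_c": 2}, 0, 10),
         ("R2", {"glcB_c": -1, "pyr_c": 2}, 0, 10)],
    )
    table = MappingTable(rows=[("m", "glcA_c", "C00031"), ("m", "glcB_c", "C00031")])
    out, report = map_metabolite_ids(m, table)
    assert "C00031_c" in out.metabolites
    assert len(out.metabolites) == 2
    assert out.reactions["R1"].stoichiometry == {"C00031_c": -1, "pyr_c": 2}
    assert [pair[0] for pair in report.merged] == ["C00031_c"]
    assert report.unmapped == ["pyr_c"]


def test_mapping_keeps_compartments_apart():
    m = _model(
        [("glc_c", "c", "C6H12O6"), ("glc_e", "e", "C6H12O6")],
        [("T", {"glc_e": -1, "glc_c": 1}, 0, 10)],
    )
    table = MappingTable(rows=[("m", "glc_c", "C00031"), ("m", "glc_e", "C00031")])
    out, report = map_metabolite_ids(m, table)
    assert {"C00031_c", "C00031_e"} <= set(out.metabolites)
    assert report.merged == []


def test_mapping_drops_net_zero_metabolite():
    m = _model(
        [("a_c", "c", "C"), ("b_c", "c", "C"), ("x_c", "c", "C2")],
        [("R", {"a_c": -1, "b_c": 1, "x_c": 1}, 0, 10)],
    )
    table = MappingTable(rows=[("m", "a_c", "K1"), ("m", "b_c", "K1")])
    out, report = map_metabolite_ids(m, table)
    assert out.reactions["R"].stoichiometry == {"x_c": 1}
    assert report.zeroed == [("R", "K1_c")]


# ----------------------------------------------------------------------- merge

def test_merge_disjoint_models_adds_counts():
    m1 = _model([("a_c", "c", "C")], [("R1", {"a_c": 1}, 0, 10)])
    m2 = _model([("b_c", "c", "C")], [("R2", {"b_c": 1}, 0, 10)])
    m2.id = "m2"
    merged, report = merge_models([m1, m2])
    assert len(merged.metabolites) == 2 and len(merged.reactions) == 2
    assert report.provenance["R1"] == ["m"] and report.provenance["R2"] == ["m2"]


def test_merge_self_then_dedup_is_identity(toy_model):
    merged, _ = merge_models([toy_model, toy_model])
    assert len(merged.reactions) == len(toy_model.reactions)
    deduped, report = remove_duplicates(merged)
    assert report.removed_duplicates == []
    assert set(deduped.reactions) == set(toy_model.reactions)


def test_merge_overlap_fraction():
    """50% shared metabolites between two toy source networks."""
    shared = [("s1_c", "c", "C"), ("s2_c", "c", "C")]
    m1 = _model(shared + [("a_c", "c", "C"), ("b_c", "c", "C")], [])
    m2 = _model(shared + [("x_c", "c", "C"), ("y_c", "c", "C")], [])
    inter = set(m1.metabolites) & set(m2.metabolites)
    union = set(m1.metabolites) | set(m2.metabolites)
    merged, _ = merge_models([m1, m2])
    assert set(merged.metabolites) == union
    assert len(inter) / len(m1.metabolites) == pytest.approx(0.5)


# ------------------------------------------------------------------ duplicates

def test_duplicate_reactions_collapse_with_or_rule():
    m = _model([("a_c", "c", "C"), ("b_c", "c", "C")],
               [("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                ("R2", {"a_c": -1, "b_c": 1}, 0, 20)])
    m.reactions["R1"].gr_rule = "g1"
    m.reactions["R2"].gr_rule = "g2"
    out, report = remove_duplicates(m)
    assert list(out.reactions) == ["R1"]
    assert report.removed_duplicates == [("R2", "R1")]
    assert out.reactions["R1"].gr_rule == "(g1) or (g2)"
    assert out.reactions["R1"].upper_bound == 20  # widest bounds kept


def test_reverse_duplicates_of_reversible_reactions():
    m = _model([("a_c", "c", "C"), ("b_c", "c", "C")],
               [("F", {"a_c": -1, "b_c": 1}, -10, 10),
                ("B", {"b_c": -1, "a_c": 1}, -5, 20)])
    out, report = remove_duplicates(m)
    assert list(out.reactions) == ["F"]
    assert report.removed_duplicates == [("B", "F")]
    # flipped bounds (-5, 20) become (-20, 5); widest union is (-20, 10)
    assert out.reactions["F"].lower_bound == -20
    assert out.reactions["F"].upper_bound == 10


def test_different_stoichiometry_not_duplicates():
    m = _model([("a_c", "c", "C"), ("b_c", "c", "C")],
               [("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                ("R2", {"a_c": -1, "b_c": 2}, 0, 10)])
    out, _ = remove_duplicates(m)
    assert len(out.reactions) == 2


def test_dedup_idempotent_and_biomass_invariant(toy_model):
    once, _ = remove_duplicates(toy_model)
    twice, report = remove_duplicates(once)
    assert report.removed_duplicates == []
    assert fba(once).objective_value == pytest.approx(
        fba(toy_model).objective_value, abs=1e-6)


# ------------------------------------------------------------- elemental balance

def test_balanced_glycolysis_stub():
    m = _model([("glc_c", "c", "C6H12O6"), ("lac_c", "c", "C3H6O3")],
               [("R", {"glc_c": -1, "lac_c": 2}, 0, 10)])
    res = elemental_balance(m.reactions["R"], m.metabolites)
    assert res.status == "balanced"
    assert all(v == 0 for v in res.imbalance.values())


def test_carbon_imbalance_signed():
    m = _model([("glc_c", "c", "C6H12O6"), ("pyr_c", "c", "C3H4O3")],
               [("R", {"glc_c": -1, "pyr_c": 1}, 0, 10)])
    res = elemental_balance(m.reactions["R"], m.metabolites)
    assert res.status == "imbalanced"
    assert res.imbalance["C"] == -3
    assert res.imbalance["O"] == -3


def test_formulaless_metabolite_is_undetermined():
    m = _model([("a_c", "c", None), ("b_c", "c", "C")],
               [("R", {"a_c": -1, "b_c": 1}, 0, 10)])
    assert elemental_balance(m.reactions["R"], m.metabolites).status == "undetermined"


def test_exchange_reactions_skipped():
    m = _model([("a_e", "e", "C")], [("EX", {"a_e": -1}, -10, 10)])
    assert elemental_balance(m.reactions["EX"], m.metabolites).status == "exchange"


@pytest.mark.parametrize("k", [2.0, 0.5, 7.0])
def test_imbalance_scales_with_reaction(k):
    m = _model([("glc_c", "c", "C6H12O6"), ("pyr_c", "c", "C3H4O3")],
               [("R", {"glc_c": -1, "pyr_c": 1}, 0, 10)])
    base = elemental_balance(m.reactions["R"], m.metabolites).imbalance
    m.reactions["R"].stoichiometry = {
        mid: k * c for mid, c in m.reactions["R"].stoichiometry.items()}
    scaled = elemental_balance(m.reactions["R"], m.metabolites).imbalance
    for el in base:
        assert scaled[el] == pytest.approx(k * base[el])


# ----------------------------------------------------------------------- tasks

def test_toy_model_passes_default_tasks(toy_model):
    results = check_tasks(toy_model, make_default_tasks())
    assert all(r.passed for r in results.values()), {
        k: str(v) for k, v in results.items() if not v.passed}


def test_task_with_unknown_metabolite_fails_with_reason(toy_model):
    task = MetabolicTask("bad", [("nope_e", 10.0)], [("co2_e", 1.0)])
    res = check_tasks(toy_model, [task])["bad"]
    assert not res.passed and "unknown metabolite" in res.reason


def test_unreachable_output_fails(toy_model):
    task = MetabolicTask("impossible", [("glc_e", 10.0)], [("fa_e", 1.0)])
    assert not check_tasks(toy_model, [task])["impossible"].passed


def test_empty_task_list(toy_model):
    assert check_tasks(toy_model, []) == {}


# --------------------------------------------------------------------- pruning

def test_prune_removes_imbalanced_dead_end(toy_model):
    m = toy_model.copy()
    m.add_metabolite(Metabolite(id="junk_c", compartment="c", formula={"C": 9}))
    m.add_reaction(Reaction(id="BADRXN", stoichiometry={"pyr_c": -1, "junk_c": 1},
                            lower_bound=0, upper_bound=10))
    pruned, report = prune_imbalanced(m, make_default_tasks())
    assert report.pruned == ["BADRXN"]
    assert "BADRXN" not in pruned.reactions
    assert fba(pruned).objective_value == pytest.approx(
        fba(toy_model).objective_value, rel=1e-6)


def test_prune_retains_essential_imbalanced_reaction():
    """An imbalanced reaction on the sole biomass route must be kept."""
    m = _model(
        [("a_e", "e", "C2"), ("a_c", "c", "C2"), ("b_c", "c", "C3")],
        [("EX_a", {"a_e": -1}, -10, 0),
         ("T", {"a_e": -1, "a_c": 1}, 0, 100),
         ("BAD", {"a_c": -1, "b_c": 1}, 0, 100),  # C2 -> C3, imbalanced
         ("BIO", {"b_c": -1}, 0, 100)],
        objective="BIO",
    )
    pruned, report = prune_imbalanced(m, [])
    assert report.retained_flagged == ["BAD"]
    assert report.pruned == []
    assert "BAD" in pruned.reactions


def test_prune_noop_without_imbalance(toy_model):
    pruned, report = prune_imbalanced(toy_model, [])
    assert report.imbalanced == [] and report.pruned == []
    assert set(pruned.reactions) == set(toy_model.reactions)


def test_prune_requires_feasible_start(toy_model):
    m = toy_model.copy()
    m.reactions["BIOMASS"].lower_bound = 1e6  # impossible demand
    with pytest.raises(ValueError, match="optimal biomass"):
        prune_imbalanced(m, [])


# ----------------------------------------------------------- consistency

def test_reversible_pair_consistent():
    m = _model([("a_c", "c", None), ("b_c", "c", None)],
               [("R", {"a_c": -1, "b_c": 1}, -10, 10)])
    assert stoichiometric_consistency(m) == set()


def test_self_amplifying_metabolite_inconsistent():
    m = _model([("a_c", "c", None)], [])
    m.add_reaction(Reaction(id="R", stoichiometry={"a_c": 1.0},
                            lower_bound=0, upper_bound=10, exchange=False))
    assert stoichiometric_consistency(m) == {"a_c"}


def test_exchange_only_model_consistent():
    m = _model([("a_e", "e", None)], [("EX", {"a_e": -1}, -10, 10)])
    assert stoichiometric_consistency(m) == set()


def test_toy_model_is_consistent(toy_model):
    assert stoichiometric_consistency(toy_model) == set()


def _brute_force_inconsistent(model):
    """Per-metabolite LP oracle: maximize m_i over the mass cone."""
    import scipy.sparse as sp
    from scipy.optimize import linprog

    internal = [r for r in model.reactions.values()
                if not r.is_exchange and r.id != model.objective]
    met_ids = list(model.metabolites)
    idx = {m: i for i, m in enumerate(met_ids)}
    rows = []
    for r in internal:
        row = np.zeros(len(met_ids))
        for mid, c in r.stoichiometry.items():
            row[idx[mid]] = c
        rows.append(row)
    A = np.array(rows) if rows else np.zeros((0, len(met_ids)))
    bad = set()
    for i, mid in enumerate(met_ids):
        c = np.zeros(len(met_ids))
        c[i] = -1.0
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]),
                      bounds=[(0, 1)] * len(met_ids), method="highs")
        if res.status != 0 or -res.fun < 1e-9:
            bad.add(mid)
    return bad


@pytest.mark.parametrize("seed", range(8))
def test_consistency_matches_per_metabolite_oracle(seed):
    """Joint LP agrees with an independent per-metabolite formulation."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 7))
    m = _model([(f"m{i}", "c", None) for i in range(n)], [])
    for j in range(int(rng.integers(2, 6))):
        picks = rng.choice(n, size=2, replace=False)
        coeffs = rng.integers(1, 4, size=2)
        m.add_reaction(Reaction(
            id=f"R{j}",
            stoichiometry={f"m{picks[0]}": -float(coeffs[0]),
                           f"m{picks[1]}": float(coeffs[1])},
            lower_bound=-10, upper_bound=10))
    if rng.random() < 0.5:
        m.add_reaction(Reaction(id="RAUTO", stoichiometry={"m0": 1.0},
                                lower_bound=0, upper_bound=10, exchange=False))
    assert stoichiometric_consistency(m) == _brute_force_inconsistent(m)
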