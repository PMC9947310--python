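"""Diet, gas and expression bound construction; carbon accounting."""

import pytest

from sydicos import (
    DietEntry,
    DietSpec,
    ExpressionProfile,
    GasExchangeSpec,
    MetabolicTask,
    apply_constraints,
    carbon_flux,
    classify_expression,
    diet_bounds,
    eflux_bounds,
    expression_gate_extraction,
    gas_bounds,
    make_toy_hepatic_model,
    split_pooled_components,
    uptake_bound_mmol,
)
from sydicos.constraints import DEFAULT_INTAKE_G


def _entry(mid, pct, cls="carbohydrate", mw=180.156, c=6):
    return DietEntry(metabolite_id=mid, percent_w_w=pct, component_class=cls,
                     molecular_weight=mw, carbons=c)


# ------------------------------------------------------------------ diet bounds

def test_glucose_worked_example():
    """10 % w/w glucose at 3 g/day: 0.10*3/180.156*1000 = 1.6652 mmol/day."""
    b = uptake_bound_mmol(10.0, 3.0, 180.156)
    assert b == pytest.approx(1.6652, abs=5e-5)


def test_default_intake_is_three_grams():
    diet = DietSpec(name="d", entries=[_entry("glc_e", 10.0)])
    assert diet.intake_W == DEFAULT_INTAKE_G == 3.0


def test_diet_bounds_cap_uptake_only():
    diet = DietSpec(name="d", entries=[_entry("glc_e", 10.0), _entry("fru_e", 0.0)])
    bounds = diet_bounds(diet, {"glc_e": "EX_glc", "fru_e": "EX_fru"})
    lo, hi = bounds["EX_glc"]
    assert lo == pytest.approx(-1.6652, abs=5e-5)
    assert hi is None  # secretion side untouched
    assert bounds["EX_fru"] == (0.0, None)  # absent nutrient: no uptake


def test_diet_bounds_missing_exchange_lists_metabolites():
    diet = DietSpec(name="d", entries=[_entry("glc_e", 10.0)])
    with pytest.raises(KeyError, match="glc_e"):
        diet_bounds(diet, {})


def test_diet_bounds_linear_in_intake_and_percent():
    diet = DietSpec(name="d", entries=[_entry("glc_e", 10.0)])
    exch = {"glc_e": "EX_glc"}
    b1 = diet_bounds(diet, exch)["EX_glc"][0]
    doubled = diet.copy()
    doubled.intake_W *= 2
    assert diet_bounds(doubled, exch)["EX_glc"][0] == pytest.approx(2 * b1)
    richer = DietSpec(name="d", entries=[_entry("glc_e", 20.0)])
    assert diet_bounds(richer, exch)["EX_glc"][0] == pytest.approx(2 * b1)


# ------------------------------------------------------------------- pool splits

def test_saturated_fa_pool_split_equally():
    """An 8 % saturated-FA pool over 4 members gives 2 % each."""
    diet = DietSpec(name="d", entries=[
        _entry("satfa_pool", 8.0, cls="lipid", mw=250.0, c=16)])
    members = [_entry(m, 0.0, cls="lipid", mw=mw, c=c) for m, mw, c in [
        ("palmitate", 256.4, 16), ("stearate", 284.5, 18),
        ("myristate", 228.4, 14), ("laurate", 200.3, 12)]]
    out = split_pooled_components(diet, {"satfa_pool": members})
    assert {e.metabolite_id for e in out.entries} == {
        "palmitate", "stearate", "myristate", "laurate"}
    assert all(e.percent_w_w == pytest.approx(2.0) for e in out.entries)
    assert all(e.component_class == "lipid" for e in out.entries)


def test_monounsaturated_pool_three_members():
    diet = DietSpec(name="d", entries=[
        _entry("mufa_pool", 6.0, cls="lipid", mw=282.0, c=18)])
    members = [_entry(m, 0.0, cls="lipid", mw=282.0, c=18)
               for m in ("eicosenoate", "octadecenoate", "palmitoleate")]
    out = split_pooled_components(diet, {"mufa_pool": members})
    assert all(e.percent_w_w == pytest.approx(2.0) for e in out.entries)


def test_split_without_pools_is_identity():
    diet = DietSpec(name="d", entries=[_entry("glc_e", 10.0)])
    out = split_pooled_components(diet, {})
    assert [e.metabolite_id for e in out.entries] == ["glc_e"]
    assert out.entries[0].percent_w_w == 10.0


def test_split_empty_member_list_rejected():
    diet = DietSpec(name="d", entries=[_entry("pool", 8.0)])
    with pytest.raises(ValueError, match="no members"):
        split_pooled_components(diet, {"pool": []})


# ------------------------------------------------------------------- gas bounds

def test_oxygen_worked_example():
    """p=1.429 g/L, V=1 L/day, M=31.998: 44.66 mmol/day minimum uptake."""
    spec = GasExchangeSpec(gas="O2", density_p=1.429, volume_V=1.0,
                           molecular_weight_M=31.998)
    bounds = gas_bounds(spec, "EX_o2", direction="uptake")
    lo, hi = bounds["EX_o2"]
    assert lo is None
    assert hi == pytest.approx(-44.66, abs=5e-3)


def test_co2_production_direction():
    spec = GasExchangeSpec(gas="CO2", density_p=1.977, volume_V=1.0,
                           molecular_weight_M=44.01)
    bounds = gas_bounds(spec, "EX_co2", direction="production")
    lo, hi = bounds["EX_co2"]
    assert lo == pytest.approx(1.977 / 44.01 * 1000, rel=1e-9)
    assert hi is None


def test_zero_volume_zero_bound():
    spec = GasExchangeSpec(gas="O2", density_p=1.429, volume_V=0.0,
                           molecular_weight_M=31.998)
    assert gas_bounds(spec, "EX_o2")["EX_o2"][1] == pytest.approx(0.0)


# ---------------------------------------------------------------- carbon moles

def test_carbon_flux_weighted_sum():
    assert carbon_flux({"glc": 2.0}, {"glc": 6}) == 12.0
    assert carbon_flux({}, {}) == 0.0


def test_carbon_flux_missing_carbons_raises():
    with pytest.raises(KeyError, match="glc"):
        carbon_flux({"glc": 2.0}, {})


def test_carbon_flux_additive_over_disjoint_sets():
    a = {"glc": 2.0}
    b = {"fa": 1.0}
    carbons = {"glc": 6, "fa": 16}
    assert carbon_flux(a | b, carbons) == pytest.approx(
        carbon_flux(a, carbons) + carbon_flux(b, carbons))


def test_diet_carbon_moles_matches_spreadsheet_sum(diets):
    """Independent per-entry arithmetic over the CD fixture."""
    from sydicos import diet_carbon_moles

    cd, _ = diets
    expected = sum(e.carbons * (e.percent_w_w / 100 * cd.intake_W
                                / e.molecular_weight * 1000)
                   for e in cd.entries)
    assert diet_carbon_moles(cd) == pytest.approx(expected, rel=1e-12)


# --------------------------------------------------------------------- E-flux

def test_eflux_or_sum_and_reversibility(toy_model):
    expr = ExpressionProfile(condition="x", values={"Sdha": 5.0, "Sdhb": 7.0,
                                                    "Tpi1": 3.0})
    bounds = eflux_bounds(toy_model, expr)
    assert bounds["SUCOX"] == (0.0, 12.0)  # irreversible, OR-sum
    assert bounds["TPI"] == (-3.0, 3.0)  # reversible: symmetric


def test_eflux_and_min(toy_model):
    expr = ExpressionProfile(condition="x", values={"Cpt1a": 9.0, "Cpt2": 4.0})
    assert eflux_bounds(toy_model, expr)["CPT"] == (0.0, 4.0)


def test_eflux_orphans_and_exchanges_untouched(toy_model):
    expr = ExpressionProfile(condition="x", values={"Gck": 5.0})
    bounds = eflux_bounds(toy_model, expr)
    assert "BIOMASS" not in bounds  # orphan: kept unconstrained
    assert "EX_glc" not in bounds
    assert "O2tc" not in bounds  # orphan transport


def test_eflux_unmeasured_gene_blocks_sole_catalyst(toy_model):
    bounds = eflux_bounds(toy_model, ExpressionProfile(condition="x", values={}))
    assert bounds["HEX"] == (0.0, 0.0)


def test_eflux_monotone_in_expression(toy_model):
    lo = eflux_bounds(toy_model, ExpressionProfile(
        condition="x", values={"Sdha": 5.0, "Cpt1a": 2.0, "Cpt2": 8.0}))
    hi = eflux_bounds(toy_model, ExpressionProfile(
        condition="x", values={"Sdha": 9.0, "Cpt1a": 2.5, "Cpt2": 8.0}))
    for rid in lo:
        assert hi[rid][1] >= lo[rid][1]
        assert hi[rid][0] <= lo[rid][0]


# -------------------------------------------------------------- classification

@pytest.mark.parametrize("value,expected", [
    (50.0, "high"), (120.0, "high"),
    (10.0, "medium"), (49.999, "medium"),
    (1.0, "low"), (9.999, "low"),
    (0.5, "none"), (0.0, "none"),
])
def test_fpkm_bins(value, expected):
    assert classify_expression(value) == expected


def test_negative_expression_rejected():
    with pytest.raises(ValueError):
        classify_expression(-0.1)


# ----------------------------------------------------------- constraint layers

def test_apply_empty_layers_is_identity(toy_model):
    out = apply_constraints(toy_model, [])
    assert {r.id: (r.lower_bound, r.upper_bound) for r in out.reactions.values()} == \
        {r.id: (r.lower_bound, r.upper_bound) for r in toy_model.reactions.values()}


def test_later_layer_wins(toy_model):
    out = apply_constraints(toy_model, [{"HEX": (0.0, 5.0)}, {"HEX": (0.0, 2.0)}])
    assert out.reactions["HEX"].upper_bound == 2.0


def test_layers_never_widen_irreversibility(toy_model):
    out = apply_constraints(toy_model, [{"HEX": (-7.0, 7.0)}])
    assert out.reactions["HEX"].lower_bound == 0.0  # structurally irreversible


def test_conflicting_bounds_raise(toy_model):
    with pytest.raises(ValueError, match="HEX"):
        apply_constraints(toy_model, [{"HEX": (5.0, 2.0)}])


def test_input_model_untouched(toy_model):
    before = toy_model.reactions["HEX"].upper_bound
    apply_constraints(toy_model, [{"HEX": (0.0, 1.0)}])
    assert toy_model.reactions["HEX"].upper_bound == before


# --------------------------------------------------------- gated extraction

def test_extraction_keeps_expressed_model_unchanged(toy_model):
    from sydicos import make_default_tasks

    expr = ExpressionProfile(condition="x",
                             values={g: 10.0 for g in toy_model.genes})
    out = expression_gate_extraction(toy_model, expr, make_default_tasks())
    assert set(out.reactions) == set(toy_model.reactions)


def test_extraction_removes_unexpressed_dead_end():
    from sydicos import Gene, Metabolite, Reaction, make_default_tasks

    m = make_toy_hepatic_model()
    m.add_metabolite(Metabolite(id="dead_c", compartment="c", formula={"C": 3}))
    m.add_gene(Gene(id="Gdead", name="other"))
    m.add_reaction(Reaction(id="DEADRXN", stoichiometry={"pyr_c": -1, "dead_c": 1},
                            lower_bound=0, upper_bound=10, gr_rule="Gdead"))
    expr = ExpressionProfile(
        condition="x", values={g: 10.0 for g in m.genes} | {"Gdead": 0.2})
    out = expression_gate_extraction(m, expr, make_default_tasks())
    assert "DEADRXN" not in out.reactions


def test_extraction_reinstates_task_essential_reaction(toy_model):
    """KHK is the only fructolysis entry; unexpressed, it must come back."""
    from sydicos import make_default_tasks

    expr = ExpressionProfile(
        condition="x", values={g: 10.0 for g in toy_model.genes} | {"Khk": 0.0})
    out = expression_gate_extraction(toy_model, expr, make_default_tasks())
    assert "KHK" in out.reactions  # fructose_to_glycerol task needs it
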