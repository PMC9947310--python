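"""Condition-specific flux bounds from diet, gas exchange, and expression.

Three constraint layers turn measurements into reaction bounds
(mmol/mouse/day):

* **Diet**: each nutrient's maximum uptake is ``b = (P/100 · W / M) · 1000``
  where P is its % w/w in the diet, W the grams of food eaten per mouse per
  day (default 3 g), and M its molecular weight in g/mol.  The bound caps
  the uptake direction of the nutrient's exchange reaction; the model is
  free to take less, and secretion stays open.
* **Respiratory gas exchange**: metabolic-cage volume rates are converted
  with ``b = p·V/M · 1000`` (p density g/L, V litres/mouse/day) and imposed
  as a *minimum* on the measured direction (O2 consumption or CO2
  production).
* **Gene expression (adapted E-flux)**: a reaction's bound magnitude is its
  GPR rule folded over mean per-gene expression — isozymes (OR) sum, complex
  subunits (AND) take the minimum.  Irreversible reactions get (0, b),
  reversible ones (−b, +b); orphan reactions and exchanges are left
  unconstrained.

Carbon-mole accounting multiplies each flux or bound by the metabolite's
carbon count, giving the C_moles totals used to compare diets and flux
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core_model import MetabolicModel
from .curation import MetabolicTask, check_tasks
from .fba import SolverOptions, fba
from .gpr import evaluate_gpr, gpr_genes, parse_gpr

COMPONENT_CLASSES = ("carbohydrate", "lipid", "amino_acid", "other")

#: grams of food consumed per mouse per day, the study default
DEFAULT_INTAKE_G = 3.0


@dataclass
class DietEntry:
    metabolite_id: str
    percent_w_w: float
    component_class: str
    molecular_weight: float  # g/mol
    carbons: int

    def __post_init__(self) -> None:
        if self.percent_w_w < 0:
            raise ValueError(f"{self.metabolite_id}: negative percent_w_w")
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.metabolite_id}: molecular_weight must be positive")
        if self.component_class not in COMPONENT_CLASSES:
            raise ValueError(
                f"{self.metabolite_id}: unknown component class {self.component_class!r}"
            )


@dataclass
class DietSpec:
    name: str
    entries: list[DietEntry]
    intake_W: float = DEFAULT_INTAKE_G  # g food / mouse / day

    def __post_init__(self) -> None:
        total = sum(e.percent_w_w for e in self.entries)
        if total > 100 + 1e-9:
            raise ValueError(f"diet {self.name}: percent_w_w sums to {total} > 100")

    def entry(self, metabolite_id: str) -> DietEntry | None:
        for e in self.entries:
            if e.metabolite_id == metabolite_id:
                return e
        return None

    def copy(self) -> "DietSpec":
        return DietSpec(
            name=self.name,
            entries=[replace(e) for e in self.entries],
            intake_W=self.intake_W,
        )


@dataclass
class GasExchangeSpec:
    gas: str  # O2 | CO2
    density_p: float  # g/L
    volume_V: float  # L / mouse / day
    molecular_weight_M: float  # g/mol

    def __post_init__(self) -> None:
        if self.gas not in ("O2", "CO2"):
            raise ValueError(f"unknown gas {self.gas!r}")
        if self.density_p <= 0 or self.molecular_weight_M <= 0 or self.volume_V < 0:
            raise ValueError("gas spec values must be positive")


@dataclass
class ExpressionProfile:
    condition: str
    values: dict[str, float]  # gene id -> mean expression across replicates
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        bad = [g for g, v in self.values.items() if v < 0]
        if bad:
            raise ValueError(f"negative expression for genes {bad}")


#: reaction id -> (lower or None, upper or None); None leaves that side as-is
BoundMap = dict[str, tuple[float | None, float | None]]


def uptake_bound_mmol(percent_w_w: float, intake_W: float, molecular_weight: float) -> float:
    """Diet uptake bound b = (P/100 · W / M) · 1000 mmol/mouse/day."""
    return percent_w_w / 100.0 * intake_W / molecular_weight * 1000.0


def diet_bounds(diet: DietSpec, exchange_map: dict[str, str]) -> BoundMap:
    """Maximum-uptake bounds for every diet nutrient's exchange reaction.

    With the convention that positive exchange flux secretes, uptake of up
    to b means a lower bound of −b; the upper (secretion) bound is left
    untouched and the model may always take up less than b.
    """
    missing = [e.metabolite_id for e in diet.entries if e.metabolite_id not in exchange_map]
    if missing:
        raise KeyError(f"no exchange reaction for diet metabolites: {', '.join(missing)}")
    out: BoundMap = {}
    for e in diet.entries:
        b = uptake_bound_mmol(e.percent_w_w, diet.intake_W, e.molecular_weight)
        out[exchange_map[e.metabolite_id]] = (-b, None)
    return out


def split_pooled_components(
    diet: DietSpec,
    split_rules: dict[str, list[DietEntry]],
) -> DietSpec:
    """Divide pooled diet entries (e.g. "saturated FAs") among members.

    Each pool's % w/w is split equally across its member metabolites, which
    inherit the pool's component class; the pool entry is removed.  Members
    are given as :class:`DietEntry` templates carrying their own molecular
    weight and carbon count (percent_w_w on the template is ignored).
    """
    out_entries: list[DietEntry] = []
    for e in diet.entries:
        if e.metabolite_id not in split_rules:
            out_entries.append(replace(e))
            continue
        members = split_rules[e.metabolite_id]
        if not members:
            raise ValueError(f"pool {e.metabolite_id} has no members")
        share = e.percent_w_w / len(members)
        for m in members:
            out_entries.append(
                DietEntry(
                    metabolite_id=m.metabolite_id,
                    percent_w_w=share,
                    component_class=e.component_class,
                    molecular_weight=m.molecular_weight,
                    carbons=m.carbons,
                )
            )
    return DietSpec(name=diet.name, entries=out_entries, intake_W=diet.intake_W)


def gas_bounds(
    spec: GasExchangeSpec,
    reaction_id: str,
    direction: str = "uptake",
) -> BoundMap:
    """Minimum-rate bound from a gas-exchange measurement, b = p·V/M · 1000.

    ``direction="uptake"`` forces at least b of uptake (exchange flux
    <= −b, e.g. O2 consumption); ``direction="production"`` forces at least
    b of secretion (exchange flux >= b, e.g. CO2 production).
    """
    b = spec.density_p * spec.volume_V / spec.molecular_weight_M * 1000.0
    if direction == "uptake":
        return {reaction_id: (None, -b)}
    if direction == "production":
        return {reaction_id: (b, None)}
    raise ValueError(f"direction must be 'uptake' or 'production', got {direction!r}")


def carbon_flux(values: dict[str, float], carbons: dict[str, int]) -> float:
    """Carbon-weighted total, C_moles = Σ_j C_j·v_j (mmol C/day)."""
    total = 0.0
    for mid, v in values.items():
        if v == 0:
            continue
        if mid not in carbons or carbons[mid] is None:
            raise KeyError(f"carbon count unknown for metabolite {mid}")
        total += carbons[mid] * v
    return total


def diet_carbon_moles(diet: DietSpec, component_class: str | None = None) -> float:
    """C_moles available from a diet, optionally for one component class."""
    return sum(
        e.carbons * uptake_bound_mmol(e.percent_w_w, diet.intake_W, e.molecular_weight)
        for e in diet.entries
        if component_class is None or e.component_class == component_class
    )


def eflux_bounds(model: MetabolicModel, expr: ExpressionProfile) -> BoundMap:
    """Adapted E-flux bounds from a GPR fold over mean expression.

    Unmeasured genes contribute 0 at their leaf.  Orphan reactions (empty
    GPR) and exchange reactions get no entry and keep their existing
    bounds.
    """
    out: BoundMap = {}
    for rxn in model.reactions.values():
        if not rxn.gr_rule or rxn.is_exchange:
            continue
        try:
            tree = parse_gpr(rxn.gr_rule)
        except ValueError as exc:
            raise ValueError(f"reaction {rxn.id}: malformed gr_rule: {exc}") from exc
        b = float(evaluate_gpr(tree, expr.values, missing=0.0))
        if rxn.reversible:
            out[rxn.id] = (-b, b)
        else:
            out[rxn.id] = (0.0, b)
    return out


def classify_expression(value: float) -> str:
    """Bin an FPKM value: high >=50, medium [10,50), low [1,10), none <1."""
    if value < 0:
        raise ValueError(f"negative expression value {value}")
    if value >= 50:
        return "high"
    if value >= 10:
        return "medium"
    if value >= 1:
        return "low"
    return "none"


def apply_constraints(
    model: MetabolicModel, layers: list[BoundMap]
) -> MetabolicModel:
    """Apply bound layers to a copy of the model; later layers win.

    Structural irreversibility is preserved: a reaction irreversible in the
    input model never receives a lower bound below zero.  A final lower >
    upper conflict raises, naming the reaction.
    """
    out = model.copy()
    for layer in layers:
        for rid, (lo, hi) in layer.items():
            if rid not in out.reactions:
                raise KeyError(f"bound layer names unknown reaction {rid}")
            rxn = out.reactions[rid]
            structural_lo = model.reactions[rid].lower_bound
            if lo is not None:
                rxn.lower_bound = max(lo, 0.0) if structural_lo >= 0 else lo
            if hi is not None:
                rxn.upper_bound = hi
    bad = [
        r.id for r in out.reactions.values() if r.lower_bound > r.upper_bound + 1e-12
    ]
    if bad:
        raise ValueError(f"conflicting bounds (lower > upper) for reactions: {bad}")
    return out


def expression_gate_extraction(
    model: MetabolicModel,
    expr: ExpressionProfile,
    tasks: list[MetabolicTask],
    options: SolverOptions | None = None,
) -> MetabolicModel:
    """Simplified expression-gated model extraction.

    Removes reactions whose every associated gene is unexpressed
    (FPKM < 1, class "none"), then greedily reinstates removed reactions in
    id-sorted order until all tasks pass and biomass is feasible.  This is a
    deliberately simple extraction heuristic, not the task-driven MILP
    (tINIT) used to build published tissue models.
    """
    options = options or SolverOptions()
    baseline = check_tasks(model, tasks, options)
    if not all(r.passed for r in baseline.values()) or fba(model, options).status != "optimal":
        raise ValueError("input model does not satisfy the tasks / biomass")

    removable = []
    for rxn in model.reactions.values():
        if not rxn.gr_rule or rxn.is_exchange:
            continue
        genes = gpr_genes(parse_gpr(rxn.gr_rule))
        if all(classify_expression(expr.values.get(g, 0.0)) == "none" for g in genes):
            removable.append(rxn.id)

    work = model.copy()
    for rid in removable:
        del work.reactions[rid]

    def satisfied(m: MetabolicModel) -> bool:
        if fba(m, options).status != "optimal":
            return False
        return all(r.passed for r in check_tasks(m, tasks, options).values())

    for rid in sorted(removable):
        if satisfied(work):
            break
        work.add_reaction(model.reactions[rid].copy())
    if not satisfied(work):  # pragma: no cover - full model satisfies by pre-check
        raise RuntimeError("tasks unsatisfiable even after reinstating all reactions")
    return work
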