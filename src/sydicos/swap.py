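"""Systematic Diet Composition Swap (SyDiCoS) and differential-flux analytics.

A *swap* replaces the content of one or more nutrient component classes
(carbohydrates, lipids, amino acids) of a base diet with the corresponding
content of a reference diet, leaving the rest of the base composition
unchanged.  Running the same expression-constrained model under the base
diet and under its swapped variants, and comparing the resulting
parsimonious flux distributions, attributes flux differences to specific
diet components.  The comparison toolkit: Euclidean distances between flux
vectors (optionally normalized to the maximum pairwise distance),
reaction-wise flux ratios, carbon influx/efflux accounting over the
exchange reactions, per-subsystem "reaction ratios" (the fraction of
flux-carrying reactions higher in one condition), and extraction of a
biomass-connected differential subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .constraints import BoundMap, DietSpec, apply_constraints, diet_bounds, eflux_bounds
from .core_model import FluxDistribution, MetabolicModel
from .fba import SolverOptions, pfba

SWAPPABLE_CLASSES = ("carbohydrate", "lipid", "amino_acid")

#: metabolite base names treated as currency for connectivity purposes
DEFAULT_CURRENCY = ("h2o", "h", "atp", "adp", "nad", "nadh", "co2", "pi")


@dataclass
class SwapPlan:
    name: str
    base_diet: DietSpec
    reference_diet: DietSpec
    swap_classes: tuple[str, ...] = ()
    sugar_restriction: tuple[str, ...] | None = None  # metabolite ids to retain

    def __post_init__(self) -> None:
        for c in self.swap_classes:
            if c not in SWAPPABLE_CLASSES:
                raise ValueError(f"cannot swap component class {c!r}")

    def effective_diet(self) -> DietSpec:
        diet = swap_diet(self)
        if self.sugar_restriction is not None:
            diet = restrict_sugars(diet, self.sugar_restriction)
        return diet


def swap_diet(plan: SwapPlan) -> DietSpec:
    """Build the swapped diet for a plan.

    For every metabolite whose class is being swapped, the % w/w is taken
    from the reference diet (0 if absent there), and swapped-class
    metabolites present only in the reference are added; everything else
    keeps its base value.  Daily intake stays the base diet's.
    """
    base, ref = plan.base_diet, plan.reference_diet
    for e in base.entries:
        r = ref.entry(e.metabolite_id)
        if r is not None and r.component_class != e.component_class:
            raise ValueError(
                f"metabolite {e.metabolite_id} has class {e.component_class!r} in "
                f"{base.name} but {r.component_class!r} in {ref.name}"
            )
    entries = []
    for e in base.entries:
        if e.component_class in plan.swap_classes:
            r = ref.entry(e.metabolite_id)
            entries.append(replace(e, percent_w_w=r.percent_w_w if r else 0.0))
        else:
            entries.append(replace(e))
    base_ids = {e.metabolite_id for e in base.entries}
    for r in ref.entries:
        if r.component_class in plan.swap_classes and r.metabolite_id not in base_ids:
            entries.append(replace(r))
    suffix = "+".join(sorted(plan.swap_classes)) if plan.swap_classes else "none"
    return DietSpec(
        name=f"{base.name}^{suffix}({ref.name})" if plan.swap_classes else base.name,
        entries=entries,
        intake_W=base.intake_W,
    )


def restrict_sugars(diet: DietSpec, keep: tuple[str, ...]) -> DietSpec:
    """Zero out every carbohydrate except the ones to keep."""
    carb_ids = {e.metabolite_id for e in diet.entries if e.component_class == "carbohydrate"}
    bad = [k for k in keep if k not in carb_ids]
    if bad:
        raise ValueError(f"sugar restriction names non-carbohydrates: {bad}")
    entries = [
        replace(e, percent_w_w=0.0)
        if e.component_class == "carbohydrate" and e.metabolite_id not in keep
        else replace(e)
        for e in diet.entries
    ]
    return DietSpec(name=f"{diet.name}|{'+'.join(sorted(keep)) or 'nosugar'}",
                    entries=entries, intake_W=diet.intake_W)


@dataclass
class SydicosCell:
    model_id: str
    plan_name: str
    diet: DietSpec
    distribution: FluxDistribution


def run_sydicos(
    models: list[MetabolicModel],
    plans: list[SwapPlan],
    expression_layers: dict[str, BoundMap] | None = None,
    options: SolverOptions | None = None,
) -> dict[tuple[str, str], SydicosCell]:
    """Parsimonious FBA for every (model, plan) pair.

    For each cell the plan's effective diet is turned into uptake bounds and
    applied on top of the model's (optionally expression-constrained)
    bounds; solver failures are recorded per cell and the batch continues.
    """
    options = options or SolverOptions()
    expression_layers = expression_layers or {}
    out: dict[tuple[str, str], SydicosCell] = {}
    for model in models:
        layers: list[BoundMap] = []
        if model.id in expression_layers:
            layers.append(expression_layers[model.id])
        exch = model.exchange_map()
        for plan in plans:
            diet = plan.effective_diet()
            try:
                constrained = apply_constraints(model, layers + [diet_bounds(diet, exch)])
                dist = pfba(constrained, options)
            except (KeyError, ValueError) as exc:
                dist = FluxDistribution(fluxes={}, objective_value=None,
                                        status=f"error: {exc}")
            out[(model.id, plan.name)] = SydicosCell(model.id, plan.name, diet, dist)
    return out


def constrain_with_expression(
    model: MetabolicModel, expr_profile, options: SolverOptions | None = None
) -> MetabolicModel:
    """Convenience: apply adapted E-flux bounds for one profile."""
    return apply_constraints(model, [eflux_bounds(model, expr_profile)])


# ---------------------------------------------------------------------------
# distances and ratios


def flux_distance(a: FluxDistribution, b: FluxDistribution) -> float:
    """Euclidean distance between two flux vectors over shared reactions."""
    for d in (a, b):
        if d.status != "optimal":
            raise ValueError(f"flux distance needs optimal distributions, got {d.status}")
    shared = sorted(set(a.fluxes) & set(b.fluxes))
    if set(a.fluxes) != set(b.fluxes):
        import warnings

        warnings.warn("flux distributions cover different reaction sets; "
                      "using the intersection", stacklevel=2)
    va = np.array([a.fluxes[r] for r in shared])
    vb = np.array([b.fluxes[r] for r in shared])
    return float(np.linalg.norm(va - vb))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    normalized: bool

    def at(self, la: str, lb: str) -> float:
        return float(self.values[self.labels.index(la), self.labels.index(lb)])


def distance_matrix(
    distributions: dict[str, FluxDistribution], normalize: bool = False
) -> DistanceMatrix:
    """All pairwise flux distances; optionally relative to the maximum."""
    if len(distributions) < 2:
        raise ValueError("need at least two distributions")
    labels = list(distributions)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = flux_distance(distributions[labels[i]], distributions[labels[j]])
            mat[i, j] = mat[j, i] = d
    if normalize:
        peak = mat.max()
        if peak > 0:
            mat = mat / peak
    return DistanceMatrix(labels=labels, values=mat, normalized=normalize)


def flux_ratio(
    a: FluxDistribution, b: FluxDistribution, epsilon: float = 1e-9
) -> dict[str, float | str]:
    """Reaction-wise |a|/|b| with categorical codes for (near-)zero fluxes.

    ``"new"`` marks reactions active only in a; ``"off"`` marks reactions
    inactive in both.
    """
    out: dict[str, float | str] = {}
    for rid in sorted(set(a.fluxes) & set(b.fluxes)):
        fa, fb = abs(a.fluxes[rid]), abs(b.fluxes[rid])
        if fb > epsilon:
            out[rid] = fa / fb
        elif fa > epsilon:
            out[rid] = "new"
        else:
            out[rid] = "off"
    return out


# ---------------------------------------------------------------------------
# carbon influx / efflux accounting


@dataclass
class CarbonSummary:
    influx: dict[str, float]  # metabolite -> mmol C/day taken up
    efflux: dict[str, float]  # metabolite -> mmol C/day produced
    total_influx: float
    total_efflux: float
    biomass_sunk: float


def efflux_influx_summary(
    dist: FluxDistribution,
    model: MetabolicModel,
    carbons: dict[str, int] | None = None,
    flux_epsilon: float = 0.0,
) -> CarbonSummary:
    """Carbon taken up and produced through the exchange reactions.

    With the secrete-positive exchange convention, negative exchange flux is
    influx.  Carbons drained by the biomass reaction are reported
    separately; on a fully carbon-balanced model
    total influx = total efflux + biomass-sunk carbons.
    """
    if dist.status != "optimal":
        raise ValueError("need an optimal flux distribution")
    if carbons is None:
        carbons = {m.id: m.carbons for m in model.metabolites.values()}
    influx: dict[str, float] = {}
    efflux: dict[str, float] = {}
    for rxn in model.exchanges:
        v = dist.fluxes.get(rxn.id, 0.0)
        if abs(v) <= flux_epsilon:
            continue
        (mid,) = rxn.stoichiometry
        coeff = rxn.stoichiometry[mid]
        net = -coeff * v  # mmol/day leaving the model boundary
        if carbons.get(mid) is None:
            raise KeyError(f"carbon count unknown for exchanged metabolite {mid}")
        if net > 0:
            efflux[mid] = efflux.get(mid, 0.0) + carbons[mid] * net
        else:
            influx[mid] = influx.get(mid, 0.0) + carbons[mid] * (-net)
    sunk = 0.0
    if model.objective and model.objective in model.reactions:
        v_bio = dist.fluxes.get(model.objective, 0.0)
        for mid, coeff in model.reactions[model.objective].stoichiometry.items():
            c = carbons.get(mid)
            if c is None:
                raise KeyError(f"carbon count unknown for biomass precursor {mid}")
            sunk += -coeff * c * v_bio  # substrates have negative coeff
    return CarbonSummary(
        influx=influx,
        efflux=efflux,
        total_influx=sum(influx.values()),
        total_efflux=sum(efflux.values()),
        biomass_sunk=sunk,
    )


# ---------------------------------------------------------------------------
# subsystem-level comparison


@dataclass
class SubsystemReport:
    rows: dict[str, dict[str, float]] = field(default_factory=dict)
    # subsystem -> {n_reactions_with_flux, n_higher_in_a, reaction_ratio}


def subsystem_reaction_ratio(
    a: FluxDistribution,
    b: FluxDistribution,
    model: MetabolicModel,
    flux_epsilon: float = 1e-6,
) -> SubsystemReport:
    """Per subsystem, the fraction of flux-carrying reactions higher in a.

    Only subsystems with at least one reaction carrying flux (|v| >
    flux_epsilon in a or b) are reported; a ratio of 1 means every carried
    reaction in that subsystem has higher absolute flux in a than in b.
    """
    report = SubsystemReport()
    by_subsystem: dict[str, list[str]] = {}
    for rxn in model.reactions.values():
        if not rxn.subsystem:
            continue
        by_subsystem.setdefault(rxn.subsystem, []).append(rxn.id)
    for subsystem, rids in sorted(by_subsystem.items()):
        carried = [
            r
            for r in rids
            if r in a.fluxes and r in b.fluxes
            and (abs(a.fluxes[r]) > flux_epsilon or abs(b.fluxes[r]) > flux_epsilon)
        ]
        if not carried:
            continue
        higher = [r for r in carried if abs(a.fluxes[r]) > abs(b.fluxes[r]) + flux_epsilon]
        report.rows[subsystem] = {
            "n_reactions_with_flux": len(carried),
            "n_higher_in_a": len(higher),
            "reaction_ratio": len(higher) / len(carried),
        }
    return report


def differential_subnetwork(
    a: FluxDistribution,
    b: FluxDistribution,
    model: MetabolicModel,
    subsystems: set[str] | None = None,
    biomass_id: str | None = None,
    flux_epsilon: float = 1e-6,
    currency: tuple[str, ...] = DEFAULT_CURRENCY,
) -> MetabolicModel:
    """Biomass-connected subnetwork of differential reactions.

    Reactions from the selected subsystems (default: all) whose flux
    differs between a and b by more than flux_epsilon are assembled into a
    reaction-metabolite bipartite graph; currency metabolites (matched by
    base name, compartment stripped) do not create connectivity.  The
    connected component containing the biomass reaction is returned as a
    sub-model; if biomass is not connected to any differential reaction an
    empty model is returned with a warning.
    """
    biomass_id = biomass_id or model.objective
    if biomass_id not in model.reactions:
        raise ValueError(f"biomass reaction {biomass_id!r} not in model")

    def is_currency(mid: str) -> bool:
        base = mid
        met = model.metabolites.get(mid)
        if met is not None and met.compartment and mid.endswith(f"_{met.compartment}"):
            base = mid[: -(len(met.compartment) + 1)]
        return base.lower() in currency

    selected = []
    for rxn in model.reactions.values():
        if subsystems is not None and rxn.subsystem not in subsystems:
            continue
        da = a.fluxes.get(rxn.id, 0.0)
        db = b.fluxes.get(rxn.id, 0.0)
        if abs(da - db) > flux_epsilon:
            selected.append(rxn.id)

    graph = nx.Graph()
    for rid in selected + [biomass_id]:
        graph.add_node(("r", rid))
        for mid in model.reactions[rid].stoichiometry:
            if is_currency(mid):
                continue
            graph.add_edge(("r", rid), ("m", mid))

    component = nx.node_connected_component(graph, ("r", biomass_id))
    rxn_ids = sorted(n[1] for n in component if n[0] == "r" and n[1] != biomass_id)
    if not rxn_ids:
        import warnings

        warnings.warn("biomass reaction is not connected to any differential "
                      "reaction; returning an empty subnetwork", stacklevel=2)
    sub = MetabolicModel(id=f"{model.id}_diffnet")
    keep_rxns = rxn_ids + ([biomass_id] if rxn_ids else [])
    for rid in keep_rxns:
        for mid in model.reactions[rid].stoichiometry:
            if mid not in sub.metabolites:
                sub.add_metabolite(model.metabolites[mid].copy())
        sub.add_reaction(model.reactions[rid].copy())
    sub.objective = biomass_id if biomass_id in sub.reactions else None
    return sub


def subnetwork_edge_list(sub: MetabolicModel) -> list[tuple[str, str, float]]:
    """(reaction, metabolite, coefficient) rows for graph tools."""
    return [
        (rxn.id, mid, coeff)
        for rxn in sub.reactions.values()
        for mid, coeff in sorted(rxn.stoichiometry.items())
    ]
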