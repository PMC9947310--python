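"""Model integration and quality control.

Covers the curation steps used when assembling a metabolic reconstruction
from several source networks: harmonizing metabolite identifiers onto a
common namespace (e.g. KEGG), merging stoichiometric matrices, collapsing
duplicate reactions, elemental mass-balance checks, stepwise removal of
imbalanced reactions under biomass/task guards, metabolic-task feasibility
testing, and detection of stoichiometrically inconsistent metabolites
(metabolites for which no strictly positive molecular mass can make every
internal reaction mass-conserving).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .core_model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    stoichiometric_matrix,
)
from .fba import SolverOptions, fba

DEFAULT_ELEMENTS = ("C", "N", "O", "S", "P")


# ---------------------------------------------------------------------------
# identifier mapping and merging


@dataclass
class MappingTable:
    """Rows of (source_namespace, source_id, target_id); many-to-one allowed."""

    rows: list[tuple[str, str, str]]
    target_namespace: str = "kegg"

    def __post_init__(self) -> None:
        seen = set()
        for ns, sid, _ in self.rows:
            if (ns, sid) in seen:
                raise ValueError(f"duplicate mapping source ({ns}, {sid})")
            seen.add((ns, sid))

    def lookup(self) -> dict[str, str]:
        return {sid: tid for _, sid, tid in self.rows}


@dataclass
class MappingReport:
    mapped: list[tuple[str, str]] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)
    merged: list[tuple[str, str]] = field(default_factory=list)  # (kept, removed)
    zeroed: list[tuple[str, str]] = field(default_factory=list)  # (reaction, metabolite)


def map_metabolite_ids(
    model: MetabolicModel, mapping: MappingTable
) -> tuple[MetabolicModel, MappingReport]:
    """Rename metabolites onto the mapping's target namespace.

    The mapped id is ``<target>_<compartment>`` so that the same compound in
    different compartments stays distinct; metabolites of one compartment
    that collide onto the same target are merged and every reaction is
    re-pointed.  If re-pointing puts a metabolite on both sides of a
    reaction the coefficients are summed; a net-zero sum drops the
    metabolite from that reaction and is flagged.
    """
    lut = mapping.lookup()
    report = MappingReport()
    new_id: dict[str, str] = {}
    for met in model.metabolites.values():
        if met.id in lut:
            target = lut[met.id]
            nid = f"{target}_{met.compartment}" if met.compartment else target
            new_id[met.id] = nid
            report.mapped.append((met.id, nid))
        else:
            new_id[met.id] = met.id
            report.unmapped.append(met.id)

    out = MetabolicModel(id=model.id, objective=model.objective,
                         compartments=list(model.compartments))
    for met in model.metabolites.values():
        nid = new_id[met.id]
        if nid in out.metabolites:
            report.merged.append((nid, met.id))
            continue
        m = met.copy()
        m.id = nid
        if met.id in lut:
            m.external_ids[mapping.target_namespace] = lut[met.id]
        out.add_metabolite(m)
    for g in model.genes.values():
        out.add_gene(g)
    for rxn in model.reactions.values():
        stoich: dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            nid = new_id[mid]
            stoich[nid] = stoich.get(nid, 0.0) + coeff
        dropped = [m for m, c in stoich.items() if c == 0]
        for m in dropped:
            del stoich[m]
            report.zeroed.append((rxn.id, m))
        r = rxn.copy()
        r.stoichiometry = stoich
        out.add_reaction(r)
    return out, report


@dataclass
class MergeReport:
    provenance: dict[str, list[str]] = field(default_factory=dict)
    formula_conflicts: list[str] = field(default_factory=list)
    renamed: list[tuple[str, str]] = field(default_factory=list)


def merge_models(models: list[MetabolicModel]) -> tuple[MetabolicModel, MergeReport]:
    """Union of metabolites, reactions and genes across models.

    Metabolites must already share a namespace (run
    :func:`map_metabolite_ids` first).  The first-seen formula wins on
    conflict (flagged).  Reactions sharing an id with identical
    stoichiometry gain joint provenance; same id with different
    stoichiometry is kept under a ``<id>__<model>`` alias.
    """
    if not models:
        raise ValueError("nothing to merge")
    out = MetabolicModel(id="+".join(m.id for m in models))
    report = MergeReport()
    for src in models:
        for met in src.metabolites.values():
            if met.id in out.metabolites:
                existing = out.metabolites[met.id]
                if (met.formula is not None and existing.formula is not None
                        and met.formula != existing.formula):
                    report.formula_conflicts.append(met.id)
                elif existing.formula is None and met.formula is not None:
                    existing.formula = dict(met.formula)
            else:
                out.add_metabolite(met.copy())
        for g in src.genes.values():
            out.add_gene(g)
        for rxn in src.reactions.values():
            rid = rxn.id
            if rid in out.reactions:
                if out.reactions[rid].stoichiometry == rxn.stoichiometry:
                    report.provenance[rid].append(src.id)
                    continue
                rid = f"{rxn.id}__{src.id}"
                report.renamed.append((rxn.id, rid))
            r = rxn.copy()
            r.id = rid
            out.add_reaction(r)
            report.provenance[rid] = [src.id]
    out.objective = next((m.objective for m in models if m.objective), None)
    return out, report


# ---------------------------------------------------------------------------
# duplicate reactions


def _canonical_key(rxn: Reaction) -> tuple:
    fwd = tuple(sorted((m, round(c, 9)) for m, c in rxn.stoichiometry.items()))
    if not rxn.reversible:
        return fwd
    rev = tuple(sorted((m, round(-c, 9)) for m, c in rxn.stoichiometry.items()))
    return min(fwd, rev)


@dataclass
class DuplicateReport:
    removed_duplicates: list[tuple[str, str]] = field(default_factory=list)  # (removed, kept)


def remove_duplicates(model: MetabolicModel) -> tuple[MetabolicModel, DuplicateReport]:
    """Collapse reactions with identical canonicalized stoichiometry.

    Direction is normalized for reversible reactions, so A<=>B and B<=>A are
    duplicates.  The first reaction in model order is kept; GPRs of the
    merged duplicates are joined with OR (either enzyme suffices) and the
    widest bounds are retained (orientation-adjusted for flipped
    duplicates).
    """
    out = MetabolicModel(id=model.id, objective=model.objective,
                         compartments=list(model.compartments))
    for met in model.metabolites.values():
        out.add_metabolite(met.copy())
    for g in model.genes.values():
        out.add_gene(g)
    report = DuplicateReport()
    kept_by_key: dict[tuple, Reaction] = {}
    for rxn in model.reactions.values():
        key = _canonical_key(rxn)
        keeper = kept_by_key.get(key)
        if keeper is None:
            r = rxn.copy()
            kept_by_key[key] = r
            out.add_reaction(r)
            continue
        fwd_r = tuple(sorted((m, round(c, 9)) for m, c in rxn.stoichiometry.items()))
        fwd_k = tuple(sorted((m, round(c, 9)) for m, c in keeper.stoichiometry.items()))
        flipped = fwd_r != fwd_k
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if flipped:
            lb, ub = -ub, -lb
        keeper.lower_bound = min(keeper.lower_bound, lb)
        keeper.upper_bound = max(keeper.upper_bound, ub)
        if rxn.gr_rule and rxn.gr_rule != keeper.gr_rule:
            if keeper.gr_rule:
                keeper.gr_rule = f"({keeper.gr_rule}) or ({rxn.gr_rule})"
            else:
                keeper.gr_rule = rxn.gr_rule
        report.removed_duplicates.append((rxn.id, keeper.id))
        if model.objective == rxn.id:
            out.objective = keeper.id
    return out, report


# ---------------------------------------------------------------------------
# elemental balance


@dataclass
class BalanceResult:
    status: str  # balanced | imbalanced | undetermined | exchange
    imbalance: dict[str, float] = field(default_factory=dict)


def elemental_balance(
    reaction: Reaction,
    metabolites: dict[str, Metabolite],
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> BalanceResult:
    """Net elemental imbalance of a reaction (products minus substrates).

    Exchange reactions are imbalanced by construction and get status
    ``exchange``; a reaction touching a metabolite with unknown formula is
    ``undetermined``, never ``balanced``.
    """
    if reaction.is_exchange:
        return BalanceResult(status="exchange")
    for mid in reaction.stoichiometry:
        met = metabolites.get(mid)
        if met is None or met.formula is None:
            return BalanceResult(status="undetermined")
    imbalance = {
        el: sum(
            coeff * metabolites[mid].formula.get(el, 0)
            for mid, coeff in reaction.stoichiometry.items()
        )
        for el in elements
    }
    balanced = all(abs(x) < 1e-9 for x in imbalance.values())
    return BalanceResult(
        status="balanced" if balanced else "imbalanced", imbalance=imbalance
    )


# ---------------------------------------------------------------------------
# metabolic tasks


@dataclass
class MetabolicTask:
    id: str
    allowed_inputs: list[tuple[str, float]]  # (metabolite id, max uptake flux)
    required_outputs: list[tuple[str, float]]  # (metabolite id, min production flux)

    def __post_init__(self) -> None:
        for _, f in self.allowed_inputs + self.required_outputs:
            if f < 0:
                raise ValueError("task fluxes must be non-negative")


@dataclass
class TaskResult:
    passed: bool
    reason: str = ""

    def __str__(self) -> str:
        return "pass" if self.passed else f"fail ({self.reason})"


def _steady_state_feasible(model: MetabolicModel, options: SolverOptions) -> bool:
    rxns = list(model.reactions.values())
    S = sp.csr_matrix(stoichiometric_matrix(model))
    res = linprog(
        np.zeros(len(rxns)),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=[(r.lower_bound, r.upper_bound) for r in rxns],
        method="highs",
        options={"primal_feasibility_tolerance": options.feasibility_tolerance},
    )
    return res.status == 0


def check_tasks(
    model: MetabolicModel,
    tasks: list[MetabolicTask],
    options: SolverOptions | None = None,
) -> dict[str, TaskResult]:
    """Feasibility-only task testing.

    For each task every exchange is closed, the allowed inputs are opened
    for uptake (up to their stated maximum), the required outputs are
    imposed as minimum production, and the steady-state LP is solved for
    feasibility — no objective.  Task metabolites without an exchange
    reaction get a temporary one for the check.
    """
    options = options or SolverOptions()
    results: dict[str, TaskResult] = {}
    for task in tasks:
        unknown = [
            mid
            for mid, _ in task.allowed_inputs + task.required_outputs
            if mid not in model.metabolites
        ]
        if unknown:
            results[task.id] = TaskResult(False, f"unknown metabolite: {','.join(unknown)}")
            continue
        work = model.copy()
        for rxn in work.exchanges:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
        exch = work.exchange_map()

        def boundary(mid: str) -> Reaction:
            if mid in exch:
                return work.reactions[exch[mid]]
            rxn = Reaction(id=f"TASK_EX_{mid}", stoichiometry={mid: -1.0},
                           lower_bound=0.0, upper_bound=0.0)
            work.add_reaction(rxn)
            exch[mid] = rxn.id
            return rxn

        for mid, max_uptake in task.allowed_inputs:
            rxn = boundary(mid)
            rxn.lower_bound = -max_uptake
        for mid, min_prod in task.required_outputs:
            rxn = boundary(mid)
            rxn.lower_bound = max(rxn.lower_bound, min_prod)
            rxn.upper_bound = DEFAULT_BOUND
        ok = _steady_state_feasible(work, options)
        results[task.id] = TaskResult(ok, "" if ok else "infeasible")
    return results


# ---------------------------------------------------------------------------
# stepwise pruning of imbalanced reactions


@dataclass
class CurationReport:
    removed_duplicates: list[tuple[str, str]] = field(default_factory=list)
    imbalanced: list[tuple[str, dict[str, float]]] = field(default_factory=list)
    pruned: list[str] = field(default_factory=list)
    retained_flagged: list[str] = field(default_factory=list)
    inconsistent_metabolites: list[str] = field(default_factory=list)
    undetermined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_duplicates": self.removed_duplicates,
            "imbalanced": [[r, imb] for r, imb in self.imbalanced],
            "pruned": self.pruned,
            "retained_flagged": self.retained_flagged,
            "inconsistent_metabolites": self.inconsistent_metabolites,
            "undetermined": self.undetermined,
        }


def prune_imbalanced(
    model: MetabolicModel,
    tasks: list[MetabolicTask] | None = None,
    biomass_tolerance: float = 1e-6,
    options: SolverOptions | None = None,
) -> tuple[MetabolicModel, CurationReport]:
    """Remove elementally imbalanced reactions while protecting function.

    Imbalanced reactions are visited in id-sorted order; each is tentatively
    removed and kept out only if the biomass optimum stays within
    ``biomass_tolerance`` (relative) of the reference and every originally
    passing task still passes.  Otherwise the reaction is reinstated and
    flagged for manual curation.
    """
    tasks = tasks or []
    options = options or SolverOptions()
    report = CurationReport()
    reference = fba(model, options)
    if reference.status != "optimal":
        raise ValueError(f"starting model has no optimal biomass flux ({reference.status})")
    ref_obj = reference.objective_value
    baseline = {
        tid for tid, res in check_tasks(model, tasks, options).items() if res.passed
    }

    for rxn in model.reactions.values():
        if rxn.id == model.objective:
            # the biomass drain is a pseudo-reaction, imbalanced by design
            continue
        res = elemental_balance(rxn, model.metabolites)
        if res.status == "imbalanced":
            report.imbalanced.append((rxn.id, res.imbalance))
        elif res.status == "undetermined":
            report.undetermined.append(rxn.id)

    work = model.copy()
    for rid, _ in sorted(report.imbalanced):
        candidate = work.copy()
        del candidate.reactions[rid]
        sol = fba(candidate, options)
        ok = (
            sol.status == "optimal"
            and sol.objective_value >= (1 - biomass_tolerance) * ref_obj - 1e-12
        )
        if ok and tasks:
            after = check_tasks(candidate, tasks, options)
            ok = all(after[tid].passed for tid in baseline)
        if ok:
            work = candidate
            report.pruned.append(rid)
        else:
            report.retained_flagged.append(rid)
    return work, report


# ---------------------------------------------------------------------------
# stoichiometric consistency


def stoichiometric_consistency(
    model: MetabolicModel, tol: float = 1e-6
) -> set[str]:
    """Metabolites without a strictly positive conserved molecular mass.

    Boundary pseudo-reactions (exchanges and the biomass sink) are excluded;
    over the internal reactions we solve

        maximize sum_i z_i  s.t.  S_intᵀ·m = 0, 0 <= z_i <= 1, z_i <= m_i, m >= 0

    and report metabolites with z_i < 1 - tol at the optimum.
    """
    internal = [
        r for r in model.reactions.values()
        if not r.is_exchange and r.id != model.objective
    ]
    if not internal:
        return set()
    met_ids = list(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    n = len(met_ids)
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(internal):
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(j)
            cols.append(met_index[mid])
            vals.append(float(coeff))
    St = sp.coo_matrix((vals, (rows, cols)), shape=(len(internal), n)).tocsr()

    # variables x = [m (n); z (n)]
    c = np.concatenate([np.zeros(n), -np.ones(n)])
    A_eq = sp.hstack([St, sp.csr_matrix((len(internal), n))]).tocsr()
    A_ub = sp.hstack([-sp.identity(n), sp.identity(n)]).tocsr()  # z - m <= 0
    bounds = [(0.0, None)] * n + [(0.0, 1.0)] * n
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(n),
        A_eq=A_eq,
        b_eq=np.zeros(len(internal)),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:  # pragma: no cover - LP is always feasible (m=z=0)
        raise RuntimeError(f"consistency LP failed with status {res.status}")
    z = res.x[n:]
    return {met_ids[i] for i in range(n) if z[i] < 1 - tol}
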