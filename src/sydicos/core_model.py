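"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric network: metabolites placed in
compartments, reactions with signed stoichiometric coefficients, flux bounds
in mmol/mouse/day, gene-protein-reaction (GPR) boolean rules, and a biomass
objective reaction.  Exchange reactions are pseudo-reactions with a single
metabolite that move mass across the model boundary; by convention here a
*positive* exchange flux secretes (efflux) and a *negative* flux takes up
(influx).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .gpr import gpr_genes, parse_gpr

#: Default magnitude for unconstrained flux bounds (mmol/mouse/day).
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into a count map.

    An empty string yields an empty map (a *known* composition with zero of
    every element — distinct from an unknown formula, which is ``None``).
    """
    if formula is None:
        raise ValueError("formula is None; use None directly for unknown")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at offset {pos}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r} at offset {pos}")
    # zero counts (e.g. the H0 marker for a known empty composition) carry
    # no information beyond "known"
    return {el: n for el, n in counts.items() if n}


def format_formula(counts: dict[str, int] | None) -> str | None:
    if counts is None:
        return None
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(counts.items()) if n
    )


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: dict[str, int] | None = None
    external_ids: dict[str, str] = field(default_factory=dict)

    @property
    def carbons(self) -> int | None:
        """Carbon atoms per molecule, or None if the formula is unknown."""
        if self.formula is None:
            return None
        return int(self.formula.get("C", 0))

    def copy(self) -> "Metabolite":
        return replace(
            self,
            formula=None if self.formula is None else dict(self.formula),
            external_ids=dict(self.external_ids),
        )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gr_rule: str = ""
    subsystem: str = ""
    #: explicit boundary flag; None = infer from structure
    exchange: bool | None = None

    @property
    def is_exchange(self) -> bool:
        """True for boundary pseudo-reactions.

        Inferred as single-metabolite unless the ``exchange`` flag says
        otherwise (an internal reaction with net single-metabolite
        stoichiometry, e.g. an autocatalytic X -> 2 X written as net
        production, can set ``exchange=False``).
        """
        if self.exchange is not None:
            return self.exchange
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class Gene:
    id: str
    name: str = ""


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    objective: str | None = None
    compartments: list[str] = field(default_factory=list)

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        if met.compartment and met.compartment not in self.compartments:
            self.compartments.append(met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    def add_gene(self, gene: Gene) -> None:
        self.genes.setdefault(gene.id, gene)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def exchange_map(self) -> dict[str, str]:
        """Map metabolite id -> id of its exchange reaction."""
        out: dict[str, str] = {}
        for rxn in self.exchanges:
            (met,) = rxn.stoichiometry
            out[met] = rxn.id
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={k: m.copy() for k, m in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            genes={k: replace(g) for k, g in self.genes.items()},
            objective=self.objective,
            compartments=list(self.compartments),
        )


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class Violation:
    entity: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule} ({self.detail})"


def stoichiometric_matrix(model: MetabolicModel, sparse: bool = False):
    """Assemble the S matrix, metabolites x reactions.

    Rows follow ``model.metabolites`` insertion order and columns follow
    ``model.reactions`` insertion order; entry (i, j) is the signed
    coefficient of metabolite i in reaction j (negative = consumed).
    """
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    n_met, n_rxn = len(met_index), len(model.reactions)
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions.values()):
        for met, coeff in rxn.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            vals.append(float(coeff))
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n_met, n_rxn))
    return mat.tocsr() if sparse else mat.toarray()


def validate_model(model: MetabolicModel) -> list[Violation]:
    """Check the model invariants; returns violations, never raises."""
    out: list[Violation] = []
    for met in model.metabolites.values():
        if met.formula is not None and any(n < 0 for n in met.formula.values()):
            out.append(Violation(met.id, "negative element count"))
    for rxn in model.reactions.values():
        if rxn.lower_bound > rxn.upper_bound:
            out.append(
                Violation(
                    rxn.id,
                    "lower_bound > upper_bound",
                    f"{rxn.lower_bound} > {rxn.upper_bound}",
                )
            )
        for met in rxn.stoichiometry:
            if met not in model.metabolites:
                out.append(Violation(rxn.id, "unknown metabolite", met))
        if rxn.gr_rule:
            try:
                tree = parse_gpr(rxn.gr_rule)
            except ValueError as exc:
                out.append(Violation(rxn.id, "malformed gr_rule", str(exc)))
            else:
                for g in gpr_genes(tree):
                    if g not in model.genes:
                        out.append(Violation(rxn.id, "unknown gene", g))
    if model.objective is not None and model.objective not in model.reactions:
        out.append(Violation(model.id, "objective reaction missing", model.objective))
    return out


def s_dot_v(model: MetabolicModel, dist: FluxDistribution) -> np.ndarray:
    """Net production rate of every metabolite under a flux distribution."""
    S = stoichiometric_matrix(model)
    v = np.array([dist.fluxes.get(r, 0.0) for r in model.reactions])
    return S @ v
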