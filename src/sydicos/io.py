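"""Model I/O: SBML Level 3 (fbc) and a plain-text tabular dialect.

SBML reading and writing is delegated to cobrapy, the community-standard
implementation of the SBML-FBC conventions; models are converted to and from
:class:`~sydicos.core_model.MetabolicModel` losslessly for the fields this
package uses (ids, names, stoichiometry, bounds, GPRs, subsystems, formulas,
KEGG annotations, objective).

The tabular dialect is a directory of three TSV tables plus a JSON header:

``metabolites.tsv``
    columns ``id, name, compartment, formula, kegg``.  ``formula`` is an
    elemental string (``C6H12O6``); an empty cell means zero of every tracked
    element, the literal ``NA`` means unknown.
``reactions.tsv``
    columns ``id, name, equation, lower_bound, upper_bound, gr_rule,
    subsystem``.  Equations use ``⇒`` (irreversible rendering) or ``⇔``
    and compartment-bracket tokens, e.g. ``1 glc[c] + 1 atp[c] ⇒ g6p[c]``;
    a missing side denotes a boundary/sink reaction.
``genes.tsv``
    columns ``id, name``.
``model.json``
    ``{"id": ..., "objective": ..., "compartments": [...]}``.

Reversibility is carried solely by the bounds columns; the arrow in the
equation is cosmetic.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import pandas as pd

from .core_model import (
    DEFAULT_BOUND,
    Gene,
    MetabolicModel,
    Metabolite,
    Reaction,
    Violation,
    format_formula,
    parse_formula,
    validate_model,
)

_MET_TOKEN = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")
_BRACKET = re.compile(r"^(.*)\[([^\[\]]+)\]$")

FORWARD_ARROW = "⇒"
REVERSIBLE_ARROW = "⇔"


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed."""


class ModelValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "model failed validation: " + "; ".join(str(v) for v in violations)
        )


def _met_token_to_id(token: str) -> str:
    m = _BRACKET.match(token)
    if m:
        return f"{m.group(1)}_{m.group(2)}"
    return token


def _met_id_to_token(mid: str, compartment: str) -> str:
    suffix = f"_{compartment}"
    if compartment and mid.endswith(suffix):
        return f"{mid[: -len(suffix)]}[{compartment}]"
    return mid


def parse_equation(equation: str) -> dict[str, float]:
    """Parse a reaction equation string into a stoichiometry map."""
    eq = equation.strip()
    arrow = None
    for a in (FORWARD_ARROW, REVERSIBLE_ARROW, "=>", "<=>"):
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ModelFormatError(f"no reaction arrow in equation {equation!r}")
    left, right = eq.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            m = _MET_TOKEN.match(term.strip())
            if not m:
                raise ModelFormatError(f"bad term {term!r} in {equation!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            mid = _met_token_to_id(m.group(2))
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    return {k: v for k, v in stoich.items() if v != 0}


def format_equation(rxn: Reaction, model: MetabolicModel) -> str:
    def fmt(items):
        parts = []
        for mid, coeff in items:
            comp = model.metabolites[mid].compartment if mid in model.metabolites else ""
            tok = _met_id_to_token(mid, comp)
            c = abs(coeff)
            parts.append(tok if c == 1 else f"{c:g} {tok}")
        return " + ".join(parts)

    subs = [(m, c) for m, c in sorted(rxn.stoichiometry.items()) if c < 0]
    prods = [(m, c) for m, c in sorted(rxn.stoichiometry.items()) if c > 0]
    arrow = REVERSIBLE_ARROW if rxn.reversible else FORWARD_ARROW
    return f"{fmt(subs)} {arrow} {fmt(prods)}".strip()


# ---------------------------------------------------------------------------
# tabular dialect


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_tabular(path: str | Path) -> MetabolicModel:
    d = Path(path)
    for fname in ("metabolites.tsv", "reactions.tsv", "genes.tsv", "model.json"):
        if not (d / fname).exists():
            raise ModelFormatError(f"missing {fname} in {d}")
    header = json.loads((d / "model.json").read_text())
    model = MetabolicModel(id=header.get("id", d.name))
    for _, row in _read_tsv(d / "metabolites.tsv").iterrows():
        formula = None if row["formula"] == "NA" else parse_formula(row["formula"])
        ext = {"kegg": row["kegg"]} if row.get("kegg") else {}
        model.add_metabolite(
            Metabolite(
                id=row["id"],
                name=row["name"],
                compartment=row["compartment"],
                formula=formula,
                external_ids=ext,
            )
        )
    for _, row in _read_tsv(d / "genes.tsv").iterrows():
        model.add_gene(Gene(id=row["id"], name=row["name"]))
    for _, row in _read_tsv(d / "reactions.tsv").iterrows():
        stoich = parse_equation(row["equation"])
        lb = float(row["lower_bound"]) if row["lower_bound"] != "" else math.nan
        ub = float(row["upper_bound"]) if row["upper_bound"] != "" else math.nan
        if math.isnan(lb) or math.isnan(ub):
            reversible = REVERSIBLE_ARROW in row["equation"] or "<=>" in row["equation"]
            lb = -DEFAULT_BOUND if reversible else 0.0
            ub = DEFAULT_BOUND
        model.add_reaction(
            Reaction(
                id=row["id"],
                name=row["name"],
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gr_rule=row["gr_rule"],
                subsystem=row["subsystem"],
            )
        )
    model.objective = header.get("objective")
    for comp in header.get("compartments", []):
        if comp not in model.compartments:
            model.compartments.append(comp)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


def write_tabular(model: MetabolicModel, path: str | Path) -> None:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": "NA" if m.formula is None else format_formula(m.formula),
                "kegg": m.external_ids.get("kegg", ""),
            }
            for m in model.metabolites.values()
        ],
        columns=["id", "name", "compartment", "formula", "kegg"],
    )
    rxns = pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r, model),
                "lower_bound": f"{r.lower_bound:g}",
                "upper_bound": f"{r.upper_bound:g}",
                "gr_rule": r.gr_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        ],
        columns=[
            "id", "name", "equation", "lower_bound", "upper_bound",
            "gr_rule", "subsystem",
        ],
    )
    genes = pd.DataFrame(
        [{"id": g.id, "name": g.name} for g in model.genes.values()],
        columns=["id", "name"],
    )
    mets.to_csv(d / "metabolites.tsv", sep="\t", index=False)
    rxns.to_csv(d / "reactions.tsv", sep="\t", index=False)
    genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    (d / "model.json").write_text(
        json.dumps(
            {
                "id": model.id,
                "objective": model.objective,
                "compartments": model.compartments,
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# SBML via cobrapy


def to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = []
    for m in model.metabolites.values():
        # a known-empty composition is written as the zero-count marker H0,
        # which SBML keeps while an empty string would be dropped
        cmet = cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=m.compartment or "c",
            formula=None if m.formula is None else (format_formula(m.formula) or "H0"),
        )
        if "kegg" in m.external_ids:
            cmet.annotation["kegg.compound"] = m.external_ids["kegg"]
        mets.append(cmet)
    cm.add_metabolites(mets)
    rxns = []
    for r in model.reactions.values():
        crxn = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        rxns.append(crxn)
    cm.add_reactions(rxns)
    for r in model.reactions.values():
        crxn = cm.reactions.get_by_id(r.id)
        crxn.add_metabolites(
            {cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()}
        )
        crxn.gene_reaction_rule = r.gr_rule
        crxn.subsystem = r.subsystem
        if r.subsystem:
            # carried in notes so the SBML round-trip preserves it
            crxn.notes["SUBSYSTEM"] = r.subsystem
    for g in model.genes.values():
        if g.id in cm.genes:
            cm.genes.get_by_id(g.id).name = g.name
    if model.objective is not None:
        cm.objective = model.objective
    return cm


def from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(id=cm.id or "model")
    for cmet in cm.metabolites:
        formula = None
        if cmet.formula is not None:
            formula = parse_formula(cmet.formula)
        kegg = cmet.annotation.get("kegg.compound")
        if isinstance(kegg, list):
            kegg = kegg[0]
        model.add_metabolite(
            Metabolite(
                id=cmet.id,
                name=cmet.name or "",
                compartment=cmet.compartment or "",
                formula=formula,
                external_ids={"kegg": kegg} if kegg else {},
            )
        )
    for cg in cm.genes:
        model.add_gene(Gene(id=cg.id, name=cg.name or ""))
    objective = None
    for crxn in cm.reactions:
        model.add_reaction(
            Reaction(
                id=crxn.id,
                name=crxn.name or "",
                stoichiometry={m.id: c for m, c in crxn.metabolites.items()},
                lower_bound=crxn.lower_bound,
                upper_bound=crxn.upper_bound,
                gr_rule=crxn.gene_reaction_rule or "",
                subsystem=crxn.subsystem or "",
            )
        )
        if crxn.objective_coefficient:
            objective = crxn.id
    model.objective = objective
    return model


def read_sbml(path: str | Path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several exception types
        raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    model = from_cobra(cm)
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# front door


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "tabular"
    if path.suffix.lower() in (".xml", ".sbml"):
        return "sbml"
    raise ModelFormatError(f"cannot infer model format from {path}")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read and validate a model from SBML or the tabular dialect."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        return read_sbml(path)
    if fmt == "tabular":
        return read_tabular(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "tabular")
    if fmt == "sbml":
        write_sbml(model, path)
    elif fmt == "tabular":
        write_tabular(model, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
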