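"""Plain-text serialization of diets, expression, tasks, bounds and fluxes.

All tables are TSV.  Diet files start with a ``#``-prefixed JSON header line
carrying the diet name and daily intake; flux files get a JSON metadata
sidecar (``<stem>.meta.json``) with solver status, objective and options.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constraints import BoundMap, DietEntry, DietSpec, ExpressionProfile
from .core_model import FluxDistribution
from .curation import MetabolicTask
from .fba import SolverOptions
from .swap import DistanceMatrix, SubsystemReport


def write_diet(diet: DietSpec, path: str | Path) -> None:
    path = Path(path)
    header = json.dumps({"name": diet.name, "intake_W": diet.intake_W})
    df = pd.DataFrame(
        [
            {
                "metabolite": e.metabolite_id,
                "percent_w_w": e.percent_w_w,
                "class": e.component_class,
                "mw": e.molecular_weight,
                "carbons": e.carbons,
            }
            for e in diet.entries
        ]
    )
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_diet(path: str | Path) -> DietSpec:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
        df = pd.read_csv(fh, sep="\t")
    entries = [
        DietEntry(
            metabolite_id=row["metabolite"],
            percent_w_w=float(row["percent_w_w"]),
            component_class=row["class"],
            molecular_weight=float(row["mw"]),
            carbons=int(row["carbons"]),
        )
        for _, row in df.iterrows()
    ]
    return DietSpec(
        name=meta.get("name", path.stem),
        entries=entries,
        intake_W=float(meta.get("intake_W", 3.0)),
    )


def write_expression(profiles: list[ExpressionProfile], path: str | Path) -> None:
    genes = sorted({g for p in profiles for g in p.values})
    df = pd.DataFrame(
        {"gene": genes}
        | {p.condition: [p.values.get(g, 0.0) for g in genes] for p in profiles}
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, unit: str = "FPKM") -> dict[str, ExpressionProfile]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for cond in df.columns[1:]:
        out[cond] = ExpressionProfile(
            condition=cond,
            values=dict(zip(df["gene"], df[cond].astype(float))),
            unit=unit,
        )
    return out


def write_tasks(tasks: list[MetabolicTask], path: str | Path) -> None:
    rows = []
    for t in tasks:
        for mid, f in t.allowed_inputs:
            rows.append({"task": t.id, "role": "input", "metabolite": mid, "flux": f})
        for mid, f in t.required_outputs:
            rows.append({"task": t.id, "role": "output", "metabolite": mid, "flux": f})
    pd.DataFrame(rows, columns=["task", "role", "metabolite", "flux"]).to_csv(
        path, sep="\t", index=False
    )


def read_tasks(path: str | Path) -> list[MetabolicTask]:
    df = pd.read_csv(path, sep="\t")
    tasks: dict[str, MetabolicTask] = {}
    for _, row in df.iterrows():
        t = tasks.setdefault(row["task"], MetabolicTask(row["task"], [], []))
        pair = (row["metabolite"], float(row["flux"]))
        (t.allowed_inputs if row["role"] == "input" else t.required_outputs).append(pair)
    return list(tasks.values())


def write_bounds(bounds: BoundMap, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "reaction": rid,
                "lower": "" if lo is None else f"{lo:.10g}",
                "upper": "" if hi is None else f"{hi:.10g}",
            }
            for rid, (lo, hi) in sorted(bounds.items())
        ],
        columns=["reaction", "lower", "upper"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_bounds(path: str | Path) -> BoundMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        row["reaction"]: (
            float(row["lower"]) if row["lower"] != "" else None,
            float(row["upper"]) if row["upper"] != "" else None,
        )
        for _, row in df.iterrows()
    }


def write_fluxes(
    dist: FluxDistribution,
    path: str | Path,
    options: SolverOptions | None = None,
    extra_meta: dict | None = None,
) -> None:
    path = Path(path)
    pd.DataFrame(
        [{"reaction": r, "flux": f"{v:.10g}"} for r, v in sorted(dist.fluxes.items())],
        columns=["reaction", "flux"],
    ).to_csv(path, sep="\t", index=False)
    meta = {
        "status": dist.status,
        "objective_value": dist.objective_value,
        "solver_options": asdict(options) if options else None,
    } | (extra_meta or {})
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_fluxes(path: str | Path) -> FluxDistribution:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FluxDistribution(
        fluxes=dict(zip(df["reaction"], df["flux"].astype(float))),
        objective_value=meta.get("objective_value"),
        status=meta.get("status", "optimal"),
    )


def write_mapping_table(mapping, path: str | Path) -> None:
    pd.DataFrame(mapping.rows,
                 columns=["source_namespace", "source_id", "target_id"]).to_csv(
        path, sep="\t", index=False)


def read_mapping_table(path: str | Path, target_namespace: str = "kegg"):
    from .curation import MappingTable

    df = pd.read_csv(path, sep="\t", dtype=str)
    return MappingTable(rows=[tuple(r) for r in df.itertuples(index=False)],
                        target_namespace=target_namespace)


def write_edge_list(rows: list[tuple[str, str, float]], path: str | Path) -> None:
    """(reaction, metabolite, coefficient) rows, for graph tools."""
    pd.DataFrame(rows, columns=["reaction", "metabolite", "coefficient"]).to_csv(
        path, sep="\t", index=False)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(np.asarray(dm.values), index=dm.labels, columns=dm.labels).to_csv(
        path, sep="\t", index_label="label"
    )


def write_subsystem_report(report: SubsystemReport, path: str | Path) -> None:
    pd.DataFrame(
        [{"subsystem": s} | row for s, row in sorted(report.rows.items())],
        columns=["subsystem", "n_reactions_with_flux", "n_higher_in_a", "reaction_ratio"],
    ).to_csv(path, sep="\t", index=False)
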