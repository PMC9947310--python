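"""Flux balance analysis with secondary L1 flux minimization.

FBA maximizes the biomass objective flux subject to the steady-state
constraint S·v = 0 and the reaction bounds.  Because the optimal flux vector
is typically degenerate, a second stage fixes the objective at its optimum
and minimizes the sum of absolute fluxes Σ|v_j| (the parsimonious-flux
convention), which yields reproducible flux distributions suited to pairwise
comparison.  Both stages are single LPs solved with the deterministic HiGHS
solver via :func:`scipy.optimize.linprog`; the L1 stage introduces auxiliary
variables t_j >= |v_j| and minimizes Σ t_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .core_model import FluxDistribution, MetabolicModel, stoichiometric_matrix

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class SolverOptions:
    feasibility_tolerance: float = 1e-9
    optimality_tolerance: float = 1e-9
    #: relative slack allowed on the fixed objective in the L1 stage
    objective_fix_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        for f in (self.feasibility_tolerance, self.optimality_tolerance,
                  self.objective_fix_tolerance):
            if f <= 0:
                raise ValueError("solver tolerances must be positive")


def _linprog(c, A_eq, b_eq, bounds, options: SolverOptions, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": options.feasibility_tolerance,
            "dual_feasibility_tolerance": options.optimality_tolerance,
        },
    )


def fba(model: MetabolicModel, options: SolverOptions | None = None) -> FluxDistribution:
    """Maximize the objective reaction flux at steady state."""
    if model.objective is None or model.objective not in model.reactions:
        raise ValueError("model has no objective reaction")
    options = options or SolverOptions()
    rxn_ids = list(model.reactions)
    S = sp.csr_matrix(stoichiometric_matrix(model))
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(model.objective)] = -1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    res = _linprog(c, S, np.zeros(S.shape[0]), bounds, options)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    return FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, res.x))),
        objective_value=float(-res.fun),
        status="optimal",
    )


def pfba(model: MetabolicModel, options: SolverOptions | None = None) -> FluxDistribution:
    """FBA followed by minimization of Σ|v| at the fixed biomass optimum."""
    options = options or SolverOptions()
    stage1 = fba(model, options)
    if stage1.status != "optimal":
        return stage1
    rxn_ids = list(model.reactions)
    n = len(rxn_ids)
    obj_idx = rxn_ids.index(model.objective)
    f_star = stage1.objective_value

    S = sp.csr_matrix(stoichiometric_matrix(model))
    m = S.shape[0]
    # variables x = [v (n); t (n)], minimize sum t
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sp.hstack([S, sp.csr_matrix((m, n))]).tocsr()
    b_eq = np.zeros(m)
    eye = sp.identity(n, format="csr")
    # v - t <= 0 and -v - t <= 0  enforce t >= |v|
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])]).tocsr()
    b_ub = np.zeros(2 * n)

    base_bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    t_max = max(max(abs(lo), abs(hi)) for lo, hi in base_bounds)

    def solve(slack: float):
        bounds = list(base_bounds)
        lo, hi = bounds[obj_idx]
        bounds[obj_idx] = (max(lo, f_star - slack), min(hi, f_star + slack))
        bounds = bounds + [(0.0, t_max)] * n
        return _linprog(c, A_eq, b_eq, bounds, options, A_ub=A_ub, b_ub=b_ub)

    # fix the objective exactly; fall back to a small relative band only if
    # the exactly-fixed LP fails numerically
    res = solve(0.0)
    if res.status != 0:
        res = solve(options.objective_fix_tolerance * max(1.0, abs(f_star)))
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        # stage 1 was optimal; stage 2 infeasibility is numerical only
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    v = res.x[:n]
    return FluxDistribution(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(v[obj_idx]),
        status="optimal",
    )


def total_absolute_flux(dist: FluxDistribution) -> float:
    return float(sum(abs(v) for v in dist.fluxes.values()))
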