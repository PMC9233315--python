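"""Linear-programming flux analysis: FBA, parsimonious FBA, and FVA.

All three operate on the polytope ``{v : S v = 0, lb <= v <= ub}``.  FBA
maximises (or minimises) the flux of one objective reaction; parsimonious
FBA re-solves for the minimum total absolute flux among (near-)optimal
solutions, giving a reproducible representative when alternate optima
exist; flux variability analysis reports the attainable range of each
reaction at a fixed fraction of the optimum.

The LP backend is SciPy's HiGHS interface behind a minimal contract
(matrix, bounds, objective in model insertion order), so results are
deterministic for a given model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import MetabolicModel, ValidationError, build_stoich_matrix

__all__ = [
    "FluxSolution",
    "FluxRange",
    "SolverError",
    "solve_fba",
    "solve_pfba",
    "flux_variability",
    "STEADY_STATE_TOL",
    "BOUND_TOL",
]

STEADY_STATE_TOL = 1e-6
BOUND_TOL = 1e-9
PFBA_OBJECTIVE_FRACTION = 1.0 - 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "failed"}


class SolverError(RuntimeError):
    """The LP backend failed in a way that is not a clean status."""


@dataclass
class FluxSolution:
    """One flux vector: solver status, objective value, flux per reaction.

    Units are mmol gCDW^-1 h^-1; the biomass/objective flux is h^-1.
    """

    status: str
    objective_value: float
    fluxes: dict[str, float]
    objective_id: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"flux": pd.Series(self.fluxes, dtype=float)}
        ).rename_axis("reaction")

    def summary(self, top: int = 15) -> str:
        lines = [
            f"status:    {self.status}",
            f"objective: {self.objective_id} = {self.objective_value:.6g}",
            "largest fluxes:",
        ]
        series = pd.Series(self.fluxes, dtype=float)
        for rid, v in series.reindex(series.abs().sort_values(ascending=False).index)[
            :top
        ].items():
            lines.append(f"  {rid:<14s} {v: .6g}")
        return "\n".join(lines)


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float


def _lp_arrays(model: MetabolicModel):
    S, _, rxn_index = build_stoich_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    return S, rxn_index, lb, ub


def _run(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    return res


def _check_solution(model: MetabolicModel, S, v, lb, ub) -> None:
    residual = np.abs(S @ v).max() if S.size else 0.0
    if residual > STEADY_STATE_TOL:
        raise SolverError(f"steady-state residual {residual:.3g} exceeds tolerance")
    if np.any(v < lb - 1e-6) or np.any(v > ub + 1e-6):
        raise SolverError("solution violates flux bounds")


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Maximise (default) or minimise one reaction flux at steady state.

    The status is reported faithfully; an infeasible or unbounded problem
    yields a :class:`FluxSolution` with empty fluxes, never a fabricated
    vector.
    """
    objective_id = objective_id or model.objective_reaction_id
    if objective_id not in model.reactions:
        raise ValidationError(f"unknown objective reaction {objective_id!r}")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    S, rxn_index, lb, ub = _lp_arrays(model)
    n = len(rxn_index)
    c = np.zeros(n)
    c[rxn_index[objective_id]] = -1.0 if sense == "max" else 1.0
    res = _run(c, None, None, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status, float("nan"), {}, objective_id)
    v = res.x
    _check_solution(model, S, v, lb, ub)
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    return FluxSolution("optimal", float(fluxes[objective_id]), fluxes, objective_id)


def solve_pfba(
    model: MetabolicModel,
    objective_id: str | None = None,
    objective_fraction: float = PFBA_OBJECTIVE_FRACTION,
) -> FluxSolution:
    """Parsimonious FBA: minimise total |v| at (near-)optimal objective.

    Among flux vectors whose objective is at least ``objective_fraction``
    times the FBA optimum, returns the one minimising the sum of absolute
    fluxes via the standard split-variable LP.  The reported
    ``objective_value`` is the flux the representative actually carries
    through the objective reaction.
    """
    objective_id = objective_id or model.objective_reaction_id
    fba = solve_fba(model, objective_id)
    if not fba.optimal:
        return fba
    S, rxn_index, lb, ub = _lp_arrays(model)
    m, n = S.shape
    # variables: [p; q] >= 0 with v = p - q
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    c_obj = np.zeros(n)
    c_obj[rxn_index[objective_id]] = 1.0
    # v >= lb, v <= ub, c.v >= fraction*opt   (opt may be negative; use signed bound)
    opt = fba.objective_value
    target = objective_fraction * opt if opt >= 0 else opt - (1 - objective_fraction) * abs(opt)
    A_ub = np.vstack(
        [
            np.hstack([-np.eye(n), np.eye(n)]),  # -v <= -lb
            np.hstack([np.eye(n), -np.eye(n)]),  # v <= ub
            np.hstack([-c_obj, c_obj]),  # -c.v <= -target
        ]
    )
    b_ub = np.concatenate([-lb, ub, [-target]])
    cost = np.ones(2 * n)
    res = _run(cost, A_ub, b_ub, A_eq, b_eq, [(0, None)] * (2 * n))
    if res.status != 0:
        raise SolverError(f"pFBA restriction unexpectedly {_STATUS.get(res.status)}")
    v = res.x[:n] - res.x[n:]
    _check_solution(model, S, v, lb, ub)
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    return FluxSolution("optimal", float(fluxes[objective_id]), fluxes, objective_id)


def flux_variability(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    objective_fraction: float = 1.0,
    objective_id: str | None = None,
) -> dict[str, FluxRange]:
    """Min/max flux per reaction with the objective held at a fraction of
    its optimum."""
    objective_id = objective_id or model.objective_reaction_id
    if reaction_ids is None:
        reaction_ids = list(model.reactions)
    missing = [r for r in reaction_ids if r not in model.reactions]
    if missing:
        raise ValidationError(f"unknown reactions for FVA: {missing}")
    fba = solve_fba(model, objective_id)
    if not fba.optimal:
        raise SolverError(f"FVA requires an optimal FBA solution, got {fba.status}")
    S, rxn_index, lb, ub = _lp_arrays(model)
    n = S.shape[1]
    c_obj = np.zeros(n)
    c_obj[rxn_index[objective_id]] = 1.0
    opt = fba.objective_value
    target = objective_fraction * opt if opt >= 0 else opt - (1 - objective_fraction) * abs(opt)
    A_ub = -c_obj[None, :]
    b_ub = np.array([-target])
    bounds = list(zip(lb, ub))
    out: dict[str, FluxRange] = {}
    for rid in reaction_ids:
        c = np.zeros(n)
        c[rxn_index[rid]] = 1.0
        lo = _run(c, A_ub, b_ub, S, np.zeros(S.shape[0]), bounds)
        hi = _run(-c, A_ub, b_ub, S, np.zeros(S.shape[0]), bounds)
        if lo.status != 0 or hi.status != 0:
            raise SolverError(f"FVA subproblem failed for {rid!r}")
        out[rid] = FluxRange(rid, float(lo.x[rxn_index[rid]]), float(hi.x[rxn_index[rid]]))
    return out
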