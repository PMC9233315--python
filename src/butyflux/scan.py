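"""Product-rate coupling scans, cofactor turnover, and flux-switch detection.

These routines reproduce the robustness-analysis style of experiment in
which one product's secretion rate is clamped over a grid while growth
is re-maximised, and the co-products, cofactor turnover rates and key
reaction fluxes are recorded at every grid point.  A "switch" is the
grid interval over which the representative flux pattern of a reaction
pair (e.g. hydrogenase vs Rnf, or acetate kinase vs ATPase) flips from
one member to the other; flux variability analysis distinguishes forced
switches from artefacts of alternate optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MetabolicModel, ValidationError
from .fba import FluxRange, FluxSolution, flux_variability, solve_pfba

__all__ = [
    "RoleMap",
    "ScanPoint",
    "ScanResult",
    "SwitchReport",
    "cofactor_turnover",
    "production_scan",
    "detect_switch",
    "two_flux_scan",
]

ROLE_NAMES = (
    "pfor", "hyd", "bcd_etfab", "rnf", "atpase", "ack", "biomass",
    "ex_butyrate", "ex_acetate", "ex_lactate", "ex_h2", "ex_co2", "ex_formate",
)
COFACTOR_NAMES = ("nadh", "nadph", "atp", "fd_red")


@dataclass
class RoleMap:
    """Binding of abstract network roles to concrete identifiers.

    ``reactions`` maps role names (hyd, rnf, atpase, ack, pfor,
    bcd_etfab, biomass, ex_*) to reaction ids; ``cofactors`` maps
    cofactor names (nadh, nadph, atp, fd_red) to metabolite ids.  Roles
    may be left unbound; analyses skip them with a warning.
    """

    reactions: dict[str, str] = field(default_factory=dict)
    cofactors: dict[str, str] = field(default_factory=dict)

    def validate(self, model: MetabolicModel) -> None:
        for role, rid in self.reactions.items():
            if rid not in model.reactions:
                raise ValidationError(
                    f"role {role!r} bound to unknown reaction {rid!r}"
                )
        for name, mid in self.cofactors.items():
            if mid not in model.metabolites:
                raise ValidationError(
                    f"cofactor {name!r} bound to unknown metabolite {mid!r}"
                )

    def reaction(self, role: str) -> str:
        if role not in self.reactions:
            raise ValidationError(f"role {role!r} is not bound")
        return self.reactions[role]


def cofactor_turnover(
    model: MetabolicModel, solution: FluxSolution, species_id: str
) -> float:
    """Total production rate of a species in a flux solution.

    ``sum_j max(0, s_ij * v_j)`` — at steady state this equals the total
    consumption rate, so it measures how fast the pool cycles
    (mmol gCDW-1 h-1).
    """
    if species_id not in model.metabolites:
        raise ValidationError(f"unknown species {species_id!r}")
    if not solution.optimal:
        raise ValidationError("turnover requires an optimal solution")
    total = 0.0
    for rid, rxn in model.reactions.items():
        coeff = rxn.stoichiometry.get(species_id)
        if coeff is not None:
            total += max(0.0, coeff * solution.fluxes[rid])
    return total


@dataclass
class ScanPoint:
    value: float
    status: str
    growth: float
    secretion: dict[str, float]
    turnover: dict[str, float]
    fluxes: dict[str, float]
    fva: dict[str, FluxRange] = field(default_factory=dict)


@dataclass
class ScanResult:
    control_role: str
    grid: list[float]
    points: list[ScanPoint]

    def feasible(self) -> list[ScanPoint]:
        return [pt for pt in self.points if pt.status == "optimal"]

    def series(self, key: str, kind: str = "secretion") -> list[float]:
        """Per-feasible-point values for one secretion/turnover/flux key."""
        return [getattr(pt, kind)[key] for pt in self.feasible()]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row: dict[str, float | str] = {
                self.control_role: pt.value,
                "status": pt.status,
                "growth": pt.growth,
            }
            row.update({f"sec_{k}": v for k, v in pt.secretion.items()})
            row.update({f"turnover_{k}": v for k, v in pt.turnover.items()})
            row.update({f"flux_{k}": v for k, v in pt.fluxes.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_ok = len(self.feasible())
        return (
            f"scan over {self.control_role}: {len(self.grid)} points, "
            f"{n_ok} optimal, grid [{self.grid[0]:g}, {self.grid[-1]:g}]"
        )


_PRODUCT_ROLES = (
    "ex_butyrate", "ex_acetate", "ex_lactate", "ex_h2", "ex_co2", "ex_formate",
)
_TRACKED_ROLES = ("pfor", "hyd", "bcd_etfab", "rnf", "atpase", "ack")


def _point(model, roles, value, status_override=None, fva_roles=()):
    sol = solve_pfba(model)
    if not sol.optimal:
        return ScanPoint(value, sol.status, float("nan"), {}, {}, {})
    growth = sol.fluxes.get(roles.reactions.get("biomass", ""), float("nan"))
    secretion = {
        role: sol.fluxes[roles.reactions[role]]
        for role in _PRODUCT_ROLES
        if role in roles.reactions
    }
    turnover = {
        name: cofactor_turnover(model, sol, mid)
        for name, mid in roles.cofactors.items()
    }
    fluxes = {
        role: sol.fluxes[roles.reactions[role]]
        for role in _TRACKED_ROLES
        if role in roles.reactions
    }
    fva = {}
    if fva_roles:
        rids = [roles.reaction(r) for r in fva_roles]
        ranges = flux_variability(model, rids, objective_fraction=1.0 - 1e-6)
        fva = {r: ranges[roles.reaction(r)] for r in fva_roles}
    return ScanPoint(value, "optimal", growth, secretion, turnover, fluxes, fva)


def production_scan(
    model: MetabolicModel,
    rolemap: RoleMap,
    role: str,
    grid: list[float],
    fva_roles: tuple[str, ...] = (),
) -> ScanResult:
    """Clamp one product exchange across a grid, re-maximising growth.

    At each grid value g the bound pair of the exchange is fixed to
    (g, g), growth is maximised, and the parsimonious representative
    fluxes and cofactor turnover rates are extracted.  Infeasible points
    are retained with their status.  The input model is not modified.
    """
    rolemap.validate(model)
    rid = rolemap.reaction(role)
    grid = [float(g) for g in grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValidationError("scan grid must be strictly increasing")
    points = []
    for g in grid:
        work = model.copy()
        work.reactions[rid].lower_bound = g
        work.reactions[rid].upper_bound = g
        points.append(_point(work, rolemap, g, fva_roles=fva_roles))
    return ScanResult(role, grid, points)


@dataclass
class SwitchReport:
    pair: tuple[str, str]
    interval: tuple[float, float] | None
    orientation: tuple[str, str] | None  # (from_role, to_role)
    forced: bool | None

    @property
    def found(self) -> bool:
        return self.interval is not None


def detect_switch(
    scan: ScanResult,
    pair: tuple[str, str],
    eps: float = 1e-6,
) -> SwitchReport:
    """Locate the grid interval over which a flux pair changes hands.

    A point is "pure A" when flux(A) > eps and flux(B) <= eps, and
    "pure B" in the mirrored case.  The reported interval runs from the
    last pure-A point to the first subsequent pure-B point (or the
    reverse orientation, whichever occurs first along the grid);
    intermediate co-expression of both fluxes stays inside the interval,
    so refining the grid never moves the switch outside it.  The
    ``forced`` flag is True iff FVA ranges at both endpoints exclude the
    alternative pattern (requires the scan to carry FVA for the pair).
    """
    role_a, role_b = pair
    feasible = scan.feasible()
    for role in pair:
        if any(role not in pt.fluxes for pt in feasible):
            raise ValidationError(f"role {role!r} was not tracked in the scan")

    def state(pt):
        a, b = pt.fluxes[role_a], pt.fluxes[role_b]
        if a > eps and b <= eps:
            return "A"
        if b > eps and a <= eps:
            return "B"
        return "-"

    states = [state(pt) for pt in feasible]
    best = None
    for j, sj in enumerate(states):
        if sj not in ("A", "B"):
            continue
        opposite = "B" if sj == "A" else "A"
        prior = [i for i in range(j) if states[i] == opposite]
        if prior:
            best = (prior[-1], j)
            break
    if best is None:
        return SwitchReport(pair, None, None, None)
    i, j = best
    orientation = (
        (role_a, role_b) if states[i] == "A" else (role_b, role_a)
    )
    forced = None
    pt_i, pt_j = feasible[i], feasible[j]
    if role_a in pt_i.fva and role_b in pt_i.fva and role_a in pt_j.fva and role_b in pt_j.fva:
        from_role, to_role = orientation
        forced = (
            pt_i.fva[to_role].max_flux <= eps
            and pt_i.fva[from_role].min_flux > eps
            and pt_j.fva[from_role].max_flux <= eps
            and pt_j.fva[to_role].min_flux > eps
        )
    return SwitchReport(pair, (pt_i.value, pt_j.value), orientation, forced)


def two_flux_scan(
    model: MetabolicModel,
    rolemap: RoleMap,
    role_a: str,
    role_b: str,
    grid_a: list[float],
    grid_b: list[float] | None = None,
    record_role: str = "ex_acetate",
) -> pd.DataFrame:
    """Clamp two reaction fluxes on a grid; record a product exchange.

    Returns a DataFrame indexed by the role-A grid with role-B grid
    columns; entries are the recorded exchange flux at maximal growth,
    NaN where the point is infeasible.
    """
    rolemap.validate(model)
    rid_a = rolemap.reaction(role_a)
    rid_b = rolemap.reaction(role_b)
    rid_out = rolemap.reaction(record_role)
    if grid_b is None:
        grid_b = list(grid_a)
    out = np.full((len(grid_a), len(grid_b)), np.nan)
    for i, a in enumerate(grid_a):
        for j, b in enumerate(grid_b):
            work = model.copy()
            work.reactions[rid_a].lower_bound = a
            work.reactions[rid_a].upper_bound = a
            work.reactions[rid_b].lower_bound = b
            work.reactions[rid_b].upper_bound = b
            sol = solve_pfba(work)
            if sol.optimal:
                out[i, j] = sol.fluxes[rid_out]
    return pd.DataFrame(
        out,
        index=pd.Index(grid_a, name=role_a),
        columns=pd.Index(grid_b, name=role_b),
    )
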