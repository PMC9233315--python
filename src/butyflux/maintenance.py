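"""Maintenance-energy (GAM/NGAM) embedding and fitting.

Growth-associated maintenance (GAM, mmol ATP per gCDW) lives inside the
biomass reaction as an ATP-hydrolysis term; non-growth-associated
maintenance (NGAM, mmol ATP gCDW-1 h-1) is the lower bound of a
dedicated ATP-hydrolysis reaction.  Because simulated growth is
monotone non-increasing in GAM, fitting GAM to an observed specific
growth rate is a one-dimensional bisection, not a least-squares
problem.  Specific-rate constraints are derived from fermentation time
series via the usual dry-cell-weight normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import MetabolicModel, ValidationError
from .fba import solve_fba

__all__ = [
    "MaintenanceParams",
    "RateConstraint",
    "BracketError",
    "apply_maintenance",
    "fit_gam",
    "GamFitResult",
    "rates_from_timeseries",
    "apply_rate_constraints",
]

#: default species ids used by maintenance bookkeeping
ATP_SPECIES = {
    "atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h2o": "h2o_c", "h": "h_c"
}


@dataclass
class MaintenanceParams:
    gam: float
    ngam: float
    atpm_reaction_id: str = "ATPM"
    biomass_reaction_id: str = "BIOMASS"

    def validate(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValidationError("gam and ngam must be nonnegative")


@dataclass
class RateConstraint:
    """Fix (or bracket) one exchange flux, mmol gCDW-1 h-1; uptake < 0."""

    exchange_id: str
    lower: float
    upper: float | None = None

    def bounds(self) -> tuple[float, float]:
        ub = self.lower if self.upper is None else self.upper
        if self.lower > ub:
            raise ValidationError(
                f"rate constraint on {self.exchange_id!r}: lb {self.lower} > ub {ub}"
            )
        return self.lower, ub


class BracketError(ValueError):
    """The observed growth rate is outside the attainable range."""


def apply_maintenance(
    model: MetabolicModel,
    params: MaintenanceParams,
    species: dict[str, str] | None = None,
) -> MetabolicModel:
    """Return a copy with GAM embedded in biomass and NGAM as ATPM lb."""
    params.validate()
    sp = dict(ATP_SPECIES)
    if species:
        sp.update(species)
    for rid in (params.atpm_reaction_id, params.biomass_reaction_id):
        if rid not in model.reactions:
            raise ValidationError(f"maintenance reaction {rid!r} not in model")
    new = model.copy()
    atpm = new.reactions[params.atpm_reaction_id]
    if atpm.stoichiometry.get(sp["atp"], 0.0) >= 0:
        raise ValidationError(
            f"ATPM reaction {atpm.id!r} must consume {sp['atp']!r}"
        )
    atpm.lower_bound = params.ngam
    biomass = new.reactions[params.biomass_reaction_id]
    for key in ("atp", "adp", "pi", "h2o", "h"):
        mid = sp[key]
        if mid in new.metabolites or key in ("atp", "adp", "pi", "h2o"):
            biomass.stoichiometry.pop(mid, None)
    if params.gam > 0:
        for key, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1)):
            mid = sp[key]
            if mid not in new.metabolites:
                raise ValidationError(
                    f"biomass reaction needs species {mid!r} for GAM"
                )
            biomass.stoichiometry[mid] = sign * params.gam
        if sp["h"] in new.metabolites:
            biomass.stoichiometry[sp["h"]] = params.gam
    new.validate()
    return new


@dataclass
class GamFitResult:
    gam: float
    mu: float
    observed_mu: float
    bracket: tuple[float, float]
    n_iterations: int

    def summary(self) -> str:
        return (
            f"GAM fit: {self.gam:.3f} mmol ATP/gCDW "
            f"(mu = {self.mu:.4f} vs observed {self.observed_mu:.4f} h^-1, "
            f"bracket +/- {0.5 * (self.bracket[1] - self.bracket[0]):.3g}, "
            f"{self.n_iterations} bisections)"
        )


def fit_gam(
    model: MetabolicModel,
    observed_mu: float,
    ngam: float,
    search: tuple[float, float] = (0.0, 100.0),
    tol: float = 0.01,
    atpm_reaction_id: str = "ATPM",
    biomass_reaction_id: str = "BIOMASS",
    constraints: list[RateConstraint] | None = None,
    species: dict[str, str] | None = None,
) -> GamFitResult:
    """Bisect GAM so simulated growth matches an observed rate.

    Requires the observed rate to lie between the growth attainable at
    the two ends of the search bracket (growth is monotone
    non-increasing in GAM); otherwise raises :class:`BracketError`
    stating the attainable range.
    """
    work = model.copy()
    if constraints:
        work = apply_rate_constraints(work, constraints)

    def mu_at(gam: float) -> float:
        m = apply_maintenance(
            work,
            MaintenanceParams(gam, ngam, atpm_reaction_id, biomass_reaction_id),
            species,
        )
        sol = solve_fba(m, biomass_reaction_id)
        return sol.objective_value if sol.optimal else 0.0

    lo, hi = float(search[0]), float(search[1])
    mu_lo, mu_hi = mu_at(lo), mu_at(hi)
    if not (mu_hi <= observed_mu <= mu_lo):
        raise BracketError(
            f"observed growth {observed_mu:g} h^-1 outside attainable range "
            f"[{mu_hi:g}, {mu_lo:g}] for GAM in [{lo:g}, {hi:g}]"
        )
    # strict comparison: on a flat stretch of mu(gam) the bracket slides
    # to the smallest gam reproducing the observation
    n = 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mu_at(mid) > observed_mu:
            lo = mid
        else:
            hi = mid
        n += 1
    gam = 0.5 * (lo + hi)
    return GamFitResult(gam, mu_at(gam), observed_mu, (lo, hi), n)


def apply_rate_constraints(
    model: MetabolicModel, constraints: list[RateConstraint]
) -> MetabolicModel:
    new = model.copy()
    for con in constraints:
        if con.exchange_id not in new.reactions:
            raise ValidationError(f"unknown exchange {con.exchange_id!r}")
        lb, ub = con.bounds()
        rxn = new.reactions[con.exchange_id]
        rxn.lower_bound, rxn.upper_bound = lb, ub
    return new


def rates_from_timeseries(
    series: pd.DataFrame,
    interval: tuple[float, float],
    molar_mass: dict[str, float],
    dcw_per_od: float = 0.30,
    time_column: str = "time",
    od_column: str = "od600",
) -> tuple[dict[str, float], float]:
    """Specific rates and growth rate from a fermentation time series.

    ``series`` has a time column (h), an OD600 column and one
    concentration column (g/L) per analyte named in ``molar_mass``
    (g/mol).  Over ``interval`` the specific rate of an analyte is
    (delta concentration / delta t) / mean biomass, converted to
    mmol gCDW-1 h-1 (uptake negative), with biomass = OD600 x
    ``dcw_per_od`` g DCW/L.  The specific growth rate is
    ln(X2/X1)/delta t.  Returns ``({analyte: rate}, mu)``.
    """
    for col in (time_column, od_column):
        if col not in series.columns:
            raise ValidationError(f"time series lacks column {col!r}")
    t0, t1 = interval
    window = series[(series[time_column] >= t0) & (series[time_column] <= t1)]
    if len(window) < 2:
        raise ValidationError("need at least two time points inside the interval")
    first, last = window.iloc[0], window.iloc[-1]
    dt = float(last[time_column] - first[time_column])
    x1 = float(first[od_column]) * dcw_per_od
    x2 = float(last[od_column]) * dcw_per_od
    if x1 <= 0 or x2 <= 0:
        raise ValidationError("nonpositive biomass in the interval")
    x_mean = 0.5 * (x1 + x2)
    rates = {}
    for analyte, mass in molar_mass.items():
        if analyte not in series.columns:
            raise ValidationError(f"time series lacks column {analyte!r}")
        dconc = float(last[analyte] - first[analyte])  # g/L
        rates[analyte] = (dconc / dt) / x_mean * 1000.0 / mass
    mu = math.log(x2 / x1) / dt
    return rates, mu
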