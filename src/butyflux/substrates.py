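"""Qualitative in-silico growth tests on sole carbon/nitrogen sources.

Mirrors the standard model-validation exercise: close every alternative
substrate exchange to uptake, open one, and ask whether flux balance
analysis still predicts growth above a small threshold.  The resulting
yes/no matrix is compared against an in-vivo reference panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import MetabolicModel, ValidationError, parse_formula
from .fba import solve_fba

__all__ = ["SubstrateEntry", "test_substrate", "utilization_matrix"]

MU_THRESHOLD = 1e-4


@dataclass
class SubstrateEntry:
    name: str
    exchange_id: str
    klass: str  # "carbon" | "nitrogen"
    in_vivo: bool


def _element_exchanges(model: MetabolicModel, element: str) -> list[str]:
    """Exchanges whose metabolite contains the given element."""
    out = []
    for rxn in model.exchanges:
        (mid,) = rxn.stoichiometry
        met = model.metabolites[mid]
        if met.formula is None:
            continue
        try:
            counts = parse_formula(met.formula)
        except ValidationError:
            continue
        if counts.get(element, 0) > 0:
            out.append(rxn.id)
    return out


def test_substrate(
    model: MetabolicModel,
    exchange_id: str,
    klass: str = "carbon",
    uptake_bound: float = 10.0,
    mu_threshold: float = MU_THRESHOLD,
    glucose_exchange: str = "EX_glc",
    element_exchanges: list[str] | None = None,
) -> bool:
    """Can the model grow with this exchange as the sole C (or N) source?

    For a carbon test, every carbon-containing exchange is closed to
    uptake and the tested one opened to ``-uptake_bound``.  For a
    nitrogen test the glucose exchange keeps its bounds and every
    nitrogen-containing exchange except the tested one is closed.  The
    input model is not modified.
    """
    if exchange_id not in model.reactions:
        raise ValidationError(f"unknown exchange {exchange_id!r}")
    if klass not in ("carbon", "nitrogen"):
        raise ValidationError(f"substrate class must be carbon or nitrogen, got {klass!r}")
    element = "C" if klass == "carbon" else "N"
    closed = element_exchanges
    if closed is None:
        closed = _element_exchanges(model, element)
    work = model.copy()
    for rid in closed:
        if rid == exchange_id:
            continue
        if klass == "nitrogen" and rid == glucose_exchange:
            continue
        work.reactions[rid].lower_bound = 0.0
    work.reactions[exchange_id].lower_bound = -abs(uptake_bound)
    sol = solve_fba(work)
    return sol.optimal and sol.objective_value >= mu_threshold


test_substrate.__test__ = False  # not a pytest test despite the name


def utilization_matrix(
    model: MetabolicModel,
    panel: list[SubstrateEntry],
    uptake_bound: float = 10.0,
    mu_threshold: float = MU_THRESHOLD,
    glucose_exchange: str = "EX_glc",
) -> tuple[pd.DataFrame, int]:
    """Run the whole panel; return (table, agreement count).

    The table has one row per substrate with in-vivo growth, in-silico
    growth and their agreement; the count is the number of agreeing rows.
    """
    names = [e.name for e in panel]
    if len(set(names)) != len(names):
        raise ValidationError("substrate names must be unique")
    rows = []
    for entry in panel:
        grows = test_substrate(
            model,
            entry.exchange_id,
            entry.klass,
            uptake_bound,
            mu_threshold,
            glucose_exchange,
        )
        rows.append(
            {
                "substrate": entry.name,
                "class": entry.klass,
                "in_vivo": entry.in_vivo,
                "in_silico": grows,
                "agree": grows == entry.in_vivo,
            }
        )
    df = pd.DataFrame(
        rows, columns=["substrate", "class", "in_vivo", "in_silico", "agree"]
    )
    n_agree = int(df["agree"].sum()) if rows else 0
    return df, n_agree
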