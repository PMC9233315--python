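"""In-memory representation of constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric reconstruction: metabolites
partitioned into compartments, reactions with bounded fluxes (mmol gCDW^-1
h^-1; the biomass reaction in h^-1), boolean gene rules, and a designated
objective reaction.  The sign convention is the usual one: negative
stoichiometric coefficients are substrates, positive are products, and
reversibility is encoded purely by ``lower_bound < 0``.  Exchange reactions
carry a single extracellular (or declared-boundary) metabolite; positive
exchange flux is secretion, negative is uptake.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ValidationError",
    "build_stoich_matrix",
    "parse_formula",
    "check_mass_balance",
    "model_summary",
    "knockout",
    "orf_coverage",
]

_ID_RE = re.compile(r"^\S+$")
_GENE_TOKEN_RE = re.compile(r"[A-Za-z0-9_.\-]+")
_FORMULA_TOKEN_RE = re.compile(r"([A-Z][a-z]*)(\d*\.?\d*)")


class ValidationError(ValueError):
    """A model violates a structural invariant."""


@dataclass
class Metabolite:
    """A chemical species located in one compartment.

    ``boundary`` marks pseudo-species (e.g. a biomass sink species) whose
    drain reactions are treated as exchanges.
    """

    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = "c"
    boundary: bool = False


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: str = ""
    subsystem: str = ""
    ec_number: str | None = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


def _parse_gene_rule(rule: str) -> set[str]:
    tokens = set(_GENE_TOKEN_RE.findall(rule))
    return {t for t in tokens if t.lower() not in ("and", "or")}


class MetabolicModel:
    """A validated collection of metabolites and reactions.

    Metabolites and reactions keep insertion order; the stoichiometric
    matrix and the LP variable ordering follow it, which makes all
    downstream solves deterministic.
    """

    def __init__(
        self,
        id: str = "model",
        compartments: Mapping[str, str] | None = None,
        objective_reaction_id: str | None = None,
    ):
        self.id = id
        self.compartments: dict[str, str] = dict(compartments or {})
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_reaction_id = objective_reaction_id

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if not _ID_RE.match(met.id or ""):
            raise ValidationError(f"invalid metabolite id {met.id!r}")
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise ValidationError(
                f"metabolite {met.id!r} references unknown compartment "
                f"{met.compartment!r}"
            )
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if not _ID_RE.match(rxn.id or ""):
            raise ValidationError(f"invalid reaction id {rxn.id!r}")
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
        if rxn.lower_bound > rxn.upper_bound:
            raise ValidationError(
                f"reaction {rxn.id!r}: lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in self.metabolites:
                raise ValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            if not np.isfinite(coeff) or coeff == 0.0:
                raise ValidationError(
                    f"reaction {rxn.id!r}: coefficient of {met_id!r} must be "
                    f"finite and nonzero, got {coeff}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    # -- derived properties -------------------------------------------
    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= _parse_gene_rule(rxn.gene_rule)
        return out

    def is_exchange(self, rxn: Reaction) -> bool:
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        met = self.metabolites[met_id]
        return met.compartment == "e" or met.boundary

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if self.is_exchange(r)]

    def validate(self) -> None:
        """Re-check every structural invariant; raise on the first failure."""
        if self.objective_reaction_id is not None and (
            self.objective_reaction_id not in self.reactions
        ):
            raise ValidationError(
                f"objective reaction {self.objective_reaction_id!r} does not exist"
            )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ValidationError(
                    f"metabolite {met.id!r} references unknown compartment "
                    f"{met.compartment!r}"
                )
        for rxn in self.reactions.values():
            if not rxn.stoichiometry:
                raise ValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise ValidationError(f"reaction {rxn.id!r} has crossed bounds")
            for met_id, coeff in rxn.stoichiometry.items():
                if met_id not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
                if not np.isfinite(coeff) or coeff == 0.0:
                    raise ValidationError(
                        f"reaction {rxn.id!r}: coefficient of {met_id!r} is "
                        f"{coeff}"
                    )

    def copy(self) -> "MetabolicModel":
        new = MetabolicModel(self.id, dict(self.compartments), self.objective_reaction_id)
        for met in self.metabolites.values():
            new.metabolites[met.id] = replace(met)
        for rxn in self.reactions.values():
            new.reactions[rxn.id] = rxn.copy()
        return new

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites>"
        )


# ---------------------------------------------------------------------
def build_stoich_matrix(
    model: MetabolicModel,
) -> tuple[np.ndarray, dict[str, int], dict[str, int]]:
    """Assemble the stoichiometric matrix S (metabolites x reactions).

    Returns ``(S, met_index, rxn_index)`` where the index maps are
    bijections from identifier to row/column, in model insertion order.
    """
    model.validate()
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(met_index), len(rxn_index)))
    for rid, rxn in model.reactions.items():
        j = rxn_index[rid]
        for met_id, coeff in rxn.stoichiometry.items():
            S[met_index[met_id], j] = coeff
    return S, met_index, rxn_index


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula like ``C6H12O6`` into element counts.

    Pseudo-elements (any capitalised symbol, e.g. ``X`` for a CoA moiety)
    are allowed; they let lumped reactions balance exactly.
    """
    if formula is None or formula == "":
        raise ValidationError(f"unparseable formula {formula!r}")
    pos = 0
    counts: dict[str, float] = {}
    for match in _FORMULA_TOKEN_RE.finditer(formula):
        if match.start() != pos:
            raise ValidationError(f"unparseable formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
    if pos != len(formula) or not counts:
        raise ValidationError(f"unparseable formula {formula!r}")
    return counts


def _default_exempt(model: MetabolicModel) -> set[str]:
    # protons in either compartment, and biomass pseudo-species
    out = set()
    for met in model.metabolites.values():
        base = met.id.rsplit("_", 1)[0].lower()
        if base in ("h", "h+", "biomass") or met.boundary:
            out.add(met.id)
    return out


def check_mass_balance(
    model: MetabolicModel,
    exempt_metabolites: Iterable[str] | None = None,
    tol: float = 1e-6,
) -> dict[str, dict[str, float]]:
    """Report elementally unbalanced non-exchange reactions.

    A reaction is flagged iff for some element the signed sum of
    coefficient x element-count deviates from zero by more than ``tol``.
    Exchange reactions and reactions touching exempt metabolites (by
    default intra-/extracellular protons and biomass pseudo-species) are
    skipped.  Returns ``{reaction_id: {element: net_excess}}``.
    """
    exempt = (
        set(exempt_metabolites) if exempt_metabolites is not None else _default_exempt(model)
    )
    unknown = exempt - set(model.metabolites)
    if exempt_metabolites is not None and unknown:
        raise ValidationError(f"unknown exempt metabolites: {sorted(unknown)}")
    flagged: dict[str, dict[str, float]] = {}
    for rxn in model.reactions.values():
        if model.is_exchange(rxn):
            continue
        if any(met_id in exempt for met_id in rxn.stoichiometry):
            continue
        balance: dict[str, float] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.formula is None:
                raise ValidationError(
                    f"metabolite {met_id!r} in reaction {rxn.id!r} has no formula"
                )
            for element, count in parse_formula(met.formula).items():
                balance[element] = balance.get(element, 0.0) + coeff * count
        deficits = {el: v for el, v in balance.items() if abs(v) > tol}
        if deficits:
            flagged[rxn.id] = deficits
    return flagged


@dataclass
class ModelSummary:
    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_exchanges: int
    n_gene_associated: int
    n_non_gene_associated: int
    by_subsystem: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"reactions:   {self.n_reactions}\n"
            f"metabolites: {self.n_metabolites}\n"
            f"genes:       {self.n_genes}\n"
            f"exchanges:   {self.n_exchanges}\n"
            f"gene-associated reactions: {self.n_gene_associated}\n"
        )
        return head + self.by_subsystem.to_string()


def model_summary(model: MetabolicModel) -> ModelSummary:
    """Count reactions/metabolites/genes and gene association per subsystem."""
    rows = []
    for rxn in model.reactions.values():
        rows.append(
            {
                "subsystem": rxn.subsystem or "(unassigned)",
                "gene_associated": bool(rxn.gene_rule.strip()),
            }
        )
    if rows:
        df = pd.DataFrame(rows)
        by = (
            df.groupby("subsystem")["gene_associated"]
            .agg(gene_associated="sum", total="count")
            .astype(int)
        )
        by["non_gene_associated"] = by["total"] - by["gene_associated"]
        by = by[["total", "gene_associated", "non_gene_associated"]].sort_index()
        n_ga = int(df["gene_associated"].sum())
    else:
        by = pd.DataFrame(
            columns=["total", "gene_associated", "non_gene_associated"]
        ).rename_axis("subsystem")
        n_ga = 0
    return ModelSummary(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
        n_exchanges=len(model.exchanges),
        n_gene_associated=n_ga,
        n_non_gene_associated=len(model.reactions) - n_ga,
        by_subsystem=by,
    )


def knockout(model: MetabolicModel, reaction_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy of the model with both bounds of each reaction set to 0.

    The original model is untouched.  Unknown ids raise, listing all of them.
    """
    ids = list(reaction_ids)
    missing = [r for r in ids if r not in model.reactions]
    if missing:
        raise ValidationError(f"cannot knock out unknown reactions: {missing}")
    new = model.copy()
    for rid in ids:
        new.reactions[rid].lower_bound = 0.0
        new.reactions[rid].upper_bound = 0.0
    return new


def orf_coverage(n_model_genes: int, n_orfs: int) -> float:
    """Percentage of genome ORFs captured by the model's gene set."""
    if n_orfs <= 0:
        raise ValueError("n_orfs must be positive")
    return 100.0 * n_model_genes / n_orfs
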