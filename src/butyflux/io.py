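"""Readers and writers for metabolic models and fermentation data.

Three model formats are supported:

* SBML Level 3 (core + the fbc package for flux bounds and the
  objective); gene rules, subsystems and EC numbers travel in
  COBRA-style notes, and fbc gene-product associations are read when
  present.
* a JSON dialect that is lossless for every field of the data model and
  diff-stable (canonical key order, 12 significant digits),
* a tab-separated reaction table with human-readable equations
  (``2 A[c] + B[c] <=> C[e]``), the format used for supplementary
  reaction lists.

plus a reader for fermentation time-series tables (time, OD600,
concentrations) used to derive specific-rate constraints.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import pandas as pd

from .core import MetabolicModel, Metabolite, Reaction, ValidationError

__all__ = [
    "read_sbml", "write_sbml",
    "read_json", "write_json",
    "read_reaction_table", "write_reaction_table",
    "read_timeseries",
]

logger = logging.getLogger(__name__)

_SIG = 12


def _fmt(x: float) -> float:
    """Round to 12 significant digits for diff-stable serialisation."""
    return float(f"{x:.{_SIG}g}")


# ------------------------------------------------------------------ JSON
def write_json(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "id": model.id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
                "boundary": m.boundary,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: _fmt(v) for k, v in r.stoichiometry.items()},
                "lower_bound": _fmt(r.lower_bound),
                "upper_bound": _fmt(r.upper_bound),
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
                "ec_number": r.ec_number,
            }
            for r in model.reactions.values()
        ],
        "objective_reaction_id": model.objective_reaction_id,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> MetabolicModel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in {path}: {exc}") from exc
    for key in ("compartments", "metabolites", "reactions"):
        if key not in doc:
            raise ValidationError(f"JSON model misses key $.{key}")
    model = MetabolicModel(
        doc.get("id", "model"),
        doc["compartments"],
        doc.get("objective_reaction_id"),
    )
    for i, m in enumerate(doc["metabolites"]):
        try:
            model.add_metabolite(
                Metabolite(
                    m["id"], m.get("name", ""), m.get("formula"),
                    m.get("charge"), m.get("compartment", "c"),
                    bool(m.get("boundary", False)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"bad metabolite at $.metabolites[{i}]: {exc}")
    for i, r in enumerate(doc["reactions"]):
        try:
            lb, ub = r["lower_bound"], r["upper_bound"]
            if not isinstance(lb, (int, float)) or not isinstance(ub, (int, float)):
                raise ValidationError(
                    f"bounds must be numbers at $.reactions[{i}]"
                )
            model.add_reaction(
                Reaction(
                    r["id"], r.get("name", ""),
                    {k: float(v) for k, v in r["stoichiometry"].items()},
                    float(lb), float(ub), r.get("gene_rule", ""),
                    r.get("subsystem", ""), r.get("ec_number"),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"missing field {exc} at $.reactions[{i}]")
    model.validate()
    return model


# ------------------------------------------------------------------ SBML
def _sanitize(sid: str) -> str:
    # SBML SIds must match [a-zA-Z_][a-zA-Z0-9_]*
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml = doc.createModel()
    sbml.setId(_sanitize(model.id))
    mplug = sbml.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in model.compartments.items():
        comp = sbml.createCompartment()
        comp.setId(_sanitize(cid))
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml.createSpecies()
        sp.setId("M_" + _sanitize(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.boundary)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"fb_{len(bounds_seen)}"
            par = sbml.createParameter()
            par.setId(pid)
            par.setValue(_fmt(value))
            par.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for rxn in model.reactions.values():
        sr = sbml.createReaction()
        sr.setId("R_" + _sanitize(rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        for met_id, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + _sanitize(met_id))
            ref.setStoichiometry(abs(_fmt(coeff)))
            ref.setConstant(True)
        notes = []
        if rxn.gene_rule:
            notes.append(f"GENE_ASSOCIATION: {rxn.gene_rule}")
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        if rxn.ec_number:
            notes.append(f"EC Number: {rxn.ec_number}")
        if notes:
            body = "".join(f"<p>{n}</p>" for n in notes)
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )

    if model.objective_reaction_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sanitize(model.objective_reaction_id))
        fo.setCoefficient(1.0)

    writer = libsbml.SBMLWriter()
    writer.setProgramName("butyflux")
    writer.setProgramVersion("0")
    if writer.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


_NOTE_KEYS = {
    "GENE_ASSOCIATION": "gene_rule",
    "GENE ASSOCIATION": "gene_rule",
    "SUBSYSTEM": "subsystem",
    "EC NUMBER": "ec_number",
}


def _parse_notes(notes_str: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in re.findall(r"<p>(.*?)</p>", notes_str, flags=re.S):
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        field = _NOTE_KEYS.get(key.strip().upper())
        if field:
            out[field] = value.strip()
    return out


def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def read_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ValidationError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    sbml = doc.getModel()
    if sbml is None:
        raise ValidationError(f"{path} contains no SBML model")
    for attr, label in (("getNumRules", "rules"), ("getNumEvents", "events"),
                        ("getNumConstraints", "constraints")):
        n = getattr(sbml, attr)() if hasattr(sbml, attr) else 0
        if n:
            logger.warning("ignoring %d unsupported SBML %s in %s", n, label, path)

    model = MetabolicModel(id=sbml.getId() or "model")
    for i in range(sbml.getNumCompartments()):
        comp = sbml.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()
    for i in range(sbml.getNumSpecies()):
        sp = sbml.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                _strip_prefix(sp.getId(), "M_"), sp.getName(), formula,
                charge, sp.getCompartment(), sp.getBoundaryCondition(),
            )
        )

    params = {}
    for i in range(sbml.getNumParameters()):
        par = sbml.getParameter(i)
        params[par.getId()] = par.getValue()

    for i in range(sbml.getNumReactions()):
        sr = sbml.getReaction(i)
        rid = _strip_prefix(sr.getId(), "R_")
        stoich: dict[str, float] = {}
        for ref, sign in [(sr.getReactant(j), -1.0) for j in range(sr.getNumReactants())] + [
            (sr.getProduct(j), 1.0) for j in range(sr.getNumProducts())
        ]:
            sid = _strip_prefix(ref.getSpecies(), "M_")
            if sid not in model.metabolites:
                raise ValidationError(
                    f"reaction {rid!r} references undefined species {ref.getSpecies()!r}"
                )
            stoich[sid] = stoich.get(sid, 0.0) + sign * ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        rplug = sr.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
        if lb is None or ub is None:
            raise ValidationError(f"reaction {rid!r} has no flux bounds")
        fields = {"gene_rule": "", "subsystem": "", "ec_number": None}
        if sr.isSetNotes():
            fields.update(_parse_notes(sr.getNotesString()))
        if rplug is not None and not fields["gene_rule"]:
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                assoc = gpa.getAssociation()
                if assoc is not None:
                    fields["gene_rule"] = assoc.toInfix()
        model.add_reaction(
            Reaction(rid, sr.getName(), stoich, float(lb), float(ub),
                     fields["gene_rule"], fields["subsystem"], fields["ec_number"])
        )

    mplug = sbml.getPlugin("fbc")
    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_reaction_id = _strip_prefix(
                obj.getFluxObjective(0).getReaction(), "R_"
            )
    model.validate()
    return model


# ------------------------------------------------- reaction-table TSV
TABLE_COLUMNS = [
    "id", "equation", "lower_bound", "upper_bound",
    "gene_rule", "subsystem", "ec_number",
]
_TERM_RE = re.compile(r"^(?:(\d+\.?\d*|\.\d+)\s+)?(\S+?)\[(\w+)\]$")


def _parse_equation(eq: str, row: int) -> tuple[dict[str, tuple[str, float]], bool]:
    """Parse ``2 A[c] + B[c] <=> C[e]`` into {met_id: (compartment, coeff)}."""
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>", 1)
        reversible = True
    elif "-->" in eq:
        lhs, rhs = eq.split("-->", 1)
        reversible = False
    else:
        raise ValidationError(
            f"row {row}: equation {eq!r} lacks an arrow ('<=>' or '-->')"
        )
    stoich: dict[str, tuple[str, float]] = {}

    def side(text: str, sign: float) -> None:
        text = text.strip()
        if not text:
            return
        for term in text.split(" + "):
            term = term.strip()
            m = _TERM_RE.match(term)
            if not m:
                raise ValidationError(
                    f"row {row}: cannot parse equation term {term!r}"
                )
            coeff_s, met, comp = m.groups()
            coeff = sign * (float(coeff_s) if coeff_s else 1.0)
            key = f"{met}_{comp}"
            prev = stoich.get(key, (comp, 0.0))[1]
            stoich[key] = (comp, prev + coeff)

    side(lhs, -1.0)
    side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v[1] != 0.0}
    if not stoich:
        raise ValidationError(f"row {row}: equation {eq!r} has empty stoichiometry")
    return stoich, reversible


def read_reaction_table(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Build a model from a supplementary-style TSV reaction list.

    Required columns ``id`` and ``equation``; optional bounds, gene rule,
    subsystem and EC columns; extra columns are ignored.  When bound
    columns are absent, the arrow decides: ``<=>`` -> (-1000, 1000),
    ``-->`` -> (0, 1000).  Compartment suffixes ``[c]``/``[e]`` map onto
    compartments; single-metabolite extracellular rows act as exchanges.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("id", "equation"):
        if col not in df.columns:
            raise ValidationError(f"reaction table lacks required column {col!r}")
    model = MetabolicModel(id=model_id or Path(path).stem)
    for _, rec in df.iterrows():
        row = int(rec.name) + 2  # header is line 1
        stoich, reversible = _parse_equation(rec["equation"], row)
        for met_id, (comp, _) in stoich.items():
            if comp not in model.compartments:
                model.compartments[comp] = comp
            if met_id not in model.metabolites:
                model.add_metabolite(Metabolite(met_id, compartment=comp))
        lb_s = rec.get("lower_bound", "")
        ub_s = rec.get("upper_bound", "")
        try:
            lb = float(lb_s) if lb_s != "" else (-1000.0 if reversible else 0.0)
            ub = float(ub_s) if ub_s != "" else 1000.0
        except ValueError:
            raise ValidationError(f"row {row}: non-numeric bound {lb_s!r}/{ub_s!r}")
        model.add_reaction(
            Reaction(
                rec["id"].strip(), rec.get("name", "") or rec["id"].strip(),
                {k: v[1] for k, v in stoich.items()}, lb, ub,
                rec.get("gene_rule", ""), rec.get("subsystem", ""),
                rec.get("ec_number") or None,
            )
        )
    # objective: the biomass-producing reaction (largest stoichiometry
    # among reactions mentioning biomass; sinks/exchanges carry one term)
    candidates = [
        rid for rid in model.reactions
        if "biomass" in rid.lower() or "biomass" in model.reactions[rid].name.lower()
    ]
    if candidates:
        model.objective_reaction_id = max(
            candidates, key=lambda r: len(model.reactions[r].stoichiometry)
        )
    model.validate()
    return model


def write_reaction_table(model: MetabolicModel, path: str | Path) -> None:
    rows = []
    for rxn in model.reactions.values():
        def term(met_id: str, coeff: float) -> str:
            met = model.metabolites[met_id]
            base = met_id
            if base.endswith(f"_{met.compartment}"):
                base = base[: -len(met.compartment) - 1]
            c = abs(_fmt(coeff))
            prefix = "" if c == 1 else f"{c:g} "
            return f"{prefix}{base}[{met.compartment}]"

        lhs = " + ".join(term(m, c) for m, c in rxn.stoichiometry.items() if c < 0)
        rhs = " + ".join(term(m, c) for m, c in rxn.stoichiometry.items() if c > 0)
        arrow = "<=>" if rxn.reversible else "-->"
        rows.append(
            {
                "id": rxn.id,
                "equation": f"{lhs} {arrow} {rhs}".strip(),
                "lower_bound": _fmt(rxn.lower_bound),
                "upper_bound": _fmt(rxn.upper_bound),
                "gene_rule": rxn.gene_rule,
                "subsystem": rxn.subsystem,
                "ec_number": rxn.ec_number or "",
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- time series
def read_timeseries(path: str | Path, time_column: str = "time") -> pd.DataFrame:
    """Read a fermentation time series (TSV or CSV).

    Requires a strictly increasing time column (hours); all other
    columns are numeric (OD600 dimensionless, concentrations g/L).
    Units are recorded in ``df.attrs["units"]``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if time_column not in df.columns:
        raise ValidationError(f"time series lacks column {time_column!r}")
    t = df[time_column].to_numpy()
    if len(t) and not all(b > a for a, b in zip(t, t[1:])):
        raise ValidationError("time column must be strictly increasing")
    df = df.apply(pd.to_numeric)
    df.attrs["units"] = {
        c: ("h" if c == time_column else "" if c == "od600" else "g/L")
        for c in df.columns
    }
    return df
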