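"""Generator for a clostridial butyrate-fermentation core network.

The generated model is a compact, fully curated stand-in for a
genome-scale reconstruction of *Clostridium tyrobutyricum*-type
metabolism.  It contains the pathways that carry essentially all
catabolic flux in acidogenic clostridia:

* lumped glycolysis (glucose -> 2 pyruvate, 2 ATP, 2 NADH),
* pyruvate:ferredoxin oxidoreductase (PFOR) and pyruvate formate-lyase,
* lactate dehydrogenase,
* phosphotransacetylase/acetate kinase (lumped, reversible),
* the butyryl-CoA chain (thiolase, HBD, crotonase) with the
  flavin-based electron-bifurcating butyryl-CoA dehydrogenase/EtfAB
  (crotonyl-CoA + 2 NADH + Fd_ox -> butyryl-CoA + 2 NAD+ + Fd_red),
* butyrate formation exclusively through butyryl-CoA:acetate
  CoA-transferase (so butyrate production recycles acetate and keeps
  the acetate-kinase ATP),
* the two ferredoxin redox loops: a ferredoxin-only [FeFe]-hydrogenase
  (HydA) and the proton-pumping Rnf complex, closed over the FoF1
  ATPase and proton-coupled acid export,
* a biomass drain with growth-associated maintenance (GAM) and a
  separate ATP-hydrolysis reaction whose lower bound is the
  non-growth-associated maintenance (NGAM).

Reduced ferredoxin is produced only by PFOR and Bcd/EtfAB and consumed
only by HydA, Rnf and the ferredoxin:NADP+ reductase, so the coupling
between butyrate flux, H2/CO2 emission, proton efflux and ATP synthesis
is structural, not fitted.

Stoichiometric choices that the literature leaves open (protons
translocated per ferredoxin by Rnf, protons per ATP for the ATPase,
biomass composition) are parameters of :class:`CoreParams`; the defaults
are discussed in the methods document.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .core import MetabolicModel, Metabolite, Reaction, ValidationError
from .scan import RoleMap

__all__ = ["CoreParams", "build_core_model", "build_toy_model", "random_model"]


@dataclass
class CoreParams:
    """Tunable parameters of the core network.

    glucose_uptake_max : maximal specific glucose uptake, mmol gCDW-1 h-1.
        The default mirrors a measured bioreactor uptake rate; the
        product-coupling scans are meant to run under carbon limitation.
    gam, ngam : growth- and non-growth-associated maintenance,
        mmol ATP gCDW-1 (per unit growth) and mmol ATP gCDW-1 h-1.
    rnf_h_per_fd : protons translocated outward per Fd_red oxidised by Rnf.
    atpase_h_per_atp : protons translocated per ATP by the FoF1 ATPase.
    biomass_* : precursor demands, mmol per gCDW (coarse placeholders).
    include_pfl : include pyruvate formate-lyase.
    """

    glucose_uptake_max: float = 4.0
    gam: float = 35.0
    ngam: float = 5.0
    rnf_h_per_fd: float = 0.5
    atpase_h_per_atp: float = 4.0
    biomass_pyruvate: float = 0.5
    biomass_accoa: float = 0.5
    biomass_nadph: float = 0.2
    biomass_nadh: float = 2.0
    include_pfl: bool = True

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name == "include_pfl":
                continue
            if value < 0:
                raise ValidationError(f"CoreParams.{name} must be nonnegative")
        if self.atpase_h_per_atp < 1:
            raise ValidationError("atpase_h_per_atp must be >= 1")


_METS = [
    # id, name, formula, compartment
    ("glc_e", "D-glucose", "C6H12O6", "e"),
    ("glc_c", "D-glucose", "C6H12O6", "c"),
    ("pyr_c", "pyruvate", "C3H4O3", "c"),
    ("lac_c", "lactate", "C3H6O3", "c"),
    ("lac_e", "lactate", "C3H6O3", "e"),
    ("ac_c", "acetate", "C2H4O2", "c"),
    ("ac_e", "acetate", "C2H4O2", "e"),
    ("but_c", "butyrate", "C4H8O2", "c"),
    ("but_e", "butyrate", "C4H8O2", "e"),
    ("for_c", "formate", "CH2O2", "c"),
    ("for_e", "formate", "CH2O2", "e"),
    ("co2_c", "carbon dioxide", "CO2", "c"),
    ("co2_e", "carbon dioxide", "CO2", "e"),
    ("h2_c", "molecular hydrogen", "H2", "c"),
    ("h2_e", "molecular hydrogen", "H2", "e"),
    ("h2o_c", "water", "H2O", "c"),
    ("h2o_e", "water", "H2O", "e"),
    ("pi_c", "phosphate", "H3O4P", "c"),
    ("pi_e", "phosphate", "H3O4P", "e"),
    ("h_c", "proton", "H", "c"),
    ("h_e", "proton", "H", "e"),
    ("coa_c", "coenzyme A", "HX", "c"),
    ("accoa_c", "acetyl-CoA", "C2H3OX", "c"),
    ("aacoa_c", "acetoacetyl-CoA", "C4H5O2X", "c"),
    ("hbcoa_c", "(S)-3-hydroxybutyryl-CoA", "C4H7O2X", "c"),
    ("b2coa_c", "crotonyl-CoA", "C4H5OX", "c"),
    ("btcoa_c", "butyryl-CoA", "C4H7OX", "c"),
    ("nad_c", "NAD+", "Nd", "c"),
    ("nadh_c", "NADH", "HNd", "c"),
    ("nadp_c", "NADP+", "Np", "c"),
    ("nadph_c", "NADPH", "HNp", "c"),
    ("fdox_c", "oxidised ferredoxin", "Fd", "c"),
    ("fdred_c", "reduced ferredoxin", "Fd", "c"),
    ("atp_c", "ATP", "AdHO3P", "c"),
    ("adp_c", "ADP", "Ad", "c"),
    ("xu_e", "dead-end pentose", "C5H10O5", "e"),
]


def build_core_model(
    params: CoreParams | None = None,
) -> tuple[MetabolicModel, dict, RoleMap]:
    """Build the core network; return (model, manifest, role map).

    The manifest records every reaction's exact stoichiometry and bounds
    so tests can cross-check the construction entry by entry, and flags
    the biomass coefficients as placeholders.
    """
    p = params or CoreParams()
    p.validate()

    model = MetabolicModel(
        id="clostridial_core",
        compartments={"c": "cytoplasm", "e": "extracellular"},
        objective_reaction_id="BIOMASS",
    )
    for mid, name, formula, comp in _METS:
        model.add_metabolite(Metabolite(mid, name, formula, compartment=comp))
    model.add_metabolite(
        Metabolite("biomass_c", "biomass", None, compartment="c", boundary=True)
    )

    nh = p.rnf_h_per_fd
    na = p.atpase_h_per_atp

    def rxn(rid, stoich, lb, ub, gene="", subsystem="", name="", ec=None):
        model.add_reaction(
            Reaction(rid, name or rid, stoich, lb, ub, gene, subsystem, ec)
        )

    # central carbon
    rxn(
        "GLYC",
        {
            "glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
            "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h_c": 2, "h2o_c": 2,
        },
        0, 1000, gene="CTR0101 and CTR0102", subsystem="Glycolysis",
        name="glycolysis (lumped EMP)",
    )
    rxn(
        "PFOR",
        {"pyr_c": -1, "coa_c": -1, "fdox_c": -1,
         "accoa_c": 1, "co2_c": 1, "fdred_c": 1, "h_c": 1},
        0, 1000, gene="CTR0461", subsystem="Pyruvate metabolism",
        name="pyruvate:ferredoxin oxidoreductase", ec="1.2.7.1",
    )
    if p.include_pfl:
        rxn(
            "PFL",
            {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1},
            0, 1000, gene="CTR0510", subsystem="Pyruvate metabolism",
            name="pyruvate formate-lyase", ec="2.3.1.54",
        )
    rxn(
        "LDH",
        {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac_c": 1, "nad_c": 1},
        0, 1000, gene="CTR0390", subsystem="Pyruvate metabolism",
        name="lactate dehydrogenase", ec="1.1.1.27",
    )
    rxn(
        "PTAACK",
        {"accoa_c": -1, "adp_c": -1, "pi_c": -1,
         "ac_c": 1, "atp_c": 1, "coa_c": 1},
        -1000, 1000, gene="CTR0069 and CTR0070", subsystem="Acetate metabolism",
        name="phosphotransacetylase + acetate kinase (lumped)", ec="2.7.2.1",
    )
    # butyryl-CoA chain
    rxn(
        "THL",
        {"accoa_c": -2, "aacoa_c": 1, "coa_c": 1},
        -1000, 1000, gene="CTR0411", subsystem="Butyrate synthesis",
        name="thiolase", ec="2.3.1.9",
    )
    rxn(
        "HBD",
        {"aacoa_c": -1, "nadh_c": -1, "h_c": -1, "hbcoa_c": 1, "nad_c": 1},
        0, 1000, gene="CTR0413", subsystem="Butyrate synthesis",
        name="3-hydroxybutyryl-CoA dehydrogenase", ec="1.1.1.157",
    )
    rxn(
        "CRT",
        {"hbcoa_c": -1, "b2coa_c": 1, "h2o_c": 1},
        -1000, 1000, gene="CTR0414", subsystem="Butyrate synthesis",
        name="crotonase", ec="4.2.1.55",
    )
    rxn(
        "BCD",
        {"b2coa_c": -1, "nadh_c": -2, "fdox_c": -1,
         "btcoa_c": 1, "nad_c": 2, "fdred_c": 1},
        0, 1000, gene="CTR0417 and CTR0418 and CTR0419",
        subsystem="Butyrate synthesis",
        name="electron-bifurcating butyryl-CoA dehydrogenase/EtfAB",
        ec="1.3.1.109",
    )
    rxn(
        "CAT1",
        {"btcoa_c": -1, "ac_c": -1, "but_c": 1, "accoa_c": 1},
        -1000, 1000, gene="CTR0423", subsystem="Butyrate synthesis",
        name="butyryl-CoA:acetate CoA-transferase", ec="2.8.3.8",
    )
    # ferredoxin redox loops and energy conversion
    rxn(
        "HYDA",
        {"fdred_c": -1, "h_c": -2, "h2_c": 1, "fdox_c": 1},
        0, 1000, gene="CTR0446", subsystem="Energy metabolism",
        name="ferredoxin hydrogenase (HydA)", ec="1.12.7.2",
    )
    rxn(
        "RNF",
        {"fdred_c": -1, "nad_c": -1, "h_c": -(1 + nh),
         "fdox_c": 1, "nadh_c": 1, "h_e": nh},
        0, 1000, gene="CTR0447", subsystem="Energy metabolism",
        name="Rnf complex (ferredoxin:NAD+ oxidoreductase, proton pump)",
    )
    rxn(
        "FNR",
        {"fdred_c": -1, "nadp_c": -1, "h_c": -1, "fdox_c": 1, "nadph_c": 1},
        0, 1000, gene="CTR0455", subsystem="Energy metabolism",
        name="ferredoxin:NADP+ reductase", ec="1.18.1.2",
    )
    # n protons translocated inward per ATP; one of them is consumed in
    # the condensation (ADP + Pi + H+ -> ATP + H2O), so n-1 reach the pool
    rxn(
        "ATPASE",
        {"adp_c": -1, "pi_c": -1, "h_e": -na,
         "atp_c": 1, "h2o_c": 1, "h_c": na - 1},
        -1000, 1000, gene="CTT0018", subsystem="Energy metabolism",
        name="FoF1 ATP synthase", ec="7.1.2.2",
    )
    rxn(
        "ATPM",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        p.ngam, 1000, subsystem="Maintenance",
        name="non-growth-associated maintenance (ATP hydrolysis)",
    )
    # biomass with GAM; precursor coefficients are coarse placeholders
    biomass = {
        "pyr_c": -p.biomass_pyruvate,
        "accoa_c": -p.biomass_accoa,
        "nadph_c": -p.biomass_nadph,
        "nadh_c": -p.biomass_nadh,
        "biomass_c": 1.0,
        "coa_c": p.biomass_accoa,
        "nadp_c": p.biomass_nadph,
        "nad_c": p.biomass_nadh,
    }
    if p.gam > 0:
        biomass.update(
            {"atp_c": -p.gam, "h2o_c": -p.gam,
             "adp_c": p.gam, "pi_c": p.gam, "h_c": p.gam}
        )
    rxn("BIOMASS", biomass, 0, 1000, subsystem="Biomass", name="biomass synthesis")
    rxn("SK_biomass", {"biomass_c": -1}, 0, 1000, subsystem="Exchange",
        name="biomass sink")

    # Undissociated weak acids (acetate pKa 4.76, butyrate 4.82) cross
    # the membrane carrying their proton: export is proton symport and a
    # proton-efflux route.  The strong acids lactate (pKa 3.86) and
    # formate (3.75) are essentially fully dissociated and leave as
    # anion uniport.
    for acid in ("ac", "but"):
        rxn(
            f"{acid.upper()}t",
            {f"{acid}_c": -1, "h_c": -1, f"{acid}_e": 1, "h_e": 1},
            -1000, 1000, subsystem="Transport",
            name=f"{acid} export (proton symport)",
        )
    for acid in ("lac", "for"):
        rxn(f"{acid.upper()}t", {f"{acid}_c": -1, f"{acid}_e": 1}, -1000, 1000,
            subsystem="Transport", name=f"{acid} export (uniport)")
    rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, gene="CTR0050",
        subsystem="Transport", name="glucose uptake")
    for sp in ("co2", "h2", "h2o"):
        rxn(f"{sp.upper()}t", {f"{sp}_c": -1, f"{sp}_e": 1}, -1000, 1000,
            subsystem="Transport", name=f"{sp} diffusion")
    rxn("PIt", {"pi_e": -1, "pi_c": 1}, -1000, 1000, subsystem="Transport",
        name="phosphate transport")

    # exchanges: secretion positive, uptake negative
    rxn("EX_glc", {"glc_e": -1}, -p.glucose_uptake_max, 1000,
        subsystem="Exchange", name="glucose exchange")
    for sp in ("lac", "ac", "but", "for", "co2", "h2", "h"):
        rxn(f"EX_{sp}", {f"{sp}_e": -1}, 0, 1000, subsystem="Exchange",
            name=f"{sp} exchange")
    rxn("EX_h2o", {"h2o_e": -1}, -1000, 1000, subsystem="Exchange",
        name="water exchange")
    rxn("EX_pi", {"pi_e": -1}, -1000, 1000, subsystem="Exchange",
        name="phosphate exchange")
    rxn("EX_xu", {"xu_e": -1}, 0, 1000, subsystem="Exchange",
        name="dead-end pentose exchange (uptake closed by default)")

    model.validate()

    roles = RoleMap(
        reactions={
            "pfor": "PFOR",
            "hyd": "HYDA",
            "bcd_etfab": "BCD",
            "rnf": "RNF",
            "atpase": "ATPASE",
            "ack": "PTAACK",
            "biomass": "BIOMASS",
            "ex_butyrate": "EX_but",
            "ex_acetate": "EX_ac",
            "ex_lactate": "EX_lac",
            "ex_h2": "EX_h2",
            "ex_co2": "EX_co2",
            "ex_formate": "EX_for",
        },
        cofactors={
            "nadh": "nadh_c",
            "nadph": "nadph_c",
            "atp": "atp_c",
            "fd_red": "fdred_c",
        },
    )
    roles.validate(model)

    manifest = {
        "params": asdict(p),
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_genes": len(model.genes),
        "reactions": {
            rid: {
                "stoichiometry": dict(r.stoichiometry),
                "bounds": (r.lower_bound, r.upper_bound),
                "subsystem": r.subsystem,
            }
            for rid, r in model.reactions.items()
        },
        "placeholder_coefficients": [
            "biomass_pyruvate", "biomass_accoa", "biomass_nadph", "biomass_nadh"
        ],
    }
    return model, manifest, roles


# ---------------------------------------------------------------------
_TOY_NAMES = ("chain3", "branch2", "cycle2", "altopt8")


def build_toy_model(name: str) -> MetabolicModel:
    """Tiny LP fixtures with known optima and alternate-optima structure.

    chain3   : linear uptake->conversion->secretion chain; optimum 10.
    branch2  : two routes with yields 2 and 1 per substrate; only the
               better route carries flux at the optimum (10 from uptake 5).
    cycle2   : chain3 plus a 2-reaction futile cycle that parsimonious
               FBA must silence.
    altopt8  : duplicated internal route; the optimum is unique (10) but
               the split across the twin reactions is free in [0, 10].
    """
    if name not in _TOY_NAMES:
        raise ValidationError(f"unknown toy model {name!r}; available: {_TOY_NAMES}")
    m = MetabolicModel(id=name, compartments={"c": "cytoplasm", "e": "extracellular"})
    def met(mid, comp):
        m.add_metabolite(Metabolite(mid, compartment=comp))
    def rxn(rid, stoich, lb=0.0, ub=1000.0):
        m.add_reaction(Reaction(rid, rid, stoich, lb, ub))

    if name == "chain3":
        for mid, comp in (("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("B_e", "e")):
            met(mid, comp)
        rxn("EX_A", {"A_e": -1}, -10, 0)
        rxn("TA", {"A_e": -1, "A_c": 1})
        rxn("R1", {"A_c": -1, "B_c": 1})
        rxn("TB", {"B_c": -1, "B_e": 1})
        rxn("EX_B", {"B_e": -1})
        m.objective_reaction_id = "EX_B"
    elif name == "branch2":
        for mid, comp in (("S_e", "e"), ("S_c", "c"), ("P_c", "c"), ("P_e", "e")):
            met(mid, comp)
        rxn("EX_S", {"S_e": -1}, -5, 0)
        rxn("TS", {"S_e": -1, "S_c": 1})
        rxn("GOOD", {"S_c": -1, "P_c": 2})
        rxn("POOR", {"S_c": -1, "P_c": 1})
        rxn("TP", {"P_c": -1, "P_e": 1})
        rxn("EX_P", {"P_e": -1})
        m.objective_reaction_id = "EX_P"
    elif name == "cycle2":
        for mid, comp in (("A_e", "e"), ("A_c", "c"), ("B_c", "c"), ("B_e", "e"),
                          ("X_c", "c"), ("Y_c", "c")):
            met(mid, comp)
        rxn("EX_A", {"A_e": -1}, -10, 0)
        rxn("TA", {"A_e": -1, "A_c": 1})
        rxn("R1", {"A_c": -1, "B_c": 1})
        rxn("TB", {"B_c": -1, "B_e": 1})
        rxn("EX_B", {"B_e": -1})
        rxn("CYC1", {"X_c": -1, "Y_c": 1}, 0, 50)
        rxn("CYC2", {"Y_c": -1, "X_c": 1}, 0, 50)
        m.objective_reaction_id = "EX_B"
    else:  # altopt8
        for mid, comp in (("A_e", "e"), ("A_c", "c"), ("M_c", "c"),
                          ("B_c", "c"), ("B_e", "e")):
            met(mid, comp)
        rxn("EX_A", {"A_e": -1}, -10, 0)
        rxn("TA", {"A_e": -1, "A_c": 1})
        rxn("TWIN1", {"A_c": -1, "M_c": 1})
        rxn("TWIN2", {"A_c": -1, "M_c": 1})
        rxn("R2", {"M_c": -1, "B_c": 1})
        rxn("TB", {"B_c": -1, "B_e": 1})
        rxn("EX_B", {"B_e": -1})
        m.objective_reaction_id = "EX_B"
    m.validate()
    return m


def random_model(
    n_metabolites: int = 10,
    n_reactions: int = 15,
    seed: int = 0,
    density: float = 0.3,
) -> tuple[MetabolicModel, list[tuple[str, str, float]]]:
    """Random sparse fixture model plus its ground-truth coefficient list.

    Used by tests as an arbitrary structurally valid model (it need not
    be feasible or biologically meaningful).  Returns the model and a
    list of (reaction_id, metabolite_id, coefficient) triples.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    m = MetabolicModel(
        id=f"random_{seed}", compartments={"c": "cytoplasm", "e": "extracellular"}
    )
    met_ids = []
    for i in range(n_metabolites):
        comp = "e" if i < max(1, n_metabolites // 5) else "c"
        mid = f"m{i}_{comp}"
        m.add_metabolite(Metabolite(mid, f"met {i}", compartment=comp))
        met_ids.append(mid)
    truth: list[tuple[str, str, float]] = []
    for j in range(n_reactions):
        k = max(1, int(rng.binomial(n_metabolites, density)))
        chosen = rng.choice(met_ids, size=min(k, n_metabolites), replace=False)
        stoich = {}
        for mid in chosen:
            coeff = float(np.round(rng.uniform(-3, 3), 3))
            if coeff == 0.0:
                coeff = 1.0
            stoich[mid] = coeff
        lb = float(np.round(rng.uniform(-50, 0), 3))
        ub = float(np.round(rng.uniform(0, 50), 3))
        gene = f"g{j}" if rng.random() < 0.6 else ""
        rxn = Reaction(f"r{j}", f"reaction {j}", stoich, lb, ub, gene,
                       subsystem=rng.choice(["S1", "S2", "S3"]))
        m.add_reaction(rxn)
        truth.extend((rxn.id, mid, c) for mid, c in stoich.items())
    m.objective_reaction_id = "r0"
    m.validate()
    return m, truth
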