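# File formats

## JSON model dialect

Lossless for every field of the data model; keys are sorted and numbers
carry 12 significant digits, so identical models give byte-identical files.

```json
{
  "id": "clostridial_core",
  "compartments": {"c": "cytoplasm", "e": "extracellular"},
  "metabolites": [
    {"id": "glc_c", "name": "D-glucose", "formula": "C6H12O6",
     "charge": null, "compartment": "c", "boundary": false}
  ],
  "reactions": [
    {"id": "GLYC", "name": "glycolysis (lumped EMP)",
     "stoichiometry": {"glc_c": -1, "pyr_c": 2},
     "lower_bound": 0.0, "upper_bound": 1000.0,
     "gene_rule": "CTR0101 and CTR0102",
     "subsystem": "Glycolysis", "ec_number": null}
  ],
  "objective_reaction_id": "BIOMASS"
}
```

Negative stoichiometric coefficients are substrates, positive products;
reversibility is `lower_bound < 0`. `boundary: true` marks pseudo-species
(e.g. the biomass sink species) whose single-metabolite drains count as
exchanges. Schema violations are reported with their JSON path.

## SBML

Level 3 Version 1 core with the fbc v2 package. Flux bounds are shared
model parameters referenced per reaction (`fbc:lowerFluxBound` /
`fbc:upperFluxBound`), the objective is an fbc objective, formulas and
charges use fbc species attributes. Gene rules, subsystems and EC numbers
are written as COBRA-style notes:

```xml
<notes><body xmlns="http://www.w3.org/1999/xhtml">
  <p>GENE_ASSOCIATION: CTR0417 and CTR0418</p>
  <p>SUBSYSTEM: Butyrate synthesis</p>
  <p>EC Number: 1.3.1.109</p>
</body></notes>
```

On reading, fbc gene-product associations are used when no notes rule is
present. Species/reaction ids gain the conventional `M_`/`R_` prefixes on
writing and lose them on reading. Unsupported constructs (rules, events,
constraints) are ignored with a logged warning.

## Reaction-table TSV

One reaction per row; tab-separated; extra columns are ignored.

| column | required | content |
|---|---|---|
| `id` | yes | reaction identifier |
| `equation` | yes | `2 A[c] + B[c] <=> C[e]`; `<=>` reversible, `-->` irreversible; `[c]`/`[e]` compartment suffixes |
| `lower_bound`, `upper_bound` | no | numeric; defaults from the arrow: `<=>` → (−1000, 1000), `-->` → (0, 1000) |
| `gene_rule` | no | boolean expression over gene ids (`and`/`or`) |
| `subsystem` | no | free text |
| `ec_number` | no | EC number string |

Metabolite ids are formed as `<name>_<compartment>`. A row whose equation
has a single extracellular metabolite acts as an exchange. The objective is
the biomass-producing reaction (the reaction mentioning "biomass" with the
largest stoichiometry), if any. Parse errors name the row and token.

## Fermentation time series

TSV or CSV with a strictly increasing `time` column (hours), an `od600`
column, and one concentration column per analyte (g/L):

```
time	od600	glucose	butyrate	acetate
0	0.20	60.0	0.0	0.0
4	0.55	52.1	2.9	1.1
```

## Role-map YAML

Binds abstract network roles to identifiers in a concrete model:

```yaml
reactions:
  pfor: PFOR
  hyd: HYDA
  bcd_etfab: BCD
  rnf: RNF
  atpase: ATPASE
  ack: PTAACK
  biomass: BIOMASS
  ex_butyrate: EX_but
  ex_acetate: EX_ac
  ex_lactate: EX_lac
  ex_h2: EX_h2
  ex_co2: EX_co2
  ex_formate: EX_for
cofactors:
  nadh: nadh_c
  nadph: nadph_c
  atp: atp_c
  fd_red: fdred_c
```

Roles may be left unbound; analyses that need them skip them with a
warning. `butyflux synth --roles roles.yaml` writes this file for the core
network.

## Substrate panel TSV

```
name	exchange_id	class	in_vivo
glucose	EX_glc	carbon	yes
pentose	EX_xu	carbon	no
```

`class` is `carbon` or `nitrogen`; `in_vivo` accepts yes/no, +/−, true/false.
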