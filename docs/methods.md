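# Methods

## Scope and modelling framework

All analyses are steady-state constraint-based: a flux vector v must satisfy
S·v = 0 with lb ≤ v ≤ ub, and flux balance analysis (FBA) maximises the flux
of a designated biomass reaction. Exchange fluxes are signed so that
secretion is positive and uptake negative; units are mmol gCDW⁻¹ h⁻¹
throughout, with the biomass flux in h⁻¹. Reversibility is encoded purely by
a negative lower bound. No thermodynamic (ΔG) constraints, metabolite
concentrations or kinetics are modelled.

## The LP engine

FBA, parsimonious FBA (pFBA) and flux variability analysis (FVA) run on
SciPy's HiGHS interface with variables ordered by model insertion order, so
every solve is deterministic for a given model. Solver statuses are reported
faithfully — an infeasible or unbounded problem returns its status and no
flux vector. Every optimal solution is verified against max|S·v| ≤ 10⁻⁶ and
its bounds before being returned.

Because FBA optima are usually degenerate, all *reported* per-reaction
fluxes (scans, knockout comparisons) come from pFBA: among solutions with
objective ≥ (1 − 10⁻⁶) × optimum, the split-variable LP minimising Σ|v|
selects a unique, parsimony-justified representative. FVA (min/max flux at a
fixed objective fraction) is exposed to check how much freedom hides behind
any representative; switch reports carry an FVA-based "forced" flag for this
reason. Consequences of the 10⁻⁶ objective slack: representative fluxes can
deviate from forced values by ~10⁻⁵ of the flux scale, and nominally silent
reactions can carry residual fluxes of that order. Switch detection in the
test-suite therefore uses a pattern threshold of 10⁻⁴ — above the
representative resolution, two orders of magnitude below any real flux in
the scans.

## The synthetic clostridial core network

`butyflux.synth.build_core_model` generates a 37-reaction, 37-metabolite,
two-compartment network that realises the acidogenic clostridial central
metabolism: lumped EMP glycolysis, PFOR and pyruvate formate-lyase (PFL),
lactate dehydrogenase, lumped phosphotransacetylase/acetate kinase, the
thiolase–HBD–crotonase chain, the electron-bifurcating butyryl-CoA
dehydrogenase/EtfAB (crotonyl-CoA + 2 NADH + Fd_ox → butyryl-CoA + 2 NAD⁺ +
Fd_red), butyrate formation exclusively via butyryl-CoA:acetate
CoA-transferase (so butyrate retains the acetate-kinase ATP and can
re-assimilate acetate), a ferredoxin-only hydrogenase, the Rnf complex, a
ferredoxin:NADP⁺ reductase, the F₀F₁ ATPase, an NGAM ATP-hydrolysis
reaction, and a biomass drain. Reduced ferredoxin is produced only by PFOR
and Bcd/EtfAB and consumed only by HydA, Rnf and the NADP⁺ reductase, so the
two redox loops are structural properties, checked by test.

Currency metabolites (NAD(H), NADP(H), ATP/ADP, ferredoxin, the CoA thioester
pool) are conserved moieties: the corresponding row-sums of S vanish for
every internal reaction. Carbon-tracked species carry real elemental
formulas (CoA and the redox carriers use opaque pseudo-elements such as `X`
and `Fd`), and the elemental-balance checker reports zero unbalanced
reactions under the default proton/biomass exemptions.

### Proton economy

Protons are tracked where they carry the model's physiology:

* chemistry protons follow standard stoichiometry (glycolysis +2 H⁺_c per
  glucose, PFOR +1, LDH/HBD/FNR −1, HydA −2 per H₂, ATP hydrolysis +1);
* Rnf consumes 1 + n_rnf cytoplasmic protons per ferredoxin (one for NADH
  formation, n_rnf translocated outward);
* the ATPase translocates n_atp protons per ATP, one of which is consumed in
  the ADP + Pi condensation, so n_atp enter and n_atp − 1 reach the
  cytoplasmic pool;
* the weak acids acetate (pKa 4.76) and butyrate (4.82) cross the membrane
  undissociated — their export is proton symport and hence a proton-efflux
  route; lactate (3.86) and formate (3.75) are essentially fully dissociated
  at cytoplasmic pH and leave as anion uniport;
* extracellular protons can be secreted but not imported, so the proton
  motive force can only be spent through the ATPase.

This bookkeeping makes the ATPase bidirectional in practice: at low butyrate
flux the cytoplasmic proton balance runs a surplus and the ATPase pumps at
ATP cost (its net flux is negative); as forced butyrate rises, the
hydrogenase and the acid symports consume the surplus and the ATPase crosses
into ATP synthesis. Its representative flux is monotone non-decreasing
across the growth-supporting scan range, mirroring the switch of the energy
production pattern from acetate kinase to the ATPase. At the exact
zero-growth feasibility corner (forced butyrate = its theoretical maximum)
the surplus ATP must be hydrolysed and pumped, so that single boundary point
is excluded from the monotonicity statement.

### Parameters and defaults

| parameter | default | meaning and rationale |
|---|---|---|
| `glucose_uptake_max` | 4.0 mmol gCDW⁻¹ h⁻¹ | specific glucose uptake of a growing batch culture; the coupling scans are meaningful under carbon limitation, and this value puts the theoretical butyrate maximum at the top of the 0–4 scan range |
| `gam` | 35 mmol ATP gCDW⁻¹ | growth-associated maintenance, embedded in the biomass reaction |
| `ngam` | 5 mmol ATP gCDW⁻¹ h⁻¹ | non-growth maintenance, the lower bound of the ATP-hydrolysis reaction |
| `rnf_h_per_fd` | 0.5 | protons translocated per ferredoxin by Rnf. With ≥ 1 H⁺/Fd (at 3–4 H⁺/ATP) the Rnf→ATPase route out-earns acetate kinase and the growth optimum collapses into the all-butyrate corner, with neither acetate nor H₂ secreted — contradicting the observed wild-type spectrum. 0.5 keeps Rnf below the acetate-kinase margin, so it engages only when the NADH balance demands it. Configurable; the qualitative couplings, not absolute fluxes, are the target |
| `atpase_h_per_atp` | 4 | F₀F₁ translocation stoichiometry; 3 is also exercised by the tests |
| `biomass_*` | pyruvate 0.5, acetyl-CoA 0.5, NADPH 0.2, NADH 2.0 mmol gCDW⁻¹ | coarse placeholder precursor demands. The NADH term represents net anabolic reduction; without any anabolic NADH sink, forcing butyrate secretion to zero pins every glycolytic NADH to lactate dehydrogenase, which consumes one pyruvate each — growth would be exactly zero there and the low-range couplings would degenerate |
| `include_pfl` | on | pyruvate formate-lyase; switching it off blocks the formate exchange entirely |

With these defaults the wild-type pFBA optimum grows at 0.231 h⁻¹ secreting
butyrate, acetate, H₂ and CO₂ with no lactate or formate; growth at GAM 40
is 0.203 h⁻¹ (growth is monotone non-increasing in GAM, which is why GAM
fitting is a bisection). Forcing acetate and the overflow acids to zero
routes glucose to butyrate : CO₂ : H₂ near the textbook 1 : 2 : 2.

## Maintenance fitting and rate constraints

GAM is fitted to an observed specific growth rate by bisection on [0, 100]
(tolerance 0.01), exploiting monotonicity; the comparison is strict, so on a
flat stretch of μ(GAM) — which occurs near GAM 0 when ATP is not the binding
resource — the fit slides to the smallest GAM reproducing the observation.
Observations outside the attainable range raise an error stating that range.
Specific rates from fermentation time series use
(Δc/Δt)/X̄ · 1000/M with X̄ the mean dry-cell weight over the interval
(OD₆₀₀ × 0.30 g DCW/L by default, configurable) and μ = ln(X₂/X₁)/Δt;
uptake is negative. Which exchanges to constrain is the caller's choice,
passed as an explicit list.

## Scans and switch detection

`production_scan` clamps one exchange to each grid value (lower = upper =
g — "setting" a rate is read as an equality), re-maximises growth, and
records the pFBA representative: growth, the product secretion rates, the
cofactor turnover rates (Σ_j max(0, s_ij v_j), which equals total
consumption at steady state) and the tracked reaction fluxes. Infeasible
grid points are retained with their status so envelope edges stay visible.

`detect_switch` classifies each feasible point as pure-A (flux(A) > ε,
flux(B) ≤ ε), pure-B, or mixed, and reports the interval from the last
pure-A point to the first subsequent pure-B point (either orientation).
Mixed points stay inside the interval, so refining the grid never moves a
switch outside the interval reported on the coarser grid. When the scan
carries FVA ranges for the pair, the report's `forced` flag states whether
the ranges at both endpoints exclude the alternative pattern.

## What the synthetic core does and does not show

The core reproduces, as emergent LP behaviour rather than anything fitted:
the wild-type co-production spectrum; the low-range positive coupling of
growth, H₂, CO₂ and acetate with forced butyrate and the negative coupling
of lactate; the HydA→Rnf hand-over in the upper butyrate range together
with the acetate-kinase→ATPase energy switch; the H₂-up/butyrate-down
response to forced acetate secretion; higher butyrate yield and collapsed
acetate secretion in the hydrogenase knockout (for 3 and 4 H⁺/ATP); and the
opposing effects of clamped hydrogenase and Rnf fluxes on acetate export.

Known limitations:

* The organism carries three hydrogenases; the core lumps them into one
  reaction. Clamping that single reaction near zero (as the corner of the
  two-flux grid does) strangles ferredoxin disposal entirely, so growth —
  not the proton-efflux pattern — dominates the response there and the
  acetate couplings invert. The grid monotonicity statements are therefore
  made over the growth-sustaining region (hydrogenase clamp ≥ 2
  mmol gCDW⁻¹ h⁻¹, growth > 0); a genome-scale model with separate
  hydrogenases does not visit that strangled state.
* Biomass composition is a four-term placeholder; absolute growth rates and
  yields are indicative, not calibrated.
* pFBA ties between PFOR and PFL are resolved by the proton economy; at the
  zero-growth feasibility corner of the butyrate scan, the representative
  route flips to PFL, which is why boundary points are reported but excluded
  from trend statements.
* Passing the qualitative tests on this 37-reaction network shows the
  mechanism is coherent, not that a particular genome-scale reconstruction
  is correct; the published-model checks require the real reaction table.

## Numerical conventions

Steady-state tolerance 10⁻⁶; bound tolerance 10⁻⁹ (reported solutions are
checked at 10⁻⁶ to absorb solver round-off); pFBA objective fraction
1 − 10⁻⁶; FVA objective fraction 1.0 unless stated; switch threshold ε =
10⁻⁶ by default, 10⁻⁴ in the scan tests (see above); growth threshold for
substrate tests 10⁻⁴ h⁻¹ (an uptake bound of 10 mmol gCDW⁻¹ h⁻¹, far above
the NGAM-imposed minimum substrate requirement). Serialised numbers carry
12 significant digits; writers are deterministic, and identical models
produce byte-identical SBML and JSON files.
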