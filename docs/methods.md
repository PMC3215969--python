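# Methods

## The model

`electrofba` simulates *microbial electrosynthesis* — supplying reducing
power to a fermenting cell from a cathode — inside the standard
constraint-based (FBA) framework.  All quantities come from linear programs

```
max/min  c·v    s.t.   S·v = 0,   lb ≤ v ≤ ub
```

over a stoichiometric model.  The cathode is represented by two added
reactions:

1. an electron exchange `EX_e_el_e` whose lower bound caps uptake at
   `electron_uptake_max` (default 30 mmol e⁻/gDW·hr ≈ 0.80 A/gDW, consistent
   with measured electricigen electron-transfer rates), and
2. a lumped NADH regeneration `NADHR: 2 e⁻ + NAD⁺ + H⁺ → NADH`, standing in
   for the electrode → cytochrome/quinone pool → NAD⁺ path.

Unless a scenario fixes it, the electron uptake is free inside `[0, bound]`,
so enhancement is a pure relaxation: an enhanced optimum can never fall below
the base optimum, and equals it at bound 0.  This monotonicity, and the
pointwise nesting of production envelopes under growing bounds, are asserted
as properties throughout the test suite.

### The proton choice

The proton consumed by `NADHR` is configurable between periplasm (default)
and cytosol.  The choice is the one genuinely open modelling decision: charge
neutrality requires electron entry to be accompanied by proton influx, and
whether that influx competes with or drives the ATP synthase depends on which
pool the lumped reaction draws from.  In genome-scale *E. coli* models the
periplasmic pool exchanges freely with the medium, so the periplasmic variant
is energetically silent; a cytosolic proton whose only import route is the
ATP synthase yields one ATP per four electrons-worth of protons translocated.
The two-compartment toy network is wired this way on purpose, and shows the
exact gain `(e/2)/4` (3.75 mmol ATP/gDW·hr at the full 30 mmol e⁻/gDW·hr
bound), linear in the current — the mechanism by which cathodic electrons
can flip the synthase from ATP-driven proton pumping to proton-driven ATP
synthesis.  Published genome-scale ATP/growth enhancement numbers are known
to be sensitive to the exact (unpublished) electrode stoichiometry; the
yield-side results below are not.

## SPEEQ

The degree of reduction used here is *pyruvate-referenced*: NADH equivalents
released oxidizing a substrate to pyruvate, or consumed making a product from
pyruvate, per carbon atom (e.g. glucose 2/6 = 0.33, ethanol 2/2 = 1.0,
1,4-butanediol 6/4 = 1.5).  SPEEQ is the substrate's degree of reduction over
the product's.  Values are shipped as tabulated data at two-decimal precision
rather than recomputed from the network — the panel is the operational
definition — and quotients inherit that precision (glucose/succinate =
0.33/0.5 = 0.66).  The smaller SPEEQ is, the larger the redox deficit the
cathode can cover, and the larger the theoretical-yield improvement; products
made through CO₂-fixing reactions (succinate, 1,4-butanediol via ppc) sit
above that trend because extra NADH lets the network buy extra carbon.

## Media and conditions

A `Condition` names substrate exchanges with positive uptake magnitudes
(uptake is negative flux; the bound set is `lb = −magnitude`).  Applying a
condition closes every other organic-carbon exchange for uptake, so the
stated substrate is the sole carbon source, while inorganic species (CO₂,
bicarbonate, minerals, water, protons) stay open.  Anaerobic means the O₂
exchange is closed for uptake only; secretion stays allowed.  Equal-carbon
uptake rates for the standard panel: glucose/gluconate/sorbitol 10,
xylose 12, glycerol 20, maltose 5 mmol/gDW·hr (60 C-mmol/gDW·hr each).

## Degeneracy

LP optima are unique; optimizers are not.  Every reported flux distribution
comes from a second LP that fixes the objective at its optimum (tolerance
1e-9) and minimizes total absolute flux (parsimonious resolution).
`flux_change_summary` refuses non-resolved inputs, because single-reaction
fluxes at an alternate optimum are reporting noise.  Group-level summaries
use direction weights so that, e.g., glycolytic flow and reductive-TCA flow
are positive regardless of each BiGG reaction's written orientation.

## The synthetic network

The toy generator emulates the minimal fermentation structure with
analytically solvable optima: substrate uptake `U` → lumped glycolysis
(`A → B + n NADH + m ATP`) → a reduced branch (`B + k NADH → P_red`), an
ATP-yielding oxidized branch (`B + ADP → P_ox + ATP`), a biomass drain on
B/ATP/NADH, an ATP maintenance drain, conserved cofactor couples and the
electrode pair.  Defaults `U = 10, n = 2, m = 2, k = 3` give the worked
optima used everywhere: max P_red = 20/3 without the cathode (redox-limited)
and 10 with it (carbon-limited), i.e. a 50% theoretical-yield improvement;
max ATP = 70/3; max biomass = 5.

Closed forms for the single-compartment family (`k ≥ n`, so the reduced
branch can always re-balance redox) follow from the three balances (B, NADH,
ATP) and are reduced to two-variable linear programs solved analytically by
pairwise line intersection — no LP solver is involved, which makes them an
independent oracle for the engine.  The suite checks 1000+ sampled
configurations to 1e-9 (observed agreement ~1e-14), and a separate
brute-force vertex enumerator over active bound sets cross-checks a subset
with no shared code path.

Optional features: `two_compartment` adds a periplasm, proton porin,
reversible ATP synthase (4 H⁺ per ATP) and an NADH-disposing hydrogenase,
with cytosolic protons reachable only through the synthase (the exact
synthase-coupling motif above).  `include_co2_fixing_branch` adds
`B + CO₂ + k NADH → P_fix`, the minimal ppc/succinate analogue.  The branch
deliberately consumes the full reduced-branch NADH quota: carboxylation must
cost redox, otherwise cathodic electrons would suppress rather than stimulate
CO₂ fixation, inverting the mechanism the branch exists to demonstrate.

What the toy does *not* emulate: realistic P/O ratios, maintenance costs,
byproduct spectra, or any genome-scale redundancy.  Passing toy tests shows
the algebra and the engine are right, not that any organism behaves this way.

## Heterologous pathways

Built-in specs (BiGG namespace, formulas supplied for new species, C/H/O
balance checked against the host model on addition):

* **1,3-propanediol** — glycerol dehydratase + NADH oxidoreductase
  (net 1 NADH per product from glycerol).
* **1,4-butanediol** — succinyl-CoA → succinate semialdehyde →
  4-hydroxybutyrate → 4HB-CoA → 4-hydroxybutanal → BDO (net 4 NADH from
  succinyl-CoA; 6 from the pyruvate reference point, matching the panel).
* **n-butanol** — clostridial route: thiolase, NADH-linked
  3-hydroxybutyryl-CoA dehydrogenase, crotonase, NADH trans-enoyl-CoA
  reductase, aldehyde/alcohol dehydrogenases (net 4 NADH from 2 acetyl-CoA).
* **Wood-Ljungdahl** — CO₂-reducing formate dehydrogenase, ATP-consuming
  formyl-THF ligase, the THF interconversions, NADH methylene-THF reductase,
  CO dehydrogenase and acetyl-CoA synthase.  All reduction steps are fixed to
  NADH and one ATP is invested per acetyl-CoA; CO₂-only growth values are
  sensitive to these cofactor choices, which is why they are documented here
  rather than treated as tunable.

Knockout sets are configuration, not computation (no OptKnock-class
algorithms).  The shipped ethanol 3/5/10-knockout and succinate designs are
illustrative defaults that remove competing NAD⁺-regenerating fermentation
routes; on the bundled genome-scale model they produce growth-coupled
ethanol (coupled flux ≈ 16.5 mmol/gDW·hr at μ ≈ 0.197/hr).

## Genome-scale results (bundled iJO1366)

The package's integration tests and acceptance script run on the iJO1366
*E. coli* reconstruction distributed inside cobrapy (no download).  Under
anaerobic glucose (10 mmol/gDW·hr), electron bound 30:

* theoretical yield improvements follow SPEEQ: succinate +12.7%, ethanol
  +12.5% (2.00 → 2.25 mol/mol, breaking the classic fermentation ceiling),
  acetate 0%;
* ppc flux at the succinate optimum rises 14.2 → 18.5 mmol/gDW·hr and ATP
  synthase crosses from pumping (−3.1) to synthesis (+1.2);
* Wood-Ljungdahl co-utilization raises growth 0.24 → 0.39/hr, and 0.43/hr
  with enhancement (net CO₂ fixation appears only in the enhanced case);
* electrons + CO₂ alone sustain growth at 0.0058/hr and a succinate maximum
  of 0.22 mmol/gDW·hr — the order-of-magnitude gap to sugar substrates that
  motivates co-utilization.

## The two-phase calculator

`two_phase_productivity` evaluates the grow-then-produce operating strategy
in closed form: exponential growth at the growth envelope's μmax with its
growth-coupled product rate until a switch density, then fixed-biomass
production at the production envelope's maximum-product point until the
substrate pool is exhausted (integrals of `U·X(t)` done analytically; no ODE
solver).  It ignores product inhibition and maintenance decay — it is an
operating-point calculator, not a bioreactor model.  On envelopes whose
growth and production optima differ, volumetric productivity peaks at an
interior switch density, the quantitative form of "grow first, then turn the
current on".

## Numerical choices

* Solver: GLPK through optlang/cobrapy; requested optimum tolerance 1e-9,
  asserted feasibility 1e-6 (headline values print to 2–3 significant
  figures).
* Envelopes: 50 growth points by default, μmax appended exactly so coupling
  at maximal growth is never interpolated; biomass is fixed (±1e-9), not
  lower-bounded.
* Electron-uptake scans: grid 0–30 in 0.2 steps, uptake *fixed* at each
  point, biomass maximized, parsimonious product flux recorded; ties broken
  toward higher growth.
* Coupling threshold: minimum product flux at μmax above 1e-6 mmol/gDW·hr.
* Yield basis: per substrate uptake; growth yield per total incoming carbon
  (gDW per mol C, counting CO₂ actually taken up) is reported alongside in
  the CO₂ scenarios.

## Known limitations

No mediator chemistry, overpotentials or membrane thermodynamics; no
electron donation to an anode; no gene-protein-reaction rules (knockouts are
reaction-level); no loopless FBA.  Published reference values computed on
the iAF1260 reconstruction are not asserted against the bundled iJO1366
stand-in — the corresponding checks require the user to supply iAF1260 under
`data/` and report that requirement explicitly when it is missing.
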