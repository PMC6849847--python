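# Methods

This note documents the model, its numerical treatment, the synthetic
data generator, and the design choices made where the published model
description leaves the functional form open.

## Model structure and dynamics

The compartment graph is fixed (`trlkin.structure.build_structure`):
delipidation cascades for apoB100 (VLDL1 1–3, VLDL2 4–6) and apoB48
(CM 13–15, VLDL1 16–17, VLDL2 18–19), mirrored triglyceride subsystems
(7–12, 20–26), plasma leucine (27–29) and glycerol (38–39) subsystems,
two-stage synthesis delays (30–31, 32–33, 40–41), intestinal-tract lipid
(48) and four secretion staging pools (49/51 chylomicron route, 52/53
direct VLDL1/VLDL2 routes). Compartment ids follow the published
schematic; ids described only in its unavailable supplement are omitted,
and the "23,34" VLDL1 apoB48-TG listing is read as 23,24 (consistent
with the 20–26 caption range).

Within each fraction the entry compartment feeds a fast and a slow arm;
the fast arm transfers to the next density fraction or is cleared, the
slow arm is a remnant pool cleared directly. The published description
states compartment counts and fast/slow roles but not the exact edge
list; the canonical choice here (16→17 fast-to-slow conversion, 16→18
transfer, losses from 14–19; apoB100 analogously) is the most
parsimonious wiring that supports the described behaviours (delipidation
chains, slow remnant species, CM→VLDL1→VLDL2 transfer).

All kinetics are first-order mass action with rate constants in
pools/day. ApoB masses are in mg, TG in g; concentrations use a plasma
volume of 0.045 L/kg body weight (the published account states no
convention; this common default is isolated in one property).

### Protein/TG linkage and lipolytic shedding

Mirror edges share one rate constant per linkage group (k(0,5) =
k(0,11) and so on), and TG productions are apoB productions times the
newly-secreted composition ratios. A fully mirrored system with full
mass transfer would freeze every pool at the secretion composition and
force TG FCR ≡ apoB FCR, contradicting the observed divergence between
TG and apoB kinetics. `trlkin` therefore delivers, on each
ratio-decreasing transfer edge, only the fraction
ratio(destination)/ratio(source) of the TG mass (capped at 1); the shed
remainder is lipolysis product leaving the system and is counted in the
TG fraction's direct catabolism. The four apoB100 ratios (and the apoB48
analogues) are thereby genuine model variables that set the rate of
delipidation. When all ratios are equal every efficiency is 1 and the TG
subsystem mirrors the protein subsystem exactly (this special case is
exercised by the conservation and mirror tests).

### Secretion routing

Dietary TG enters compartment 48 as a boxcar flux (meal fat x 0.95
absorption over a 10-min consumption window) and drains through
first-order staging pools; the split over routes is fixed (0.97 CM, 0.02
VLDL1, 0.01 VLDL2 by default — TG absorption is near-complete and
varies little between subjects), while the staging rate constants are
per-subject, making appearance timing free to vary between individuals.
Each route's apoB48 protein flux is its TG flux divided by the TG/apoB48
composition ratio of the route's entry compartment, so the (derived)
apoB48 route shares weight the TG-poor direct-VLDL routes far above
their TG shares: with defaults, roughly half of meal-driven apoB48
enters VLDL1/VLDL2 directly while >95% of TG enters the CM fraction.
Basal apoB48 secretion is constant, meal-independent, uses the same
derived route shares, and carries its own (low) TG/apoB48 ratio —
fasting-state intestinal particles are TG-poor and VLDL-sized. A
`cm_only` configuration toggle retains the rejected all-CM-secretion
variant for structural comparison.

### Tracers

d3-leucine (7 mg/kg) and d5-glycerol (500 mg) enter compartments 27 and
38 as state jumps at t = 0. Label reaches apoB48 via the intestinal
delay, apoB100 via the hepatic delay, and hepatic TG via the glycerol
delay; the distribution over secretion-entry compartments uses the
constant derived route shares (for apoB48) or the production shares (for
apoB100 and TG), scaled by fitted enrichment-scale parameters (alpha per
labelled species). This keeps the tracer subsystems linear
time-invariant; the alternative — modulating the label split by the
instantaneous synthesis shares — would make the system bilinear and
coincides with the implemented form whenever basal and meal-driven
secretion share one route-share vector, as they do here. Bound label
then follows the tracee kinetics exactly (trace doses do not perturb
rates), TTR observables are summed tracer over summed tracee per
fraction, and plasma leucine enrichment is tracer mass over a fitted
constant unlabelled pool. d5-glycerol label has no path into
intestinally derived TG (enterocytes lack glycerol kinase): the
apoB48-TG compartments simply have no glycerol-label state, so the
invariant is structural. Measured VLDL TG pools contain both apoB100-TG
and (unlabelled) apoB48-TG, which dilutes the observed glycerol
enrichment — a deliberate feature of the observable mapping. Label
recycling from catabolized apoB is neglected over 24 h.

## Numerical treatment

Because every input is piecewise constant, the simulator propagates the
exact solution segment by segment with matrix exponentials of the
augmented system [[A, u], [0, 0]] (stacked `scipy.linalg.expm` calls),
with breakpoints at meal starts/ends; running integrals for absorbed
TG, secreted apoB48/apoB48-TG and the time-averaged pools used in FCR
derivation are obtained the same way (an integral-augmented block), so
no quadrature error enters the derived parameters. A general-purpose
stiff solver (`solve_ivp`/LSODA at rtol 1e-10) over the pure
`derivatives` function serves as an independent oracle in the tests and
agrees to <1e-5 relative.

The 0 h state is produced by placing the system at its basal (meal-free)
steady state — a linear solve — and simulating a "previous day" of
three meals and two snacks (08:00, 12:00, 16:00, 19:00, 21:00; fat
30/30/10/25/5 g, 100 g total; times and splits are a stated convention,
configurable) with the subject's own rate constants. This supplies both
basally secreted apoB48 and long-lived meal remnants at the moment of
tracer injection. Initializing apoB48 at its basal steady state before
the previous day (rather than at zero) was chosen so that a single
simulated day suffices; with zero basal secretion and zero fat it
reduces to empty apoB48 pools.

## Fitting

All series are fitted simultaneously. The cost is
`Σ w_s ((model − value)/max(|value|, floor))²` with the floor at 2% of
each series maximum (masses and TTRs span orders of magnitude; the
published account states no weighting scheme) and optional per-series
multipliers `w_s`. Optimization is `scipy.optimize.least_squares`
(trust-region reflective) on log-parameters with box bounds (sampling
envelopes widened 3x), seeded multistart (start 0 = configured init,
further starts log-uniform in the envelopes). The default iteration
budget (`max_nfev`) is deliberately modest — each iteration costs one
simulation per free parameter for the finite-difference Jacobian — and
is a reported diagnostic, not a convergence guarantee; `FitResult`
carries per-start costs, the convergence flag and per-series SSE.

Per-subject free parameters (41) are the cascade rate constants,
productions, composition ratios, basal secretion, meal-timing constants
and enrichment scales. Tracer-subsystem exchange rates, delay-stage
constants and the route TG shares are cohort-level constants in both the
generator and the default fit configuration: with one 24 h bolus study
per protocol they are not separately identifiable per subject, and
holding them fixed mirrors standard precursor-model practice. Fasted
datasets (total plasma apoB48 mass + enrichment + plasma leucine only)
identify a reduced set: basal secretion, removal rates and scales; in
the paired design the fasted fit starts from the same subject's fed-fit
estimate.

## Derived kinetic parameters

For fraction F over the 24 h study day (including the postprandial
transient — the reporting convention here for a non-steady-state
system): FCR(F) = time-averaged outflux / time-averaged pool, FDC the
irreversible part (for TG including shed lipolysis product), FTR the
transfer part, FCR = FDC + FTR exactly. The whole-plasma apoB48 FCR uses
all apoB48 compartments combined, matching the total-plasma observable
of fasted studies. Productions: apoB100 VLDL1 and VLDL2-direct are the
secretion parameters; VLDL2 total adds the time-averaged VLDL1→VLDL2
transfer flux; apoB48 postprandial production is the absorbed meal TG
times the route-share/composition coupling (so TG postprandial
production equals absorbed fat, 65.075 g for the standard meal — the
operational definition used throughout); totals are basal +
postprandial. These operational definitions stand in for the original
appendix formulas, which are not available.

## Synthetic-data generator

The generator *is* the study conditions: leucine sampling at 0–45 min
(dense) then hourly to 24 h; enrichment/mass sampling at 0–150 min then
to 24 h; the fed protocol's 68.5 g meal at +2 h; 19 observable series
fed, 3 fasted. Subject-level parameters are log-uniform within the
min–max envelopes of the four development-cohort subjects; removal and
transfer rates are drawn from a tier-dependent quantile window of the
envelope (low TG: upper 55%, normal: middle 60%, high: lower 55%),
reproducing the observed steep fall of FCRs with rising triglyceride.
Draws are rejected until the implied postprandial apoB48 production
falls in the cohort envelope (85–388 mg/day) and the implied fasting
plasma TG lands in the tier's range (low 0.5–1.3, normal 1.0–2.6, high
2.0–6.5 mmol/L, jointly spanning the cohort's 0.74–5.7). Parameters are
treated as independent within envelopes — the real between-subject
covariance is unknowable from four subjects.

Noise is Gaussian and proportional (default CV 5% on mass series, 7% on
enrichment series — typical LC/MS–GC/MS analytic precision; no
measurement-error model is published) with an additive floor of 0.1% of
each series maximum; negative draws are clipped at zero with a logged
count. What passing recovery tests therefore show is identifiability
under the model's own error structure; they do not speak to model
misspecification, inter-laboratory bias, or ultracentrifugation
carry-over in real data.

## Problem sizes and reported experiments

The recovery experiment uses 10 synthetic subjects cycling the three
tiers, 5% noise, 2-start fits with a 40-iteration budget; the structural
comparison fits the full and CM-only variants to one high-tier subject
with equal budgets; the fed/fasted comparison uses 4 paired subjects.
These sizes were chosen so the full pipeline re-runs from scratch in
minutes on a single CPU while leaving the conclusions stable across
seeds.

## Known limitations

* The apoB48 VLDL FCRs are the weakest-identified parameters (slow
  remnant pools are informed mainly by late time points); their recovery
  is reported as a diagnostic rather than asserted tightly.
* No LDL/IDL compartments, no apoE-phenotype effects, no enterocyte
  lipid-droplet storage submodel, no leucine oxidation or glycerol
  gluconeogenesis; plasma TG observables include only the modelled TRL
  pools (no HDL/LDL-TG background term).
* The fasted protocol alone cannot separate basal secretion from
  previous-day remnant history; fasted estimates inherit the fed-fit's
  kinetics in the paired design and are correspondingly noisy.
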