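# trlkin

Non-steady-state multicompartmental modelling of apoB48- and
apoB100-containing lipoprotein kinetics from dual stable-isotope tracer
studies.

## The problem

Triglyceride-rich lipoproteins (TRLs) — intestinally derived chylomicrons
(CM, one apoB48 molecule per particle) and hepatically derived VLDL (one
apoB100 per particle) — and their remnants are causal risk factors for
cardiovascular disease. Measuring their turnover is hard because the
system is genuinely non-steady-state: a fat-rich meal launches a wave of
chylomicron secretion over the near-steady background of VLDL secretion,
and both particle families traverse the same density intervals (CM,
VLDL<sub>1</sub> Sf 60–400, VLDL<sub>2</sub> Sf 20–60) while lipolysis
strips their core triglyceride.

`trlkin` implements an integrated compartmental model of this system for
studies in which d3-leucine (7 mg/kg) and d5-glycerol (500 mg) are
injected as a bolus, with or without a standard test meal (68.5 g fat at
+2 h), and pool masses plus tracer-to-tracee ratios (TTR) are followed
for 24 h in plasma, CM, VLDL1 and VLDL2. It is aimed at researchers in
lipoprotein metabolism who want to simulate such studies, fit the model
to (real or synthetic) data, and derive the standard kinetic parameters.

## The model

Compartments form delipidation cascades per species and density
fraction: apoB100 in VLDL1 (1–3) and VLDL2 (4–6) with a mirrored
apoB100-TG subsystem (7–12); apoB48 in CM (13–15), VLDL1 (16–17) and
VLDL2 (18–19) with mirrored apoB48-TG (20–26); three-compartment plasma
leucine (27–29) and two-compartment glycerol (38–39) tracer subsystems;
two-stage synthesis delays (intestine 30–31, liver 32–33, glycerol
40–41); and dietary lipid in the intestinal tract (48) feeding secretion
staging pools for the CM route (49, 51) and direct VLDL1/VLDL2 routes
(52, 53). Dynamics are first-order mass action,

    dx_i/dt = Σ_j k(i,j) x_j + u_i(t) − Σ_j k(j,i) x_i ,

with mirror edges between protein and TG subsystems sharing rate
constants (e.g. k(0,5) = k(0,11)) and productions linked through
TG/apoB composition ratios. Because all inputs are piecewise-constant
(boxcar meals, constant secretion, bolus doses), trajectories are
propagated *exactly* with matrix exponentials — no ODE tolerance enters.

Fitting minimizes a proportional-error weighted sum of squares over all
mass and enrichment series simultaneously (trust-region least squares in
log space, seeded multistart). Derived parameters follow the standard
definitions: for fraction F, FCR = (time-averaged flux leaving F) /
(time-averaged pool of F), split into direct catabolism (FDC) and
transfer to the next density fraction (FTR), with FCR = FDC + FTR by
construction; productions are 24 h time-integrals of entry fluxes.

A first-class synthetic-data generator (`trlkin.synth`) draws
ground-truth subjects across low/normal/high triglyceride tiers from the
development cohort's observed parameter envelopes and produces noisy
datasets on the study's sampling schedule, so the whole pipeline is
testable without access to raw tracer data.

## Worked example

```python
from trlkin.synth import sample_parameters, generate_dataset, NoiseModel
from trlkin.fitting import fit_subject, FitConfig, derive_kinetics

truth = sample_parameters(seed=1, tier="normal")
dataset = generate_dataset(truth, protocol="fed",
                           noise=NoiseModel(cv_mass=0.05, cv_enrichment=0.05,
                                            seed=1))
result = fit_subject(dataset, FitConfig(n_starts=2, seed=1, max_nfev=40))
est = derive_kinetics(result.estimate)
true = derive_kinetics(truth.params)
print(f"fit cost: {result.cost:.3f}")
for row in ("apob48_basal_prod", "apob48_pp_prod", "apob48_cm_fcr",
            "apob100_vldl1_prod"):
    print(f"{row:22s} estimate {getattr(est, row):8.1f}"
          f"   truth {getattr(true, row):8.1f}")
```

prints

```
fit cost: 0.625
apob48_basal_prod      estimate     71.3   truth     69.5
apob48_pp_prod         estimate    202.2   truth    200.2
apob48_cm_fcr          estimate     15.9   truth     16.0
apob100_vldl1_prod     estimate    943.6   truth    933.0
```

i.e. the budgeted multistart fit of one noisy synthetic subject recovers
basal apoB48 secretion (mg/day), the meal-driven (postprandial) apoB48
secretion increment, the chylomicron apoB48 fractional catabolic rate
(pools/day) and hepatic apoB100 secretion to within a few percent of the
generating truth.

The same pipeline is available from the shell:

```sh
trlkin --seed 1 --out-dir out run --n 4
```

which writes per-subject datasets, ground-truth sidecars, fit results,
kinetic summaries, diagnostic figures and the cohort mean ± SD table.

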