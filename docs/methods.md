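# Methods

## Model structure and assumptions

The model couples conventional compartmental plasma PK with a
physiologically parameterized brain for two drugs at once: risperidone
(RIS) and its active metabolite paliperidone (PALI).

State, per drug: SC depot, plasma central and peripheral, brain vascular,
brain extra-vascular, free striatum, free cortex (amounts, nmol/kg), plus
D₂- and 5-HT₂A-bound concentrations (nM) shared pairwise between the drugs.
Eighteen states in total.

Key assumptions, and why:

- **Sequential structure.** Plasma PK is self-contained (brain holds <1% of
  the dose), so plasma parameters are estimated first and then fixed while
  brain distribution and binding are estimated from brain concentrations and
  occupancies. This mirrors how such sparse destructive-sampling data are
  analyzed in practice.
- **Metabolite stoichiometry.** RIS→PALI conversion (systemic CL_met and
  the IP first-pass fraction Fr_FPM) is mole-for-mole.
- **Unbound-only BBB transport.** Plasma↔brain-vascular exchange at
  cerebral blood flow acts on total concentrations; every transport across
  the BBB and within brain acts on unbound concentrations (fu_plasma on the
  vascular side, fu_brain elsewhere), and binding is driven by the unbound
  free-compartment concentration. Rationale: unbound drug equilibrates with
  the receptor biophase, and the nM-scale Kd values are comparable to
  in-vitro unbound affinities.
- **Efflux direction.** Linear active efflux moves unbound drug from the
  extra-vascular compartment back to the vascular compartment — the
  conventional abluminal-to-luminal P-gp representation. Saturable efflux is
  deliberately not implemented: observed brain concentrations (≤ ~2 µM) sit
  far below reported P-gp Km values (5.6–26 µM), so the linear form is the
  appropriate regime.
- **Fast regional equilibration.** Striatum and cortex free compartments
  exchange with the rest of brain through a large fixed clearance
  (500 L/h/kg), making them kinetically transparent except for binding.
- **Disjoint volumes.** The residual extra-vascular volume is
  V_ev = 0.00656 − V_st − V_cx = 0.00306 L/kg, so regional volumes never
  overlap ("total extra-vascular" is read as inclusive).
- **Plasma mass balance includes the brain exchange term.** The CL_bv flux
  appears in the plasma central equation; this conserves mass exactly and
  perturbs plasma by well under 1%.
- **Molecular weights** (needed because doses are mg/kg while binding works
  in nM) default to 410.5 (RIS) and 426.5 (PALI) g/mol, overridable in the
  parameter file.

## Parameters

All defaults are the published rat population estimates; units are per kg
body weight throughout (the source datasets carried no body weights).
The parameters that matter most in practice:

| parameter | default | unit | role |
|---|---|---|---|
| CL_RIS / CL_met / CL_PALI | 1.62 / 0.775 / 1.06 | L/h/kg | elimination and metabolite formation |
| V_c_RIS / V_c_PALI | 1.29 / 1.27 | L/kg | central volumes |
| F_IP, Fr_FPM | 0.412, 0.268 | – | IP bioavailability and first-pass split |
| CL_bev | 2.13 | L/h/kg | passive BBB clearance (shared) |
| CL_efflux RIS / PALI | 9.97 / 47.0 | L/h/kg | active efflux |
| Kd, koff, Bmax (D₂) | 0.463 nM, 0.671 h⁻¹, 245 nM | | striatal binding |
| Kd, koff, Bmax (5-HT₂A) | 0.219 nM, 0.525 h⁻¹, 46.5 nM | | cortical binding |

kon is always derived as koff/Kd and never estimated independently. On
sparse in-vivo data the absolute BBB clearances are not identifiable — only
the efflux-to-passive ratios are (4.68 for RIS, 22.1 for PALI); profiling
CL_bev upward leaves the likelihood flat, which the profiling routine
reports as an unbounded upper confidence limit.

## Synthetic data

The generator reproduces the statistical structure of the original twelve
rat studies: per-study drug, route, dose ladder, sampling times, observation
panel and animal count; destructive sampling (each animal is observed at
exactly one time point); log-normal inter-individual variability on six
plasma parameters (p·exp(η), η ~ N(0, ln(1+CV²)); CVs 16–91%); exact
log-normal proportional residual error on concentrations (σ as SD of the
log residual: 0.233/0.186 plasma, 0.362/0.424 brain for RIS/PALI); additive
Gaussian error in percentage points on occupancy (17.7 / 18.2). Occupancy
observations are deliberately not truncated to [0, 100]: the additive error
model implies overshoot, and truncation would bias the likelihood. Animals
are allocated to (dose × time) cells as evenly as possible, remainder to the
earliest cells. Below-LOQ censoring is available but off by default (the
original limits are not public); censored rows are flagged, kept in files,
and excluded from estimation.

What the generator does **not** emulate: body-weight covariates,
rat-strain or laboratory effects, in-vivo vs ex-vivo assay differences, and
inter-occasion variability. Passing tests therefore demonstrate internal
consistency of the pipeline under the stated stochastic structure, not
robustness to these real-data features.

## Estimation

Naive-pooled maximum likelihood: each animal's prediction is the noiseless
population simulation of its arm, with no per-animal random effects. With
one time point per animal the data cannot support conditional (mixed-effect)
estimation, and variability fixed to zero was already the accepted choice
for all brain parameters; the cost is that residual σ estimates absorb the
simulated inter-individual variability (plasma σ̂ ≈ 0.6–0.75 instead of
0.233 when IIV is on), which is expected and documented rather than a
defect. Fixed-effect recovery is the quantity of interest.

- OFV = −2 log L with log-normal concentration residuals and additive
  occupancy residuals. Residual σ's have closed-form conditional MLEs
  (σ̂² = RSS/n per observation class) and are profiled out analytically
  during optimization; `neg2ll` also accepts them as explicit parameters.
- Positive parameters are optimized on the log scale, bioavailabilities on
  the logit scale; L-BFGS-B with finite-difference step 10⁻³ (log scale),
  multi-started from log-uniform ×/÷3 perturbations. The plasma stage uses
  8 starts at up to 400 iterations: the likelihood contains a nearly flat
  joint rescaling direction of (V, F, CL) — ΔOFV ≈ 2.5 across a ±20%
  slide — that shorter runs fail to traverse. The brain stage (9 parameters)
  uses 5 starts with short exploration and a long polish of the best start.
- Plasma-stage predictions use the closed-form linear plasma model
  (piecewise matrix exponentials, exact for the plasma submodel and omitting
  only the <1% brain feedback); brain-stage predictions integrate the full
  stiff system (LSODA) per unique dose arm, not per animal.
- A flat-likelihood diagnostic flags parameters whose ±20% perturbation
  moves the OFV by <0.05 (e.g. every PALI disposition parameter when PALI
  observations are absent) instead of reporting confident estimates.
- Profile-likelihood CIs fix one parameter, re-optimize the rest
  (warm-started), bracket the ΔOFV = 3.84 crossing by multiplicative
  expansion and bisect in log space to 1% relative tolerance; a crossing
  never reached within the search range is reported as an unbounded limit.
- The bootstrap resamples animals with replacement within study strata
  (preserving per-study counts exactly), refits warm-started from the point
  estimate, and reports medians with 5th/95th percentiles; non-converged
  replicates are excluded and counted.
- Nested-model comparison at ΔOFV > 6.64 (p < 0.01, χ²₁) is exposed as a
  utility; no automated model search is performed.

## Numerical choices

- Stiff LSODA integration; the fast regional exchange (500 L/h/kg into
  sub-mL volumes) makes the system stiff. Reference tolerances
  rtol 10⁻⁸ / atol 10⁻¹⁰ nmol/kg; fitting and dataset generation use
  rtol 10⁻⁶ / atol 10⁻⁹ for speed (errors far below the residual noise).
- Integration restarts at every bolus time and zero-order on/off boundary,
  so discontinuities never fall inside a solver step. States are reported
  post-dose at t = 0 and pre-dose at later dose times.
- States are clipped at zero only when computing observables; a state more
  negative than 10⁻⁶ of the trajectory scale, or a bound pool exceeding
  Bmax by more than 10⁻⁶, aborts the simulation as an integrator failure.
- The ODE right-hand side is compiled with numba; first call in a fresh
  environment pays a few seconds of JIT cost.

## The brain-to-plasma experiment

Ratios are simulated per scenario at the design doses and times (≥0.25 h,
population parameters, no variability) and summarized as median ratio per
quintile bin of log plasma concentration — the ratio-vs-concentration
presentation in which the phenomena are defined. Points are kept only when
both plasma and brain concentrations clear a 1 ng/mL quantification floor
(a routine LC-MS/MS limit, configurable), matching how observed ratios are
reported; without it, sub-picomolar tails 4–5 orders below any assay's range
dominate the lowest bin, where the bound pool's kinetic lag distorts the
ratio (e.g. the 10× clearance scenario changes binned medians by ≤0.9%
everywhere observable but by 18% in that unobservable tail, and the
no-efflux scenario can locally *lower* the risperidone ratio because brain
paliperidone, no longer effluxed, displaces risperidone from receptors).

Headline metrics with the published parameters: the final model's
low-to-high-concentration ratio factor is 7.2 (strongly declining); the
D₂-only variant is flat (1.008) for brain-minus-striatum; removing efflux
raises binned ratios everywhere; 10× brain clearances change them by <1%.
Raising Kd 10× by raising koff flattens the curve from 7.2 to 1.75
(total brain; 1.20 for the matching region under the receptor-specific
variants) — a strong qualitative flattening, though a perfectly constant
ratio is not reachable: even at 10× Kd the equilibrium bound/free
contribution at low concentration is ≈0.9 for total brain, so an
irreducible ≈1.8-fold contrast remains built into the parameter values.

## Problem sizes

Desk-scale defaults, chosen so the full pipeline runs in minutes on one
CPU: parameter recovery uses the twelve designs at replication multiplier 10
(2,820 animals, one fit of each stage); the predictive check uses 500
simulated replicates of the two occupancy time-course studies (the richest
strata) with a 90% band; the bootstrap default is 1,000 replicates from the
CLI but tests exercise it at small counts. All experiments are bit-for-bit
reproducible under a fixed seed.

## Known limitations

- Absolute CL_bev, CL_efflux are reported but only their ratios are
  identifiable from data of this design; treat the absolute values as
  conditional on the transport-speed regime.
- The naive-pooled σ estimates conflate residual and inter-individual
  variability by construction.
- Binding constants are shared between RIS and PALI and between in-vivo and
  ex-vivo assays; drug- or assay-specific constants are not estimable from
  these designs and are not attempted.
- Binding to receptors other than D₂ and 5-HT₂A (α-adrenergic, 5-HT₇, H₁)
  is outside the model; their low densities or affinities make a material
  contribution to brain kinetics unlikely, but the model cannot test this.
- No lag-time absorption models and no saturable efflux: observed brain
  concentrations sit far below P-gp saturation, and absorption lag times add
  parameters these sparse designs cannot support.
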