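# Methods

## The model

`mdzpopkit` implements a composite population-pharmacokinetic model of
midazolam (MDZ) and its CYP3A-formed metabolite 1'-OH-midazolam (OHMDZ) in
healthy adults, together with the machinery needed to use it for drug–drug
interaction (DDI) screening: trial simulation, mixed-effects estimation,
predictive checks and a clearance cut-point classifier.

Each analyte has a central and two peripheral compartments with linear
distribution and elimination. Oral midazolam is absorbed first-order
(rate `ka`); systemic midazolam is eliminated entirely by conversion to the
metabolite through the metabolic clearance `Qmet` [L/h]; the metabolite is
eliminated with clearance `CLmet` [L/h]. First-pass (pre-systemic)
metabolism is modelled as a parallel depot: an oral dose `D` splits into
`F·D` entering the absorption depot and `(1−F)·fm·D` entering a
pre-systemic depot that feeds the metabolite's central compartment at rate
`kmet` [1/h]. This reproduces the higher metabolite exposure seen after
oral versus intravenous dosing while leaving `F` interpretable as systemic
availability. The systemic fraction metabolized `fm` is fixed to 1
(midazolam is almost completely cleared via CYP3A); 0.8/0.6 are accepted
for sensitivity runs. Amounts are carried in nmol and concentrations in nM
(mg doses are converted with configurable molar masses, defaults
325.8/341.8 g/mol); parent→metabolite conversion is therefore
mole-for-mole.

All rate "Q" parameters are treated as clearances in L/h acting on
concentrations (flux `Q·C`), which makes the system dimensionally
consistent. The default typical values, variabilities and error terms ship
in `mdzpopkit/data/table3_final.yaml` (constitutive model) and
`table3_interaction.yaml` (adds the treatment effects).

### Covariates

Body weight scales the first metabolite inter-compartmental clearance by a
power model, `Qmp_i = Qmp·(WT/70)^0.986`. An analogous age exponent on
`kmet` is carried in the configuration but disabled by default (the
covariate was examined and not retained in the final model).

### Random effects

Nine structural parameters carry log-normal inter-individual variability
(IIV, `eta`), with one off-diagonal term: the correlation 0.731 between
the central-volume etas of parent and metabolite. The printed value is
interpreted as a correlation, not a covariance — as a covariance it would
exceed the Cauchy–Schwarz bound given the two variances (0.378, 0.398).
Inter-occasion variability (IOV, `kappa`) applies to `F`, `Qmet` and
`CLmet`; an occasion is one whole dosing-plus-sampling block.

Individual bioavailability `F_i = F·e^(eta+kappa)` is a physical fraction.
The simulator truncates it by redrawing `(eta_F, kappa_F)` when a draw
exceeds 1 (eta_F is independent of the other effects, so their joint law
is untouched); the likelihood clamps `F_i` at `1−1e−9` so that optimizer
excursions cannot flip the first-pass dose split negative.

### Residual error and censoring

A "two-step" proportional error: separate magnitudes before and after a
split time measured from the most recent oral dose — 0.5 h (the
approximate absorption peak) for constitutive activity and induction, with
per-analyte pairs (MDZ 0.503/0.149, OHMDZ 0.556/0.215), and 1.5 h with a
single pair (0.483/0.267) for both analytes under inhibition, whose
absorption peak is delayed. Magnitudes are stored as absolute values (a
proportional SD is sign-invariant). Simulated errors are truncated at
`eps > −1` by redrawing, since concentrations are physical. Observations
below the limit of quantification are flagged (`BLQ`, `MDV`) and omitted
from all likelihoods; the simulated value is kept in the table for audit.
The default LLOQ of 0.01 nM sits near the sensitive end of the assay range
and censors essentially only the structural pre-dose zeros (<1% of
post-dose records).

### Treatment (DDI) effects

CYP3A modulation enters as categorical covariates on the typical values:
additive deltas on `kmet`, `Qmet`, `CLmet` and `Vc`, and a fractional
change on `F` (`F → F·(1+f_F)`). Inhibition is split into a reversible
component (competitive inhibitors such as ketoconazole/voriconazole) and
an irreversible component (mechanism-based inactivators such as
ritonavir), which differ most strongly in their effect on metabolite
clearance (−64.1 vs +1117 L/h). Induction raises `Qmet` by 38 L/h and
`kmet` by 12.4 1/h while lowering `F` by 20%. Perpetrator concentrations
are not modelled; the inhibition time-course is out of scope.

## The synthetic-trial generator

The original clinical datasets are not public; the generator is the
package's stand-in and defines its study conditions. It emulates the
source designs: oral (3 mg), iv (1 mg) and semi-simultaneous
(oral + iv 6 h later) dosing; rich sampling to 24 h, a semi-simultaneous
14 h grid, and the limited schedule (pre-dose, 2, 2.5, 3, 4 h); parallel
arms for the four CYP3A conditions; weights from a truncated normal
(mean 71.7 kg, SD 12, range 47–111) and ages likewise (26.9 y, SD 7,
19–52), 60% male — means and ranges from the pooled trial population, the
SDs chosen as plausible for healthy volunteers since only ranges are
printed. Occasions restart their clock at zero; an observation at a dose
time records the post-dose state. Everything is deterministic given the
design and one integer seed (byte-identical CSV output).

What the generator does not emulate: assay calibration drift, sampling
logistics, dropout, weak/moderate perpetrator potencies, and the
inhibition time-course. Passing recovery tests therefore show that the
estimation machinery is consistent with its own generative model under
realistic designs — not that the model describes any particular real
trial.

## Numerics

The system is linear and time-invariant between dose events, so profiles
are propagated exactly with matrix exponentials via eigendecomposition of
the 9-state rate matrix (8 kinetic states plus cumulative metabolite
elimination for mass accounting), with `scipy.linalg.expm` as fallback for
near-defective matrices. There is no step-size control; accuracy is linear
algebra round-off (mass balance holds to ~1e−10 relative; agreement with a
stiff `solve_ivp` reference is well inside 1e−6). The propagator is
batched: a whole finite-difference stencil of parameter sets is solved in
one vectorized call, which is what makes likelihood work fast.

## Estimation

The marginal likelihood over (eta, kappa) is approximated Laplace-style.
For each candidate value of the free parameters, every subject's joint
−2 log-likelihood (data term with the proportional error, plus the
multivariate-normal priors of eta and the per-occasion kappas) is
minimized over the random effects — the MAP / empirical-Bayes step — and
the outer objective is the profiled value plus a Gauss–Newton Laplace
curvature term `log det(H/2) − d·log 2π` with `H ≈ 2JᵀJ + 2P` (J the
residual Jacobian, P the prior precision), obtained from the same
finite-difference stencil as the gradient. The curvature term is not
cosmetic: for weakly identified parameters (notably `kmet`, whose
pre-systemic depot half-life of 2–5 min is shorter than the first sampling
time) omitting it biases recovery severely.

The inner MAP problem is solved with a Levenberg-damped Gauss–Newton
iteration (the objective grows like `e^{2z}` away from the mode, which
breaks standard polynomial line searches; a damped step never leaves the
trust region), warm-started across outer evaluations, with a safeguarded
quasi-Newton fallback and jittered restarts. Free population parameters
are profiled on the log scale (logit for `F`) with bounded Brent search,
tolerance 1e−4 on the internal scale — far below the 6–25% statistical
uncertainty of any quantity estimated here. Predictions are floored at
1e−12 nM inside the likelihood. Treatment deltas are estimated on their
natural additive scale with positivity-preserving bounds, base model
fixed (the two-stage approach); subjects in unaffected arms contribute a
constant and are skipped. BLQ records are omitted (M1-style).

Eta-shrinkage is reported as `1 − SD(eta_hat)/omega`. Expect substantial
shrinkage for `Qmet` on single oral profiles: such a profile identifies
`CL/F`, not `CL`, so individual `Qmet` deviations shrink toward the arm
typical value — which is precisely why per-profile `Qmet` EBEs classify
DDI status so cleanly.

### Parameter uncertainty (SIR)

Sampling importance resampling with the published five-iteration schedule
(1000/1000/1000/2000/2000 samples, 200/400/500/1000/1000 resamples). The
initial multivariate-normal proposal doubles as a reference prior: each
iteration weights samples by `L(θ)·q0(θ)/q_i(θ)`, resamples without
replacement, and refits the proposal. The stationary target is the
prior-tempered posterior, so a flat likelihood reproduces the proposal
itself, while with a wide proposal the CIs converge to the likelihood's
own; CIs are percentile-based and asymmetric. Low effective sample size
(<5% of samples) triggers covariance inflation and a retry.

## Diagnostics

The VPC simulates replicate trials of the same design, dose-normalizes
concentrations to a 4 mg midazolam dose (per occasion, by total
administered dose), bins observations at their nominal protocol times
(bins with <3 observations merge into a neighbor), and compares observed
2.5/50/97.5 percentiles with 90% simulation intervals. Bins within one
trial are strongly correlated through the shared random-effect draws, so
per-trial bin coverage is dispersed around its nominal level. Residual
tables report IPRED (MAP random effects), PRED (typical individual),
`IWRES = (DV−IPRED)/(σ·IPRED)` and an FO-style population residual with
weight `σ·PRED` — an approximation of conditional weighted residuals, not
exact CWRES.

## Classification

The DDI call for a profile is a one-level decision tree on its estimated
`Qmet`: below 16.4 L/h → inhibition, 16.4–41.8 → no modulation, ≥41.8 →
induction (thresholds shipped in `paper_cutpoints.json`; boundary values
belong to the upper interval — the printed ranges touch without stating
ownership). `learn_cutpoints` recovers such thresholds by exhaustive
search over all midpoint pairs maximizing training accuracy with a
deterministic smallest-thresholds tie-break — equivalent to the one-rule
("OneR") optimum at these data sizes. Reversible and irreversible
inhibition collapse to a single class; classification uses per-profile
(subject × occasion) EBEs. With the full generative variability
(ω² + π² ≈ 0.245 on log `Qmet`), the true per-profile clearances of
adjacent conditions overlap; EBE shrinkage toward arm-typical values is
what keeps the assignment accurate.

## Problem sizes

Recovery studies use 40 constitutive subjects (oral 3 mg and iv 1 mg
occasions, rich 24 h sampling) plus modulated arms of 12 (induction) or
16 (inhibition) subjects — the scale of the source trials; reported point
estimates are medians over five seeded replicates, whose ~4–13% precision
follows from the random-effect variances at these sample sizes (per-seed
SD ≈ sqrt(ω²_eff/N)). VPCs in the validation suite use 200–500 replicate
simulations; the conventional 1000 is the default in `run_vpc`.

## Known limitations

- No enterohepatic recirculation, transit/lag absorption, or nonlinear
  elimination; perpetrators are categorical, with no potency gradation.
- The Laplace/Gauss–Newton objective is not bit-compatible with any
  specific linearization-based tool; OFVs are comparable within this
  package only.
- Exact CWRES and prediction-corrected VPC are not implemented.
- `kmet` is intrinsically weakly identified by post-15-min sampling;
  its estimates lean on the curvature term and carry wide uncertainty.
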