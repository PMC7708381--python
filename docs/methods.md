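# Methods

This note documents the models, procedures and numerical choices behind
`adcpk`, and what the synthetic-data experiments do and do not demonstrate.

## Structural PK model

Both analytes are expressed as MMAE-equivalent mass (the conjugate assay
reports the MMAE still attached to the antibody), in internal units of
micrograms, litres and days; concentrations are reported in ng/mL through the
µg/L ≡ ng/mL equivalence.

The conjugate (acMMAE) follows a two-compartment model with zero-order
infusion input and a time-dependent linear clearance
`CL(t) = CL_inf + CL_t·exp(−k_des·t)`. `t` is anchored at the simulation
origin (the first dose of a standard regimen), not at each dose event: the
declining clearance is a property of the treatment course, and anchoring at a
fixed origin keeps the system linear time-varying, so superposition of
single-dose solutions on the shared clock holds exactly — a property the test
suite exploits.

Unconjugated MMAE is formation-rate-limited: a one-compartment model driven
by the fraction `frac_ns` of the conjugate clearance flux,
`dA_m/dt = frac_ns·CL(t)·C_ac − (cl_m/v_m)·A_m`. Because the payload equation
is linear in `frac_ns` and the conjugate does not depend on it, any
multiplicative effect on `frac_ns` propagates exactly proportionally into
every payload exposure metric — the analytic oracle used for the
effect-recovery tests.

This structural form is *representative of*, not identical to, the published
two-analyte model for this drug, whose full equations are not reprinted in
the open literature. Target-mediated disposition, the total-antibody analyte
and nonlinearity outside the clinically used dose range are out of scope.

### Default parameter values (calibrated stand-ins)

Only two covariate coefficients are literature values: the bodyweight power
0.73 on conjugate clearance and the +19% proportional shift on `frac_ns` for
hepatic impairment. Every other typical value, covariate coefficient and
variance is a calibrated stand-in chosen **once**: typical values were set so
the 75-kg reference patient at 1.8 mg/kg every 3 weeks reaches Cycle-6
exposures near the published geometric-mean magnitudes (conjugate AUC
≈ 2.9·10³ ng·day/mL, Cmax ≈ 7.3·10² ng/mL; payload AUC ≈ 21 ng·day/mL, Cmax
≈ 2 ng/mL), and the anti-CD20 combination coefficients (−15.5% on CL_inf,
−38% on `frac_ns`) reproduce the published sensitivity directions (+18%
conjugate AUC, ≈−38% payload). Defaults: CL_inf 0.78 L/day, CL_t 0.30 L/day,
k_des 0.12 /day, V1 3.2 L, Q 0.55 L/day, V2 3.0 L, frac_ns 0.14, CL_m
15 L/day, V_m 45 L, dose_conv 16.75 µg/mg (≈ drug-to-antibody ratio 3.5 ×
payload/antibody mass ratio). Ω is diagonal with log-scale SDs (0.20, 0.15,
0.30, 0.35, 0.30) on (CL_inf, V1, k_des, frac_ns, CL_m), which reproduces the
published exposure CV% ranges (≈20% conjugate AUC, ≈45% payload AUC); residual
log-scale SDs are 0.20 (conjugate) and 0.25 (payload).

`frac_ns` is clipped at 1 (with a warning) if covariates and eta push it
above the physical bound.

### Numerical solution

The system is linear, smooth and non-stiff at physiological parameter values
(all rate constants ≲ 0.5/day), so it is integrated with a fixed-step
classical Runge–Kutta scheme on a grid whose nodes include every infusion
start/end and observation time, compiled with numba. The default maximum step
is 0.02 d (0.05 d for population-simulation replicates); at these steps the
solution agrees with an adaptive LSODA reference and with the one-compartment
closed form to better than 10⁻⁶ relative, far inside the 0.1% tolerance the
tests assert. The compiled kernel matters because MAP estimation and the
NPDE/VPC diagnostics perform ~10⁵–10⁶ profile solves per analysis. Negative
solution values beyond a 10⁻⁹ relative tolerance raise an error rather than
being clipped; values inside the tolerance are snapped to zero.

Cycle-6 exposures are the interval AUC over the sixth dosing interval
[105, 126) d (trapezoid on a 0.01 d grid near the infusion / 0.25 d
elsewhere, with step-halving refinement until the AUC changes < 0.1%) and the
maximum concentration on that grid. Interval AUC (AUC_tau) was chosen over
cumulative AUC as the standard pharmacometric convention for exposure after
repeated dosing.

## Virtual population

The generator reproduces the *marginal* structure of the model-building
population: ~59% male; sex-conditional truncated-lognormal bodyweight
(medians 80/66 kg, range 38–146 kg); truncated-normal age (mean 64, SD 12,
range 20–89); hepatic categories sampled (≈12% mild, ≈0.4% moderate) with
AST/ALT/bilirubin drawn consistently with the category bands; creatinine
sampled lognormally and creatinine clearance **derived** via Cockcroft-Gault,
so the stored renal band always matches the classifier; albumin normal
(39 ± 4.5 g/L) with a configurable −4 g/L shift for hepatically impaired
subjects (the one documented covariate correlation); flags for ECOG ≥ 1,
treatment-naïve status, anti-CD20 and bendamustine co-administration and
manufacturing material. The real joint covariate distribution is not public;
all other covariates are sampled independently, and passing tests therefore
demonstrate procedure correctness under *known* conditions, not realism of
covariate correlations. Dropout, race effects and CLL patients are not
modelled.

Classifier boundary conventions follow the printed band wording: bilirubin
exactly 1×ULN is normal, the mild band is (1, 1.5]×ULN, moderate (1.5, 3],
severe > 3; AST > ULN with normal bilirubin is mild (group B2). Renal bands
use ≥90 / 60–89 / 30–59 / 15–29 / <15 mL/min. Eligibility excludes AST or
ALT > 2.5×ULN, bilirubin ≥ 1.5×ULN, or CrCL < 40 mL/min. An optional,
default-off flag reclassifies isolated bilirubin elevation (Gilbert's
syndrome) as normal hepatic function; when enabled, stored categories may
deliberately disagree with the raw classifier.

Sampling schedules: the rich design takes a pre-dose sample plus eight
post-dose samples in cycles 1 and 6 and a trough every cycle; the sparse
design one post-infusion sample and one trough per cycle. Observations get
lognormal proportional residual noise and are censored below the LLOQ
(0.359 / 0.0359 ng/mL); censoring is monotone in the LLOQ by construction.

## Empirical-Bayes (MAP) estimation

Per subject the eta vector minimises
`Σ_obs [log σ²_a + (log y − log f(η))²/σ²_a] + ηᵀΩ⁻¹η` over the non-censored
observations (log-transformed proportional error). Censored records are
simply excluded (M1-style); a censored-likelihood (M3) treatment is a noted
extension point. Optimisation is L-BFGS-B within |η| ≤ 4 from three starts
(0, ±0.5 on every coordinate), objective tolerance 10⁻⁸, with a polish
restart when the line search aborts; infeasible parameter regions return a
large smooth penalty rather than infinities so finite-difference gradients
stay defined. Subjects without usable observations receive η = 0 flagged
`"prior"`; non-converged subjects are flagged, never dropped. Shrinkage is
`100·(1 − SD_{n−1}(EBE_k)/√Ω_kk)`; dimensions with Ω_kk = 0 are reported
missing.

A MAP estimate equals the generating etas only when the residual-variance
weight is negligible, so the noise-free recovery tests estimate under the
generating model with σ² = 10⁻¹² — the reading under which 10⁻³ recovery is
meaningful.

## Covariate correction and subgroup comparison

`correct_covariates` replaces the frozen covariate fields by reference values
(idempotent; the factor under assessment, including its underlying laboratory
fields, may never be frozen). pCC freezes exactly {disease state →
relapsed/refractory, anti-CD20 co-administration → active}, minus whichever
of the two is itself assessed; cCC freezes every model covariate. Corrected
exposures are simulated with each subject's own etas and with the dose
computed from the *corrected* bodyweight, so a cCC cohort is dosed uniformly
— with all etas zero, cCC exposures are identical across subjects and every
GMR is 1 to machine precision.

Reference values: relapsed/refractory disease and active anti-CD20
combination are fixed by the procedure's definition; all other reference
values are the generator medians (75 kg, 39 g/L albumin, female, ECOG 0,
normal organ function, liquid-formulation material). Note the correction
reference intentionally sets an effect-carrying level (combination active);
the model-coding reference patient (all multipliers 1) is the single-agent
female — the two notions are distinct.

Summary statistics follow the log-scale convention: GM = exp(mean log x),
CV% = 100·SD_{n−1}(log x). The GMR interval is a Welch two-sample t-interval
on the log scale (pooled-variance variant behind a flag); the published
analysis does not state its CI construction, so printed CIs are not treated
as reproduction targets — only GMRs, which are construction-independent.
Zero-spread degenerate groups collapse the interval to the point estimate.
GMRs recomputed from already-rounded GM pairs round half-away-from-zero at
the printed precision. Levels with fewer than two subjects are flagged, not
compared; no multiplicity adjustment is applied (matching the source
analysis); no bioequivalence gate is imposed.

## Sensitivity analysis

Typical-patient (population-prediction) ratios: etas and residual error are
ignored, one covariate at a time is moved to its empirical 2.5th/97.5th
percentile (10⁴ generator draws, fixed seed — the study's empirical
percentiles are unpublished) or to the non-reference category, the dose
follows the overridden bodyweight, and exposures are divided by the reference
patient's. Ratios are independent of Ω and Σ by construction. Published
sensitivity *magnitudes* for covariates whose coefficients are unpublished
(e.g. albumin) are not reproduction targets; directions and the bodyweight
bounds (< 25% conjugate, < 40% payload) are.

## Diagnostics (pc-VPC, NPDE)

Population simulation re-draws etas and residual noise per replicate on each
subject's observed design (doses, times, covariates); no EBE step, hence no
shrinkage. Below-LLOQ observations are excluded from both diagnostics (a
documented limitation; replicate values are not re-censored).

pc-VPC: each observed/simulated value is scaled by (bin-median population
prediction / subject's population prediction); bins are per-analyte quantile
bins of time-after-most-recent-dose (8 by default); the observed bin median
is compared with the 10th–90th percentile envelope of replicate bin medians;
empty bins are dropped with a warning. Under the true model ≈80% of bins are
covered; a 3× clearance misspecification drives coverage to ≈0.

NPDE: per subject, observations and simulations are decorrelated with the
empirical mean and lower-Cholesky covariance factor of that subject's K
simulations (ridge-regularised with a warning if singular); the rank of each
decorrelated observation among its simulations (ties split by a
tiny uniform jitter from a dedicated seed) gives
`pde ∈ [1/(2K), 1−1/(2K)]`, mapped through Φ⁻¹. Global tests: one-sample t
(mean 0), two-sided χ² (variance 1), Shapiro–Wilk (normality; D'Agostino
above n = 5000). Defaults K = 1000 (NPDE) and 500 (VPC). The rank step is
invariant to monotone per-design-point rescaling; post-decorrelation values
are not.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run the stochastic experiments at
sizes chosen to give adequate Monte-Carlo resolution for each claim:
effect-recovery cohorts N = 2000 (MC SE of log GMR ≈ 0.03, assertions at
≈3 SE); null-coverage 500 replicate studies of N = 40 (coverage SE ≈ 1.3%,
band ±3 points); EBE recovery/shrinkage N = 100 rich-design subjects; NPDE
calibration N = 100 / K = 1000, with the type-I-error rate over 100 replicate
studies at N = 20 / K = 150; pc-VPC coverage over 25 replicate studies at
N = 30 / K = 150. Unit tests use smaller fixtures with tolerances matched to
the statistic's dispersion at that size (e.g. the NPDE sample variance at 12
subjects has an across-dataset spread of roughly ±0.2, so only gross
miscalibration is asserted there).

## Known limitations

* Structural equations and most coefficients are calibrated stand-ins; the
  package validates *procedures* (correction, estimation, diagnostics), and
  its numerical outputs outside the two literature coefficients should not be
  read as properties of the real drug.
* BLQ data are discarded everywhere (no M3 likelihood, no censored-aware
  diagnostics).
* The EBE optimiser's convergence flag is conservative: in the degenerate
  near-zero-σ regime the line search may abort after reaching the minimum,
  leaving correct estimates flagged unconverged.
* The virtual population models marginals plus two documented correlations
  only; inference about real-data covariate confounding is out of reach of
  these tests.
* pc-VPC envelopes use replicate bin medians only (no percentile bands
  beyond the median profile, no graphics).
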