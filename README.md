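# adcpk

Population-pharmacokinetic simulation and covariate-impact analysis for a
two-analyte antibody–drug conjugate (ADC): the antibody-conjugated payload
(acMMAE, the conjugate measured as MMAE-equivalents) and the released
unconjugated payload (MMAE). The package is aimed at pharmacometricians who
need to ask, from an *established* population model rather than a new model
fit: *do patient subgroups — heavier patients, the elderly, males vs females,
hepatically or renally impaired patients, combination-therapy arms, a changed
manufacturing process — reach meaningfully different exposures under
bodyweight-based dosing?*

## The model and the method

Concentrations follow a linear time-varying compartment system. The conjugate
is two-compartment with zero-order infusion input and clearance

    CL(t) = CL_inf + CL_t · exp(−k_des · t),

the slowly decaying extra clearance being typical of ADCs over a treatment
course. Unconjugated MMAE is formation-rate-limited: a one-compartment model
whose input is the fraction `FRAC_NS` of the conjugate clearance flux,

    dA_m/dt = FRAC_NS · CL(t) · C_ac(t) − (CL_m / V_m) · A_m.

Inter-individual variability is lognormal (`exp(η)`, `η ~ MVN(0, Ω)`) on
CL_inf, V1, k_des, FRAC_NS and CL_m; residual error is proportional on the
log scale. Covariates act multiplicatively: power terms for continuous
covariates (notably bodyweight on conjugate clearance with exponent 0.73) and
proportional shifts for flags (notably +19% on FRAC_NS for hepatic
impairment).

On top of the simulator the package implements:

* **Empirical-Bayes (MAP) estimation** of each subject's η vector given the
  fixed population model, with η-shrinkage diagnostics
  `100·(1 − SD(EBE)/ω)`.
* **Partial / complete covariate correction (pCC / cCC)** — the core
  procedure: individual parameters are rebuilt from the typical values and
  each subject's own EBEs with selected covariates held at reference values
  (pCC freezes disease state → relapsed/refractory and anti-CD20
  co-administration → active; cCC freezes every model covariate), Cycle-6
  exposures (AUC and Cmax over the sixth 21-day interval of 1.8 mg/kg Q3W
  dosing) are re-simulated, and subgroups are compared by geometric means,
  log-scale CV%, and geometric mean ratios (GMR) with 90% Welch t-intervals.
* **Typical-patient sensitivity analysis**: exposure ratios at the 2.5th /
  97.5th covariate percentiles, ignoring inter-individual variability.
* **pc-VPC and NPDE** external-evaluation diagnostics against population
  simulation (no EBE step, hence shrinkage-free).
* A **virtual NHL population generator** reproducing the study population's
  marginal covariate structure, dosing regimen, rich/sparse sampling and
  below-LLOQ censoring (0.359 / 0.0359 ng/mL), so the whole pipeline is
  testable without patient data.

## Worked example

```python
import adcpk

model = adcpk.default_model()

# virtual cohort with noisy, censored observations and stored true etas
covs = adcpk.sample_covariates(200, seed=1)
patients = adcpk.simulate_dataset(model, covs, schedule="rich", seed=2)

# condition the fixed population model on each subject's data
result = adcpk.estimate_ebe(patients, model)
print({k: round(v, 1) for k, v in result.shrinkage.items()})

# pCC comparison of hepatically impaired vs normal subjects
spec = adcpk.pcc_spec("hepatic_category")
table = adcpk.corrected_exposures(patients, model, spec, etas="ebe")
comp = adcpk.compare_subgroups(table, "hepatic_category", "normal")
cols = ["level", "analyte", "metric", "n", "gm", "cv_pct", "gmr"]
print(comp[comp.metric == "auc"][cols].round(3).to_string(index=False))
```

prints:

```
{'cl_inf': -5.5, 'v1': 8.3, 'k_des': 65.9, 'frac_ns': -3.3, 'cl_m': 1.8}
   level analyte metric   n       gm  cv_pct   gmr
  normal  acmmae    auc 169 3262.169  24.141   NaN
    mild  acmmae    auc  30 3046.210  21.545 0.934
moderate  acmmae    auc   1 3847.464     NaN   NaN
  normal    mmae    auc 169   14.373  43.055   NaN
    mild    mmae    auc  30   15.665  56.070 1.090
moderate    mmae    auc   1   26.351     NaN   NaN
```

Reading: under the rich design the exposure-driving etas show essentially no
shrinkage (values near zero; small negative values simply mean the EBE sample
SD slightly exceeds ω at this cohort size), so the EBE-based correction is
trustworthy — only the weakly identified clearance-decay rate `k_des` shrinks
strongly. After correcting for disease state and co-administration, conjugate
exposure in the 30 mildly impaired subjects is similar to normal (GMR 0.93)
while unconjugated-MMAE exposure trends higher (GMR 1.09; the +19%
formation-fraction effect plus the lower albumin of impaired patients, which
pCC deliberately leaves in place, partly masked by sampling noise at n = 30).
The single "moderate" subject is reported with GM only — groups of fewer than
two subjects are flagged, never compared.

A command-line layer mirrors the library
(`adcpk simulate-pop | ebe | exposures | compare | sensitivity | vpc | npde |
run`); `adcpk run config.yaml` executes the whole pipeline and writes tidy
CSVs plus a reproducibility manifest.

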