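"""External-evaluation diagnostics: population simulation, pc-VPC and NPDE.

These compare an observed dataset against simulation from the population
model using only population-level variability (fresh etas and residual error
per replicate) — no individual empirical Bayes step — so they are free of
shrinkage and form the model-qualification counterpart to the EBE-based
correction analyses.

* The prediction-corrected visual predictive check (pc-VPC) normalises every
  observation and simulated value by its subject's population prediction
  (scaled to the bin-median prediction), then compares observed bin medians
  with the envelope of replicate bin medians.
* The normalised prediction distribution error (NPDE) decorrelates each
  subject's observation vector with the empirical mean and covariance of that
  subject's simulated vectors, ranks each decorrelated observation among its
  decorrelated simulations, and maps the rank to a standard-normal quantile.
  Under a correct model the NPDE sample is approximately N(0, 1).

Below-LLOQ observations are excluded from both diagnostics (documented
limitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ANALYTES,
    ETA_NAMES,
    ConfigurationError,
    IndividualParameters,
    InputError,
    PopulationModel,
    apply_covariates,
    profile_plan,
    simulate_profile,
    solve_plan,
)
from .population import PatientRecord, _omega_factor

__all__ = ["ReplicateSet", "VPCResult", "NPDEResult",
           "population_simulate", "pc_vpc", "npde"]


@dataclass
class ReplicateSet:
    """Population-simulation replicates aligned to the observed design.

    ``design`` has one row per non-censored observation (subject, analyte,
    time, observed value, population prediction, time after the most recent
    dose); ``sims`` is the (n_replicates, n_obs) matrix of simulated noisy
    concentrations on exactly that design.
    """

    design: pd.DataFrame
    sims: np.ndarray
    seed: int | None = None


@dataclass
class VPCResult:
    """pc-VPC bin summaries (one row per analyte x time bin)."""

    bins: pd.DataFrame
    pi: float
    n_replicates: int

    @property
    def coverage(self) -> float:
        """Fraction of bins whose observed median falls inside the envelope."""
        return float(self.bins["covered"].mean())


@dataclass
class NPDEResult:
    """Per-observation NPDE values with global calibration tests."""

    values: pd.DataFrame  # subject, analyte, time, npde
    mean: float
    variance: float
    tests: dict[str, tuple[float, float]]  # name -> (statistic, p-value)
    n_replicates: int


def _design_rows(patients: list[PatientRecord]):
    for pat in patients:
        obs = [o for o in pat.observations if not o.censored]
        if not obs:
            continue
        times = np.unique([o.time for o in obs])
        rows = np.array([ANALYTES.index(o.analyte) for o in obs])
        cols = np.searchsorted(times, [o.time for o in obs])
        y = np.array([o.concentration for o in obs], dtype=float)
        yield pat, times, rows, cols, y, obs


def _time_after_dose(pat: PatientRecord, t: float) -> float:
    prior = [d.time for d in pat.doses if d.time <= t]
    return t - max(prior) if prior else t


def population_simulate(model: PopulationModel, patients: list[PatientRecord],
                        n_replicates: int, seed: int = 0,
                        h_max: float = 0.05) -> ReplicateSet:
    """Simulate ``n_replicates`` fresh population replicates of the design.

    Each replicate re-draws etas from MVN(0, omega) and lognormal proportional
    residual noise per analyte, on the observed (non-censored) design points
    of every subject, with doses and covariates as observed.  Reproducible for
    a given seed.
    """
    if n_replicates < 2:
        raise ConfigurationError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    chol = _omega_factor(model.omega)
    sd = {a: float(np.sqrt(model.sigma[a])) for a in ANALYTES}

    design_rows = []
    sims_cols = []
    for pat, times, rows, cols, y, obs in _design_rows(patients):
        plan = profile_plan(pat.doses, times, model.dose_conv)
        base = apply_covariates(model, pat.covariates, None)
        pred = solve_plan(plan, base, h_max)[rows, cols]
        for o, p in zip(obs, pred):
            design_rows.append({
                "subject": pat.subject, "analyte": o.analyte, "time": o.time,
                "tad": _time_after_dose(pat, o.time), "observed": o.concentration,
                "pred": p,
            })
        block = np.empty((n_replicates, len(obs)))
        sig = np.array([sd[o.analyte] for o in obs])
        for k in range(n_replicates):
            etas = chol @ rng.standard_normal(len(ETA_NAMES))
            e = np.exp(etas)
            params = IndividualParameters(
                cl_inf=base.cl_inf * e[0], cl_t=base.cl_t, k_des=base.k_des * e[2],
                v1=base.v1 * e[1], q=base.q, v2=base.v2,
                frac_ns=min(base.frac_ns * e[3], 1.0),
                cl_m=base.cl_m * e[4], v_m=base.v_m)
            conc = solve_plan(plan, params, h_max)
            noise = np.exp(sig * rng.standard_normal(len(obs)))
            block[k] = conc[rows, cols] * noise
        sims_cols.append(block)

    if not design_rows:
        raise InputError("no usable (non-censored) observations in the dataset")
    design = pd.DataFrame(design_rows)
    sims = np.concatenate(sims_cols, axis=1)
    return ReplicateSet(design=design, sims=sims, seed=seed)


# ---------------------------------------------------------------------------
# pc-VPC
# ---------------------------------------------------------------------------

def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return edges


def pc_vpc(replicates: ReplicateSet, n_bins: int = 8, pi: float = 0.80) -> VPCResult:
    """Prediction-corrected VPC of the observed data against the replicates.

    Observations and simulations alike are corrected by
    ``value * median(PRED in bin) / PRED`` before the observed bin median is
    compared with the central ``pi`` envelope of the replicate bin medians.
    Bins are time-after-dose quantile bins per analyte; empty bins are dropped
    with a warning.
    """
    if not 0 < pi < 1:
        raise ConfigurationError("pi must lie in (0, 1)")
    design = replicates.design
    sims = replicates.sims
    lo_q, hi_q = 50 * (1 - pi), 50 * (1 + pi)

    out = []
    for analyte in ANALYTES:
        mask = (design["analyte"] == analyte).to_numpy()
        if not mask.any():
            continue
        sub = design[mask]
        tad = sub["tad"].to_numpy()
        pred = sub["pred"].to_numpy()
        obs = sub["observed"].to_numpy()
        sim = sims[:, mask]
        edges = _quantile_bins(tad, n_bins)
        which = np.digitize(tad, edges) - 1
        for b in range(len(edges) - 1):
            in_bin = which == b
            if not in_bin.any():
                warnings.warn(f"empty pc-VPC bin {b} for {analyte}; dropped",
                              stacklevel=2)
                continue
            pred_b = pred[in_bin]
            med_pred = np.median(pred_b)
            factor = med_pred / pred_b
            obs_med = float(np.median(obs[in_bin] * factor))
            rep_medians = np.median(sim[:, in_bin] * factor, axis=1)
            env_lo, env_hi = np.percentile(rep_medians, [lo_q, hi_q])
            out.append({
                "analyte": analyte, "bin": b, "tad_lo": float(edges[b]),
                "tad_hi": float(edges[b + 1]), "n_obs": int(in_bin.sum()),
                "obs_median": obs_med, "sim_median": float(np.median(rep_medians)),
                "ci_lo": float(env_lo), "ci_hi": float(env_hi),
                "covered": bool(env_lo <= obs_med <= env_hi),
            })
    return VPCResult(bins=pd.DataFrame(out), pi=pi, n_replicates=sims.shape[0])


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------

def npde(replicates: ReplicateSet, seed: int = 0, ridge: float = 1e-8) -> NPDEResult:
    """Normalised prediction distribution errors with global tests.

    Per subject, the observed vector and each simulated vector are
    decorrelated with the empirical mean and lower-triangular covariance
    factor of that subject's simulations; the prediction discrepancy
    ``pde = rank / K`` (ties split, uniform tie-breaking jitter from a
    dedicated seed) is clipped to ``[1/(2K), 1 - 1/(2K)]`` and mapped through
    the standard-normal quantile function.  Global tests: t-test of mean 0,
    a chi-square test of variance 1, and Shapiro-Wilk normality.
    """
    design = replicates.design
    sims = replicates.sims
    K = sims.shape[0]
    if K < 100:
        warnings.warn("NPDE with fewer than 100 replicates is unreliable",
                      stacklevel=2)
    jitter_rng = np.random.default_rng(None if seed is None else seed + 7919)

    npde_vals = np.empty(len(design))
    for subject, idx in design.groupby("subject", sort=False).groups.items():
        cols = design.index.get_indexer(idx)
        y = design.loc[idx, "observed"].to_numpy(dtype=float)
        block = sims[:, cols]
        m = block.mean(axis=0)
        cov = np.cov(block, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular simulation covariance for subject {subject}; "
                "ridge-regularised", stacklevel=2)
            scale = max(np.trace(cov) / cov.shape[0], 1e-300)
            L = np.linalg.cholesky(cov + ridge * scale * np.eye(cov.shape[0]))
        y_dec = np.linalg.solve(L, y - m)
        sims_dec = np.linalg.solve(L, (block - m).T)  # (n_i, K)
        eps = 1e-12 * np.maximum(np.abs(y_dec)[:, None], 1.0)
        tie_jitter = jitter_rng.uniform(-1.0, 1.0, size=sims_dec.shape) * eps
        below = (sims_dec + tie_jitter < y_dec[:, None]).sum(axis=1)
        pde = below / K
        pde = np.clip(pde, 1 / (2 * K), 1 - 1 / (2 * K))
        npde_vals[cols] = stats.norm.ppf(pde)

    values = design[["subject", "analyte", "time"]].copy()
    values["npde"] = npde_vals
    n = len(npde_vals)
    mean = float(np.mean(npde_vals))
    var = float(np.var(npde_vals, ddof=1))

    t_stat, t_p = stats.ttest_1samp(npde_vals, 0.0)
    chi2 = (n - 1) * var
    p_hi = stats.chi2.sf(chi2, n - 1)
    var_p = float(2 * min(p_hi, 1 - p_hi))
    if n <= 5000:
        w_stat, w_p = stats.shapiro(npde_vals)
    else:
        w_stat, w_p = stats.normaltest(npde_vals)
    return NPDEResult(
        values=values, mean=mean, variance=var,
        tests={"mean_zero_t": (float(t_stat), float(t_p)),
               "variance_one_chi2": (float(chi2), var_p),
               "normality": (float(w_stat), float(w_p))},
        n_replicates=K,
    )
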