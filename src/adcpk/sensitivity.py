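"""Typical-patient covariate sensitivity analysis.

Population predictions only: every subject with the same covariate value has
the same exposure (etas = 0, no residual error).  Each covariate is moved to
an extreme value (empirical 2.5th / 97.5th percentile of the generator's
distribution for continuous covariates, or the non-reference category for
flags) while all other covariates stay at reference, and the cycle-6
exposures are expressed as ratios to the reference (typical) patient.  The
dose follows the overridden bodyweight, so a bodyweight ratio reflects the net
effect of weight-based dosing and the sub-linear clearance power together.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ANALYTES, ConfigurationError, PopulationModel, apply_covariates
from .exposure import ExposureResult, cycle6_exposures
from .correction import DEFAULT_REFERENCE
from .population import CovariateRecord, PopulationConfig, sample_covariates

__all__ = ["reference_record", "typical_exposure", "sensitivity_table"]

_RECORD_FIELDS = set(DEFAULT_REFERENCE)

#: how a derived model flag is realised as a covariate-record override
_CATEGORY_OVERRIDES = {
    "male": {"sex": "male"},
    "hepatic_impaired": {"hepatic_category": "mild", "bili_xuln": 1.2},
    "ecog_ge1": {"ecog": 1},
    "treatment_naive": {"treatment_naive": True},
    "combo_rg": {"combo_rg": False},  # reference patient is R/G-treated
    "combo_benda": {"combo_benda": True},
}


def reference_record(overrides: dict | None = None) -> CovariateRecord:
    """The typical patient: every covariate at its reference value."""
    values = dict(DEFAULT_REFERENCE)
    if overrides:
        unknown = set(overrides) - _RECORD_FIELDS
        if unknown:
            raise ConfigurationError(f"unknown covariate override(s): {sorted(unknown)}")
        values.update(overrides)
    return CovariateRecord(**values)


def typical_exposure(model: PopulationModel, overrides: dict | None = None,
                     ) -> tuple[ExposureResult, ExposureResult]:
    """Cycle-6 exposures of the typical patient, optionally with overrides.

    With no overrides this is the reference exposure that all sensitivity
    ratios are divided by.
    """
    record = reference_record(overrides)
    params = apply_covariates(model, record, etas=None)
    return cycle6_exposures(params, record.bodyweight, model, subject="typical")


def sensitivity_table(model: PopulationModel,
                      config: PopulationConfig | None = None,
                      percentiles: tuple[float, float] = (2.5, 97.5),
                      continuous: tuple[str, ...] = ("bodyweight", "albumin",
                                                     "age", "tumor_spd"),
                      categorical: tuple[str, ...] = ("male", "hepatic_impaired",
                                                      "combo_rg", "treatment_naive",
                                                      "ecog_ge1", "combo_benda"),
                      n_quantile: int = 10_000,
                      seed: int = 2020) -> pd.DataFrame:
    """Tornado-style table of exposure ratios at extreme covariate values.

    Continuous covariate percentiles are empirical quantiles of ``n_quantile``
    generator draws at a fixed seed (the study's empirical percentile values
    are not public).  One row per covariate setting x analyte x metric;
    ``ratio`` is exposure at the setting divided by the reference exposure.
    Degenerate distributions (equal percentiles) give ratio 1 with a flag.
    """
    ref_ac, ref_m = typical_exposure(model)
    ref = {("acmmae", "auc"): ref_ac.auc_c6, ("acmmae", "cmax"): ref_ac.cmax_c6,
           ("mmae", "auc"): ref_m.auc_c6, ("mmae", "cmax"): ref_m.cmax_c6}

    sample = sample_covariates(n_quantile, config, seed=seed)
    rows = []

    def emit(covariate, setting, value_label, overrides, flag=""):
        if overrides is None:  # degenerate
            results = (None, None)
        else:
            results = typical_exposure(model, overrides)
        for analyte in ANALYTES:
            for metric in ("auc", "cmax"):
                if overrides is None:
                    ratio = 1.0
                else:
                    res = results[ANALYTES.index(analyte)]
                    value = res.auc_c6 if metric == "auc" else res.cmax_c6
                    ratio = value / ref[(analyte, metric)]
                rows.append({"covariate": covariate, "setting": setting,
                             "value": value_label, "analyte": analyte,
                             "metric": metric, "ratio": ratio, "flag": flag})

    for cov in continuous:
        values = np.array([getattr(rec, cov) for rec in sample], dtype=float)
        lo, hi = np.percentile(values, percentiles)
        if np.isclose(lo, hi):
            emit(cov, "degenerate", f"{lo:g}", None, flag="degenerate distribution")
            continue
        for pct, val in zip(percentiles, (lo, hi)):
            if cov in _RECORD_FIELDS:
                emit(cov, f"p{pct:g}", f"{val:.4g}", {cov: float(val)})
            else:
                raise ConfigurationError(f"unknown continuous covariate {cov!r}")

    for cov in categorical:
        overrides = _CATEGORY_OVERRIDES.get(cov)
        if overrides is None:
            raise ConfigurationError(f"unknown categorical covariate {cov!r}")
        emit(cov, "category", str(overrides), overrides)

    return pd.DataFrame(rows)
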