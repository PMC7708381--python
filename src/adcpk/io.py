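"""Dataset and configuration I/O plus the end-to-end pipeline driver.

The rectangular analysis dataset follows the nonlinear-mixed-effects
convention: one row per event, ``EVID`` 1 for dose rows (carrying ``AMT`` in
mg and ``DUR`` in days) and 0 for observation rows (carrying ``DV`` in ng/mL,
``CMT`` 1 for the conjugate / 2 for unconjugated MMAE, and a ``BLQ`` flag with
the ``LLOQ`` used).  Comma-separated, dot decimal, mandatory header, missing
values as empty cells.  Time is in **days**, not hours.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    ANALYTES,
    ETA_NAMES,
    ConfigurationError,
    CovariateEffect,
    DoseEvent,
    InputError,
    PopulationModel,
    default_model,
)
from .population import (
    CovariateRecord,
    ObservationRecord,
    PatientRecord,
    PopulationConfig,
    sample_covariates,
    simulate_dataset,
)
from .ebe import estimate_ebe
from .correction import ccc_spec, compare_subgroups, corrected_exposures, pcc_spec
from .diagnostics import npde, pc_vpc, population_simulate
from .sensitivity import sensitivity_table

__all__ = [
    "AnalysisDataset", "read_dataset", "write_dataset",
    "model_to_yaml", "model_from_yaml",
    "write_etas", "read_etas", "add_factor_columns", "run_pipeline",
]

log = logging.getLogger("adcpk")

_COV_COLUMNS = (
    "bodyweight", "age", "sex", "albumin", "ast_xuln", "alt_xuln", "bili_xuln",
    "hepatic_category", "serum_creatinine", "crcl", "renal_category",
    "b_cell_count", "tumor_spd", "ecog", "treatment_naive", "combo_rg",
    "combo_benda", "material",
)
_MANDATORY = ("ID", "TIME", "AMT", "DUR", "DV", "EVID", "CMT", "BLQ", "LLOQ")
_CMT_TO_ANALYTE = {1: "acmmae", 2: "mmae"}


@dataclass
class AnalysisDataset:
    """A validated rectangular dataset plus its patient-record view."""

    frame: pd.DataFrame
    patients: list[PatientRecord]

    def __len__(self) -> int:
        return len(self.frame)


def write_dataset(patients: list[PatientRecord], path) -> pd.DataFrame:
    """Serialise patient records to the rectangular CSV; returns the frame."""
    rows = []
    for pat in patients:
        cov = {c: getattr(pat.covariates, c) for c in _COV_COLUMNS}
        for d in pat.doses:
            rows.append({"ID": pat.subject, "TIME": d.time, "AMT": d.amount,
                         "DUR": d.duration, "DV": None, "EVID": 1, "CMT": 1,
                         "BLQ": 0, "LLOQ": None, **cov})
        for o in pat.observations:
            rows.append({"ID": pat.subject, "TIME": o.time, "AMT": None,
                         "DUR": None, "DV": o.concentration, "EVID": 0,
                         "CMT": 1 + ANALYTES.index(o.analyte),
                         "BLQ": int(o.censored), "LLOQ": o.lloq, **cov})
    frame = pd.DataFrame(rows, columns=list(_MANDATORY) + list(_COV_COLUMNS))
    frame = frame.sort_values(["ID", "TIME", "EVID", "CMT"],
                              ascending=[True, True, False, True],
                              kind="stable").reset_index(drop=True)
    frame.to_csv(path, index=False)
    return frame


def read_dataset(path) -> AnalysisDataset:
    """Read and validate a rectangular dataset.

    All violations (missing columns, unsorted times, dose/observation field
    mix-ups, unknown analyte codes) are collected with their row numbers and
    reported in a single error.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise InputError(f"dataset lacks mandatory column(s) {missing}")

    problems: list[str] = []
    for sid, grp in frame.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            row = grp.index[np.argmax(np.diff(t) < 0) + 1]
            problems.append(f"row {row}: times of subject {sid} not sorted")
    for row, rec in frame.iterrows():
        evid = rec["EVID"]
        if evid == 1:
            if pd.isna(rec["AMT"]) or pd.isna(rec["DUR"]):
                problems.append(f"row {row}: dose row without AMT/DUR")
            if not pd.isna(rec["DV"]):
                problems.append(f"row {row}: dose row carries an observation")
        elif evid == 0:
            if not pd.isna(rec["AMT"]):
                problems.append(f"row {row}: observation row carries AMT")
            if int(rec["CMT"]) not in _CMT_TO_ANALYTE:
                problems.append(f"row {row}: unknown analyte code {rec['CMT']}")
            if pd.isna(rec["DV"]) and not rec["BLQ"]:
                problems.append(f"row {row}: observation row without DV or BLQ")
        else:
            problems.append(f"row {row}: unknown EVID {evid}")
    if problems:
        raise InputError("invalid dataset:\n  " + "\n  ".join(problems))

    patients: list[PatientRecord] = []
    for sid, grp in frame.groupby("ID", sort=False):
        first = grp.iloc[0]
        cov_kwargs = {}
        for c in _COV_COLUMNS:
            if c in grp.columns:
                v = first[c]
                if c in ("treatment_naive", "combo_rg", "combo_benda"):
                    v = bool(v)
                elif c == "ecog":
                    v = int(v)
                cov_kwargs[c] = v
        cov = CovariateRecord(**cov_kwargs)
        doses = tuple(
            DoseEvent(time=float(r["TIME"]), amount=float(r["AMT"]),
                      duration=float(r["DUR"]))
            for _, r in grp[grp["EVID"] == 1].iterrows())
        obs = tuple(
            ObservationRecord(
                subject=int(sid), analyte=_CMT_TO_ANALYTE[int(r["CMT"])],
                time=float(r["TIME"]),
                concentration=None if r["BLQ"] else float(r["DV"]),
                censored=bool(r["BLQ"]), lloq=float(r["LLOQ"]))
            for _, r in grp[grp["EVID"] == 0].iterrows())
        patients.append(PatientRecord(subject=int(sid), covariates=cov,
                                      doses=doses, observations=obs))
    return AnalysisDataset(frame=frame, patients=patients)


# ---------------------------------------------------------------------------
# model parameter file
# ---------------------------------------------------------------------------

def model_to_yaml(model: PopulationModel, path=None) -> str:
    """Serialise a population model to YAML (units noted in comments)."""
    doc = {
        "typical_values": {
            "cl_inf_ref": model.cl_inf_ref, "cl_t_ref": model.cl_t_ref,
            "k_des_ref": model.k_des_ref, "v1_ref": model.v1_ref,
            "q_ref": model.q_ref, "v2_ref": model.v2_ref,
            "frac_ns_ref": model.frac_ns_ref, "cl_m_ref": model.cl_m_ref,
            "v_m_ref": model.v_m_ref, "dose_conv": model.dose_conv,
        },
        "covariate_effects": [
            {"parameter": e.parameter, "covariate": e.covariate, "kind": e.kind,
             "coefficient": e.coefficient, "reference": e.reference}
            for e in model.covariate_effects
        ],
        "omega": [[float(v) for v in row] for row in model.omega],
        "sigma": {k: float(v) for k, v in model.sigma.items()},
    }
    header = (
        "# Two-analyte population PK model parameters.\n"
        "# Units: clearances L/day, volumes L, k_des 1/day, dose_conv ug/mg,\n"
        "# frac_ns dimensionless; omega/sigma are log-scale (co)variances.\n"
        f"# Random-effect order: {', '.join(ETA_NAMES)}.\n"
    )
    text = header + yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_yaml(path_or_text) -> PopulationModel:
    """Load a population model from YAML produced by :func:`model_to_yaml`."""
    text = Path(path_or_text).read_text() if Path(str(path_or_text)).exists() \
        else str(path_or_text)
    doc = yaml.safe_load(text)
    known = {"typical_values", "covariate_effects", "omega", "sigma"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown model-file section(s) {sorted(unknown)}")
    effects = tuple(CovariateEffect(**e) for e in doc.get("covariate_effects", []))
    return PopulationModel(**doc["typical_values"], covariate_effects=effects,
                           omega=np.asarray(doc["omega"], dtype=float),
                           sigma=dict(doc["sigma"]))


def write_etas(etas: pd.DataFrame, path) -> None:
    """Write a per-subject eta CSV keyed by subject id."""
    etas.to_csv(path, index=True)


def read_etas(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

#: derived factor columns available for subgroup comparison, with their
#: default reference levels
FACTOR_REFERENCES = {
    "bw_ge_100": "no",
    "age_band": "20-64",
    "sex": "female",
    "hepatic_category": "normal",
    "renal_category": "normal",
    "combo_rg": False,
    "combo_benda": False,
    "material": "v0.1",
}


def add_factor_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Add the derived subgroup factor columns to an exposure table."""
    table = table.copy()
    table["bw_ge_100"] = np.where(table["bodyweight"] >= 100, "yes", "no")
    table["age_band"] = pd.cut(
        table["age"], bins=[0, 65, 75, 85, 200], right=False,
        labels=["20-64", "65-74", "75-84", "85+"]).astype(str)
    return table


_SCHEMA = {
    "seed": int, "n": int, "schedule": str, "etas": str,
    "comparisons": list, "diagnostics": dict, "outdir": str,
    "model": (str, type(None)), "population": dict, "sensitivity": bool,
}
_DIAG_KEYS = {"enabled", "vpc_replicates", "npde_replicates", "n_bins"}


def _validate_config(config: dict) -> dict:
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ConfigurationError(f"unknown config key(s) {sorted(unknown)}")
    cfg = {"seed": 0, "n": 200, "schedule": "rich", "etas": "ebe",
           "comparisons": [{"factor": "bw_ge_100"}], "diagnostics": {},
           "outdir": "adcpk_run", "model": None, "population": {},
           "sensitivity": False}
    cfg.update(config)
    for key, typ in _SCHEMA.items():
        if not isinstance(cfg[key], typ):
            raise ConfigurationError(f"config key {key!r} has wrong type")
    if cfg["etas"] not in ("ebe", "true"):
        raise ConfigurationError("config 'etas' must be 'ebe' or 'true'")
    for comp in cfg["comparisons"]:
        unknown = set(comp) - {"factor", "reference", "mode"}
        if unknown:
            raise ConfigurationError(f"unknown comparison key(s) {sorted(unknown)}")
        if comp["factor"] not in FACTOR_REFERENCES:
            raise ConfigurationError(f"unknown comparison factor {comp['factor']!r}")
    unknown = set(cfg["diagnostics"]) - _DIAG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown diagnostics key(s) {sorted(unknown)}")
    return cfg


def run_pipeline(config: dict, outdir=None) -> Path:
    """Run generate -> estimate -> correct -> compare (-> diagnose).

    Writes tidy CSV artifacts plus a ``manifest.json`` carrying the seed, the
    configuration hash and the package version, so the run is reproducible
    from the manifest alone.  Any stage failure raises with the stage name.
    """
    cfg = _validate_config(dict(config))
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = {"package": "adcpk", "version": __version__, "seed": cfg["seed"],
                "config": cfg, "config_hash": cfg_hash, "outputs": [],
                "stages": {}}

    def _stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started": _time.time()}
        return name

    stage = _stage("generate")
    try:
        model = model_from_yaml(cfg["model"]) if cfg["model"] else default_model()
        pop_cfg = PopulationConfig(**cfg["population"])
        covs = sample_covariates(cfg["n"], pop_cfg, seed=cfg["seed"])
        patients = simulate_dataset(model, covs, schedule=cfg["schedule"],
                                    seed=cfg["seed"] + 1)
        write_dataset(patients, out / "dataset.csv")
        truth = pd.DataFrame([p.true_etas for p in patients],
                             index=pd.Index([p.subject for p in patients],
                                            name="subject"),
                             columns=list(ETA_NAMES))
        write_etas(truth, out / "etas_true.csv")
        manifest["outputs"] += ["dataset.csv", "etas_true.csv"]

        if cfg["etas"] == "ebe":
            stage = _stage("ebe")
            result = estimate_ebe(patients, model)
            write_etas(result.etas, out / "etas_ebe.csv")
            pd.Series(result.shrinkage, name="shrinkage_pct").to_csv(
                out / "shrinkage.csv")
            manifest["outputs"] += ["etas_ebe.csv", "shrinkage.csv"]

        stage = _stage("compare")
        for comp in cfg["comparisons"]:
            factor = comp["factor"]
            reference = comp.get("reference", FACTOR_REFERENCES[factor])
            mode = comp.get("mode", "cCC" if factor == "material" else "pCC")
            spec = (pcc_spec if mode == "pCC" else ccc_spec)(factor)
            table = add_factor_columns(
                corrected_exposures(patients, model, spec, etas=cfg["etas"]))
            table.to_csv(out / f"exposures_{factor}.csv", index=False)
            comparison = compare_subgroups(table, factor, reference)
            comparison.to_csv(out / f"comparison_{factor}.csv", index=False)
            manifest["outputs"] += [f"exposures_{factor}.csv",
                                    f"comparison_{factor}.csv"]

        if cfg["sensitivity"]:
            stage = _stage("sensitivity")
            sensitivity_table(model, pop_cfg, seed=cfg["seed"] + 2).to_csv(
                out / "sensitivity.csv", index=False)
            manifest["outputs"].append("sensitivity.csv")

        diag = dict(cfg["diagnostics"])
        if diag.get("enabled"):
            stage = _stage("diagnostics")
            reps = population_simulate(
                model, patients, diag.get("vpc_replicates", 500),
                seed=cfg["seed"] + 3)
            vpc = pc_vpc(reps, n_bins=diag.get("n_bins", 8))
            vpc.bins.to_csv(out / "vpc.csv", index=False)
            reps_npde = population_simulate(
                model, patients, diag.get("npde_replicates", 1000),
                seed=cfg["seed"] + 4)
            res = npde(reps_npde, seed=cfg["seed"] + 5)
            res.values.to_csv(out / "npde.csv", index=False)
            tests = pd.DataFrame(
                [{"test": k, "statistic": v[0], "p_value": v[1]}
                 for k, v in res.tests.items()])
            tests.insert(0, "variance", res.variance)
            tests.insert(0, "mean", res.mean)
            tests.to_csv(out / "npde_tests.csv", index=False)
            manifest["outputs"] += ["vpc.csv", "npde.csv", "npde_tests.csv"]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    for name in manifest["stages"]:
        manifest["stages"][name]["finished"] = _time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
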