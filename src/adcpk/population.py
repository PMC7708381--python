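"""Virtual NHL population generator.

Produces synthetic patients — baseline covariates, bodyweight-based dosing
regimens, and sampled concentrations with residual noise and below-LLOQ
censoring — with the marginal statistical structure of the clinical population
the model was built on (N = 460): bodyweight 38–146 kg sampled
sex-conditionally, ages 20–89 years, a ~59% male split, NCI hepatic-function
categories (~88% normal / ~12% mild), Cockcroft-Gault-derived renal-function
bands, and the combination-therapy and manufacturing-process flags.  True
random effects are stored alongside the noisy observations so that estimation
and correction stages can be tested against known ground truth.

The joint covariate correlations of the real population are not public; the
generator encodes only the documented, qualitatively important ones
(bodyweight depends on sex; albumin is shifted downward for hepatically
impaired patients; creatinine clearance is derived deterministically from age,
weight, sex and creatinine).  Everything is configurable via
:class:`PopulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    ANALYTES,
    ETA_NAMES,
    ConfigurationError,
    DoseEvent,
    InputError,
    PopulationModel,
    apply_covariates,
    simulate_profile,
)

__all__ = [
    "LLOQ",
    "CovariateRecord",
    "ObservationRecord",
    "PatientRecord",
    "PopulationConfig",
    "cockcroft_gault",
    "classify_hepatic_nci",
    "classify_renal",
    "apply_eligibility",
    "build_regimen",
    "sample_covariates",
    "simulate_dataset",
    "rich_schedule",
    "sparse_schedule",
]

#: default lower limits of quantitation, ng/mL
LLOQ = {"acmmae": 0.359, "mmae": 0.0359}

HEPATIC_CATEGORIES = ("normal", "mild", "moderate", "severe")
RENAL_CATEGORIES = ("normal", "mild", "moderate", "severe", "esrd")


@dataclass(frozen=True)
class CovariateRecord:
    """Baseline covariates of one virtual patient."""

    bodyweight: float  # kg
    age: float  # years
    sex: str  # "male" | "female"
    albumin: float  # g/L
    ast_xuln: float  # x upper limit of normal
    alt_xuln: float
    bili_xuln: float
    hepatic_category: str
    serum_creatinine: float  # mg/dL
    crcl: float  # mL/min
    renal_category: str
    b_cell_count: float  # cells/uL
    tumor_spd: float  # mm^2, sum of product of dimensions
    ecog: int  # 0 or >=1
    treatment_naive: bool
    combo_rg: bool
    combo_benda: bool
    material: str  # "v0.1" | "v1.0"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise InputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.hepatic_category not in HEPATIC_CATEGORIES:
            raise InputError(f"unknown hepatic category {self.hepatic_category!r}")
        if self.renal_category not in RENAL_CATEGORIES:
            raise InputError(f"unknown renal category {self.renal_category!r}")
        if self.material not in ("v0.1", "v1.0"):
            raise InputError(f"unknown material {self.material!r}")

    def value(self, name: str) -> float:
        """Numeric covariate lookup, including the derived model flags."""
        if name == "male":
            return 1.0 if self.sex == "male" else 0.0
        if name == "hepatic_impaired":
            return 1.0 if self.hepatic_category in ("mild", "moderate", "severe") else 0.0
        if name == "ecog_ge1":
            return 1.0 if self.ecog >= 1 else 0.0
        if name == "material_v1":
            return 1.0 if self.material == "v1.0" else 0.0
        try:
            raw = getattr(self, name)
        except AttributeError as exc:
            raise InputError(f"unknown covariate {name!r}") from exc
        if isinstance(raw, str):
            raise InputError(f"covariate {name!r} is categorical; use a derived flag")
        return float(raw)

    def with_updates(self, **kwargs) -> "CovariateRecord":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ObservationRecord:
    """One sampled concentration of one analyte."""

    subject: int
    analyte: str  # see model.ANALYTES
    time: float  # days since first dose
    concentration: float | None  # ng/mL; None when censored
    censored: bool
    lloq: float

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise InputError(f"unknown analyte {self.analyte!r}")
        if self.censored and self.concentration is not None:
            raise InputError("censored records carry no concentration")


@dataclass
class PatientRecord:
    """Covariates plus dosing history, observations and (optionally) etas."""

    subject: int
    covariates: CovariateRecord
    doses: tuple[DoseEvent, ...] = ()
    observations: tuple[ObservationRecord, ...] = ()
    true_etas: np.ndarray | None = None
    ebe_etas: np.ndarray | None = None


# ---------------------------------------------------------------------------
# clinical classifiers
# ---------------------------------------------------------------------------

def cockcroft_gault(age: float, bodyweight: float, serum_creatinine: float,
                    sex: str) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault formula.

    ``(140 - age) * weight / (72 * SCr)``, multiplied by 0.85 for females.
    """
    if age <= 0 or bodyweight <= 0 or serum_creatinine <= 0:
        raise InputError("age, bodyweight and serum creatinine must be positive")
    if age >= 140:
        raise InputError("age must be below 140 years for Cockcroft-Gault")
    if sex not in ("male", "female"):
        raise InputError(f"sex must be 'male' or 'female', got {sex!r}")
    crcl = (140.0 - age) * bodyweight / (72.0 * serum_creatinine)
    if sex == "female":
        crcl *= 0.85
    return crcl


def classify_hepatic_nci(ast_xuln: float, bili_xuln: float) -> str:
    """NCI organ-dysfunction hepatic category from AST and total bilirubin.

    Normal: AST <= ULN and bilirubin <= ULN.  Mild: bilirubin in (1, 1.5] x ULN
    (group B1) or AST > ULN with normal bilirubin (group B2).  Moderate:
    bilirubin in (1.5, 3].  Severe: bilirubin > 3 x ULN.
    """
    if ast_xuln < 0 or bili_xuln < 0:
        raise InputError("lab values must be non-negative")
    if bili_xuln > 3.0:
        return "severe"
    if bili_xuln > 1.5:
        return "moderate"
    if bili_xuln > 1.0:
        return "mild"
    return "mild" if ast_xuln > 1.0 else "normal"


def classify_renal(crcl: float) -> str:
    """Renal-function band from creatinine clearance (mL/min)."""
    if crcl < 0:
        raise InputError("creatinine clearance must be non-negative")
    if crcl >= 90:
        return "normal"
    if crcl >= 60:
        return "mild"
    if crcl >= 30:
        return "moderate"
    if crcl >= 15:
        return "severe"
    return "esrd"


def apply_eligibility(cov: CovariateRecord) -> tuple[bool, str]:
    """Trial-eligibility screen on baseline labs and renal function.

    Excluded if AST or ALT exceeds 2.5 x ULN, total bilirubin is >= 1.5 x ULN,
    or creatinine clearance is below 40 mL/min.  Returns ``(included, reason)``
    where the reason names the first failed rule (or is empty).
    """
    for name in ("ast_xuln", "alt_xuln", "bili_xuln", "crcl"):
        value = getattr(cov, name)
        if value is None or not np.isfinite(value):
            raise InputError(f"missing laboratory value {name!r}")
    if cov.ast_xuln > 2.5 or cov.alt_xuln > 2.5:
        return False, "hepatic: AST or ALT > 2.5 x ULN"
    if cov.bili_xuln >= 1.5:
        return False, "hepatic: total bilirubin >= 1.5 x ULN"
    if cov.crcl < 40:
        return False, "renal: CrCL < 40 mL/min"
    return True, ""


def build_regimen(bodyweight: float, dose_mg_per_kg: float = 1.8,
                  n_cycles: int = 6, interval: float = 21.0,
                  infusion_minutes: float = 90.0) -> tuple[DoseEvent, ...]:
    """Bodyweight-based Q3W regimen: the label 1.8 mg/kg x 6 cycles default."""
    if bodyweight <= 0 or dose_mg_per_kg <= 0 or n_cycles <= 0:
        raise InputError("regimen arguments must be positive")
    if interval <= 0 or infusion_minutes <= 0:
        raise InputError("regimen arguments must be positive")
    amount = dose_mg_per_kg * bodyweight
    duration = infusion_minutes / 1440.0
    return tuple(
        DoseEvent(time=interval * i, amount=amount, duration=duration)
        for i in range(n_cycles)
    )


# ---------------------------------------------------------------------------
# covariate sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    """Distribution settings of the covariate generator.

    Defaults target the marginal proportions and ranges of the model-building
    population; the continuous distributions and their correlations are
    plausible placeholders (the study's joint distribution is not public).
    """

    p_male: float = 272 / 460
    bw_median_male: float = 80.0  # kg, lognormal median
    bw_median_female: float = 66.0
    bw_sdlog: float = 0.20
    bw_range: tuple[float, float] = (38.0, 146.0)
    age_mean: float = 64.0  # years, truncated normal
    age_sd: float = 12.0
    age_range: tuple[float, float] = (20.0, 89.0)
    p_hepatic_mild: float = 54 / 453
    p_hepatic_moderate: float = 2 / 453
    albumin_mean: float = 39.0  # g/L
    albumin_sd: float = 4.5
    albumin_hepatic_shift: float = -4.0  # g/L added for impaired categories
    albumin_range: tuple[float, float] = (20.0, 55.0)
    scr_median: float = 0.95  # mg/dL, lognormal median
    scr_sdlog: float = 0.22
    scr_range: tuple[float, float] = (0.4, 3.0)
    bcell_median: float = 100.0  # cells/uL
    bcell_sdlog: float = 1.0
    spd_median: float = 2000.0  # mm^2
    spd_sdlog: float = 1.0
    p_ecog_ge1: float = 0.55
    p_treatment_naive: float = 0.25
    p_combo_rg: float = 0.85
    p_combo_benda: float = 139 / 460
    material: str = "v0.1"
    gilberts_override: bool = False  # reclassify bilirubin-only moderate as normal

    def __post_init__(self) -> None:
        probs = dict(p_male=self.p_male, p_ecog_ge1=self.p_ecog_ge1,
                     p_treatment_naive=self.p_treatment_naive,
                     p_combo_rg=self.p_combo_rg, p_combo_benda=self.p_combo_benda)
        for name, p in probs.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.p_hepatic_mild < 0 or self.p_hepatic_moderate < 0:
            raise ConfigurationError("hepatic proportions must be non-negative")
        if self.p_hepatic_mild + self.p_hepatic_moderate > 1:
            raise ConfigurationError("hepatic category proportions sum to more than 1")


def _truncated(draw, lo, hi, rng):
    """Redraw until inside [lo, hi] (distributions are far from degenerate)."""
    for _ in range(1000):
        x = draw(rng)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _sample_hepatic_labs(category: str, rng: np.random.Generator) -> tuple[float, float, float]:
    """Draw (AST, ALT, bilirubin) in x-ULN consistent with the NCI category."""
    alt = float(rng.uniform(0.3, 2.0))
    if category == "normal":
        return float(rng.uniform(0.3, 1.0)), alt, float(rng.uniform(0.3, 1.0))
    if category == "mild":
        if rng.random() < 0.75:  # B1: elevated bilirubin
            return float(rng.uniform(0.3, 1.0)), alt, float(rng.uniform(1.0001, 1.4999))
        return float(rng.uniform(1.0001, 2.4)), alt, float(rng.uniform(0.3, 1.0))
    if category == "moderate":
        return float(rng.uniform(0.3, 1.0)), alt, float(rng.uniform(1.5001, 2.9999))
    return float(rng.uniform(0.3, 1.0)), alt, float(rng.uniform(3.0001, 6.0))


def sample_covariates(n: int, config: PopulationConfig | None = None,
                      seed: int | np.random.Generator = 0) -> list[CovariateRecord]:
    """Draw ``n`` virtual patients' baseline covariates.

    Reproducible for a given seed.  Bodyweight is sampled sex-conditionally
    (truncated lognormal); hepatic labs are drawn consistently with the
    sampled NCI category; creatinine clearance is computed from age, weight,
    creatinine and sex, so the stored band always matches the classifiers.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    cfg = config or PopulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out: list[CovariateRecord] = []
    for _ in range(n):
        sex = "male" if rng.random() < cfg.p_male else "female"
        bw_median = cfg.bw_median_male if sex == "male" else cfg.bw_median_female
        bw = _truncated(lambda r: bw_median * np.exp(r.normal(0, cfg.bw_sdlog)),
                        *cfg.bw_range, rng)
        age = _truncated(lambda r: r.normal(cfg.age_mean, cfg.age_sd),
                         *cfg.age_range, rng)

        u = rng.random()
        if u < cfg.p_hepatic_mild:
            hep = "mild"
        elif u < cfg.p_hepatic_mild + cfg.p_hepatic_moderate:
            hep = "moderate"
        else:
            hep = "normal"
        ast, alt, bili = _sample_hepatic_labs(hep, rng)
        if cfg.gilberts_override and hep == "moderate" and ast <= 1.0:
            # documented Gilbert's-syndrome reclassification: isolated bilirubin
            # elevation treated as normal hepatic function
            hep = "normal"

        alb_mean = cfg.albumin_mean + (cfg.albumin_hepatic_shift if hep != "normal" else 0.0)
        albumin = _truncated(lambda r: r.normal(alb_mean, cfg.albumin_sd),
                             *cfg.albumin_range, rng)
        scr = _truncated(lambda r: cfg.scr_median * np.exp(r.normal(0, cfg.scr_sdlog)),
                         *cfg.scr_range, rng)
        crcl = cockcroft_gault(age, bw, scr, sex)

        out.append(CovariateRecord(
            bodyweight=bw, age=age, sex=sex, albumin=albumin,
            ast_xuln=ast, alt_xuln=alt, bili_xuln=bili,
            hepatic_category=hep,
            serum_creatinine=scr, crcl=crcl, renal_category=classify_renal(crcl),
            b_cell_count=float(cfg.bcell_median * np.exp(rng.normal(0, cfg.bcell_sdlog))),
            tumor_spd=float(cfg.spd_median * np.exp(rng.normal(0, cfg.spd_sdlog))),
            ecog=1 if rng.random() < cfg.p_ecog_ge1 else 0,
            treatment_naive=bool(rng.random() < cfg.p_treatment_naive),
            combo_rg=bool(rng.random() < cfg.p_combo_rg),
            combo_benda=bool(rng.random() < cfg.p_combo_benda),
            material=cfg.material,
        ))
    return out


# ---------------------------------------------------------------------------
# sampling schedules and dataset simulation
# ---------------------------------------------------------------------------

def rich_schedule(n_cycles: int = 6, interval: float = 21.0) -> np.ndarray:
    """Intensive schedule: pre-dose + 8 post-dose samples in cycles 1 and 6,
    plus a trough at the end of every cycle."""
    post = np.array([90 / 1440, 0.125, 0.25, 1.0, 2.0, 4.0, 7.0, 14.0])
    times = []
    for c in (0, n_cycles - 1):
        start = c * interval
        times.append([start] if c > 0 else [0.0])
        times.append(start + post)
    troughs = [interval * (c + 1) - 0.02 for c in range(n_cycles)]
    times.append(troughs)
    return np.unique(np.concatenate([np.atleast_1d(t) for t in times]))


def sparse_schedule(n_cycles: int = 6, interval: float = 21.0) -> np.ndarray:
    """Less-intensive schedule: one post-infusion sample and one trough per
    cycle."""
    times = []
    for c in range(n_cycles):
        start = c * interval
        times.extend([start + 0.125, start + interval - 0.02])
    return np.unique(np.array(times))


def simulate_dataset(model: PopulationModel, patients: list[PatientRecord] | list[CovariateRecord],
                     schedule: str | np.ndarray = "rich",
                     seed: int | np.random.Generator = 0,
                     lloq: dict[str, float] | None = None) -> list[PatientRecord]:
    """Simulate noisy, BLQ-censored two-analyte observations for a cohort.

    Per patient the generator draws etas from MVN(0, omega), simulates the
    noise-free profile on the schedule, multiplies by lognormal proportional
    residual error per analyte, and censors values below the analyte LLOQ.
    True etas are stored on the returned records.  Patients passed as bare
    covariate records get the standard 1.8 mg/kg Q3W x 6 regimen.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lloq = dict(LLOQ if lloq is None else lloq)
    omega = model.omega
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ConfigurationError("omega is singular; cannot draw etas")
    if isinstance(schedule, str):
        if schedule not in ("rich", "sparse"):
            raise ConfigurationError(f"unknown schedule {schedule!r}")
        times = rich_schedule() if schedule == "rich" else sparse_schedule()
    else:
        times = np.asarray(schedule, dtype=float)

    chol = _omega_factor(omega)
    out: list[PatientRecord] = []
    for i, pat in enumerate(patients):
        if isinstance(pat, CovariateRecord):
            pat = PatientRecord(subject=i + 1, covariates=pat)
        if not pat.doses:
            pat.doses = build_regimen(pat.covariates.bodyweight)
        etas = chol @ rng.standard_normal(len(ETA_NAMES))
        params = apply_covariates(model, pat.covariates, etas)
        conc = simulate_profile(params, pat.doses, times, model.dose_conv)
        obs: list[ObservationRecord] = []
        for row, analyte in enumerate(ANALYTES):
            sd = float(np.sqrt(model.sigma[analyte]))
            noise = np.exp(sd * rng.standard_normal(times.size)) if sd > 0 else 1.0
            values = conc[row] * noise
            for t, y in zip(times, values):
                censored = bool(y < lloq[analyte])
                obs.append(ObservationRecord(
                    subject=pat.subject, analyte=analyte, time=float(t),
                    concentration=None if censored else float(y),
                    censored=censored, lloq=lloq[analyte]))
        pat.observations = tuple(sorted(obs, key=lambda o: (o.time, o.analyte)))
        pat.true_etas = etas
        out.append(pat)
    return out


def _omega_factor(omega: np.ndarray) -> np.ndarray:
    """Factor L with L L' = omega, tolerating PSD (zero-variance) matrices."""
    try:
        return np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(omega)
        if vals.min() < -1e-10:
            raise ConfigurationError("omega is not positive semi-definite")
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
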