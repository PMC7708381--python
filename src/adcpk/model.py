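"""Structural and covariate PK model for the two ADC analytes.

The conjugate (antibody-conjugated MMAE, "acMMAE") follows a two-compartment
disposition with zero-order intravenous infusion input and a time-dependent
linear clearance

    CL(t) = CL_inf + CL_t * exp(-k_des * t),

where ``t`` is time since the simulation origin (the first dose of a standard
regimen).  The released cytotoxic payload (unconjugated MMAE) is described by a
one-compartment model whose input is the fraction ``frac_ns`` of the conjugate
clearance flux, i.e. formation-rate-limited kinetics:

    dA_m/dt = frac_ns * CL(t) * C_ac(t) - (CL_m / V_m) * A_m.

Both analytes are quantified as MMAE-equivalent mass, so ``frac_ns`` is a
dimensionless formation fraction.  Internal units are micrograms, litres and
days; concentrations are returned in ng/mL via the ug/L == ng/mL equivalence.

Inter-individual variability is lognormal (``exp(eta)``) on CL_inf, V1, k_des,
frac_ns and CL_m.  Covariates act multiplicatively on the typical values,
either as power functions of a continuous covariate normalised to its
reference value or as proportional shifts for active categorical flags, so the
composition is order-independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "ConfigurationError",
    "InputError",
    "SolverError",
    "CovariateEffect",
    "PopulationModel",
    "IndividualParameters",
    "DoseEvent",
    "ETA_NAMES",
    "PARAM_NAMES",
    "ANALYTES",
    "apply_covariates",
    "simulate_profile",
    "profile_plan",
    "solve_plan",
    "default_model",
]


class ConfigurationError(ValueError):
    """Invalid analysis or model configuration."""


class InputError(ValueError):
    """Invalid data input."""


class SolverError(RuntimeError):
    """The concentration solver produced an unusable solution."""


#: random-effect dimensions, in OMEGA order
ETA_NAMES = ("cl_inf", "v1", "k_des", "frac_ns", "cl_m")

#: all structural parameters of an individual
PARAM_NAMES = ("cl_inf", "cl_t", "k_des", "v1", "q", "v2", "frac_ns", "cl_m", "v_m")

#: analyte labels; order matches the rows returned by :func:`simulate_profile`
ANALYTES = ("acmmae", "mmae")


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on a structural parameter.

    ``kind == "power"``: multiplier ``(value / reference) ** coefficient`` for a
    positive continuous covariate.  ``kind == "proportional"``: multiplier
    ``1 + coefficient`` whenever the (binary) covariate is active, 1 otherwise.
    """

    parameter: str
    covariate: str
    kind: str
    coefficient: float
    reference: float = 1.0

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ConfigurationError(f"unknown parameter {self.parameter!r}")
        if self.kind not in ("power", "proportional"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "power" and self.reference <= 0:
            raise ConfigurationError("power effect needs a positive reference value")

    def multiplier(self, value: float) -> float:
        if self.kind == "power":
            if value <= 0:
                raise InputError(
                    f"non-positive value {value!r} for covariate "
                    f"{self.covariate!r} with a power effect"
                )
            return (value / self.reference) ** self.coefficient
        return 1.0 + self.coefficient if value else 1.0


@dataclass(frozen=True)
class PopulationModel:
    """Population (typical) parameters, covariate table and variance terms.

    Typical values carry the units noted below; ``omega`` is the 5x5
    covariance of the lognormal random effects in :data:`ETA_NAMES` order and
    ``sigma`` maps analyte name to the residual variance of the log-scale
    proportional error.
    """

    cl_inf_ref: float  # L/day, non-specific time-stationary conjugate clearance
    cl_t_ref: float  # L/day, initial magnitude of the time-dependent clearance
    k_des_ref: float  # 1/day, decay rate of the time-dependent clearance
    v1_ref: float  # L, conjugate central volume
    q_ref: float  # L/day, intercompartmental clearance
    v2_ref: float  # L, conjugate peripheral volume
    frac_ns_ref: float  # -, fraction of conjugate clearance forming systemic MMAE
    cl_m_ref: float  # L/day, apparent unconjugated-MMAE clearance
    v_m_ref: float  # L, apparent unconjugated-MMAE volume
    dose_conv: float  # ug MMAE-equivalent reaching the central compartment per mg dosed
    covariate_effects: tuple[CovariateEffect, ...] = ()
    omega: np.ndarray = field(default_factory=lambda: np.zeros((5, 5)))
    sigma: dict[str, float] = field(default_factory=lambda: {a: 0.0 for a in ANALYTES})

    def __post_init__(self) -> None:
        for name in ("cl_inf_ref", "k_des_ref", "v1_ref", "q_ref", "v2_ref",
                     "cl_m_ref", "v_m_ref", "dose_conv"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.cl_t_ref < 0:
            raise ConfigurationError("cl_t_ref must be non-negative")
        if not 0 < self.frac_ns_ref <= 1:
            raise ConfigurationError("frac_ns_ref must lie in (0, 1]")
        omega = np.asarray(self.omega, dtype=float)
        if omega.shape != (len(ETA_NAMES),) * 2:
            raise ConfigurationError(f"omega must be {len(ETA_NAMES)}x{len(ETA_NAMES)}")
        if not np.allclose(omega, omega.T):
            raise ConfigurationError("omega must be symmetric")
        if np.linalg.eigvalsh(omega).min() < -1e-10:
            raise ConfigurationError("omega must be positive semi-definite")
        object.__setattr__(self, "omega", omega)
        if set(self.sigma) != set(ANALYTES):
            raise ConfigurationError(f"sigma must have keys {ANALYTES}")
        if any(v < 0 for v in self.sigma.values()):
            raise ConfigurationError("sigma entries must be non-negative")
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    @property
    def covariate_names(self) -> tuple[str, ...]:
        """Names of all covariates entering the model, in table order."""
        seen: list[str] = []
        for eff in self.covariate_effects:
            if eff.covariate not in seen:
                seen.append(eff.covariate)
        return tuple(seen)

    def reference_parameters(self) -> "IndividualParameters":
        """Parameters of the typical patient (reference covariates, etas = 0)."""
        return IndividualParameters(
            cl_inf=self.cl_inf_ref, cl_t=self.cl_t_ref, k_des=self.k_des_ref,
            v1=self.v1_ref, q=self.q_ref, v2=self.v2_ref,
            frac_ns=self.frac_ns_ref, cl_m=self.cl_m_ref, v_m=self.v_m_ref,
        )

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualParameters:
    """Structural parameters of one individual after covariates and etas."""

    cl_inf: float
    cl_t: float
    k_des: float
    v1: float
    q: float
    v2: float
    frac_ns: float
    cl_m: float
    v_m: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if name == "cl_t":
                if value < 0:
                    raise InputError("cl_t must be non-negative")
            elif value <= 0:
                raise InputError(f"{name} must be positive, got {value!r}")
        if self.frac_ns > 1:
            raise InputError("frac_ns must not exceed 1")


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order intravenous infusion."""

    time: float  # days since first dose
    amount: float  # mg of drug administered
    duration: float  # days of infusion

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise InputError("dose amount must be non-negative")
        if self.duration <= 0:
            raise InputError("infusion duration must be positive")


def _check_doses(doses) -> tuple[DoseEvent, ...]:
    doses = tuple(doses)
    for prev, cur in zip(doses, doses[1:]):
        if cur.time < prev.time:
            raise InputError("dose events must be sorted by time")
        if cur.time < prev.time + prev.duration - 1e-12:
            raise InputError("overlapping infusions are not supported")
    return doses


def _covariate_value(covs, name: str) -> float:
    """Read covariate ``name`` from a record (``.value`` hook or attribute)."""
    getter = getattr(covs, "value", None)
    if callable(getter):
        return float(getter(name))
    try:
        return float(getattr(covs, name))
    except AttributeError as exc:
        raise InputError(f"covariate record has no covariate {name!r}") from exc


def apply_covariates(model: PopulationModel, covs, etas=None, frozen=None) -> IndividualParameters:
    """Derive individual parameters from typical values, covariates and etas.

    Each parameter equals its reference value times the product of its
    covariate multipliers times ``exp(eta)`` for the parameters that carry a
    random effect.  Covariates named in ``frozen`` contribute a multiplier of
    exactly 1 (i.e. are held at their reference value).

    Parameters
    ----------
    model : PopulationModel
    covs : object
        A covariate record; values are read via ``covs.value(name)`` (binary
        flags must map to 0/1).
    etas : array-like of length 5, optional
        Random effects in :data:`ETA_NAMES` order; defaults to zeros.
    frozen : iterable of str, optional
        Covariate names whose effects are suppressed.
    """
    if frozen is not None:
        frozen = set(frozen)
        unknown = frozen - set(model.covariate_names)
        if unknown:
            raise ConfigurationError(
                f"unknown covariate(s) in frozen set: {sorted(unknown)}"
            )
    if etas is None:
        etas = np.zeros(len(ETA_NAMES))
    etas = np.asarray(etas, dtype=float)
    if etas.shape != (len(ETA_NAMES),):
        raise InputError(f"etas must have length {len(ETA_NAMES)}")

    mult = {name: 1.0 for name in PARAM_NAMES}
    for eff in model.covariate_effects:
        if frozen and eff.covariate in frozen:
            continue
        mult[eff.parameter] *= eff.multiplier(_covariate_value(covs, eff.covariate))

    eta_map = dict(zip(ETA_NAMES, etas))
    values = {}
    for name in PARAM_NAMES:
        ref = getattr(model, f"{name}_ref")
        values[name] = ref * mult[name] * math.exp(eta_map.get(name, 0.0))
    if values["frac_ns"] > 1.0:
        warnings.warn(
            f"frac_ns = {values['frac_ns']:.4g} exceeds 1 after covariates and "
            "eta; clipping to 1",
            stacklevel=2,
        )
        values["frac_ns"] = 1.0
    return IndividualParameters(**values)


# ---------------------------------------------------------------------------
# concentration solver
# ---------------------------------------------------------------------------

_NEG_TOL = 1e-9  # relative tolerance for negative-solution detection


@njit(cache=True)
def _integrate(nodes, seg_rate, cl_inf, cl_t, k_des, v1, q, v2, frac_ns, k_m, h_max):
    """Fixed-step RK4 over the node grid; returns amounts (3, n_nodes)."""
    n = nodes.shape[0]
    out = np.zeros((3, n))
    a1 = 0.0
    a2 = 0.0
    a3 = 0.0
    for i in range(n - 1):
        rate = seg_rate[i]
        seg = nodes[i + 1] - nodes[i]
        if seg <= 0.0:
            out[0, i + 1] = a1
            out[1, i + 1] = a2
            out[2, i + 1] = a3
            continue
        nsub = int(seg / h_max) + 1
        h = seg / nsub
        t = nodes[i]
        for _ in range(nsub):
            # RK4 on the 3-state linear system with time-varying CL(t)
            k1a1, k1a2, k1a3 = _rhs(t, a1, a2, a3, rate, cl_inf, cl_t, k_des, v1, q, v2, frac_ns, k_m)
            k2a1, k2a2, k2a3 = _rhs(t + 0.5 * h, a1 + 0.5 * h * k1a1, a2 + 0.5 * h * k1a2, a3 + 0.5 * h * k1a3, rate, cl_inf, cl_t, k_des, v1, q, v2, frac_ns, k_m)
            k3a1, k3a2, k3a3 = _rhs(t + 0.5 * h, a1 + 0.5 * h * k2a1, a2 + 0.5 * h * k2a2, a3 + 0.5 * h * k2a3, rate, cl_inf, cl_t, k_des, v1, q, v2, frac_ns, k_m)
            k4a1, k4a2, k4a3 = _rhs(t + h, a1 + h * k3a1, a2 + h * k3a2, a3 + h * k3a3, rate, cl_inf, cl_t, k_des, v1, q, v2, frac_ns, k_m)
            a1 += h / 6.0 * (k1a1 + 2.0 * k2a1 + 2.0 * k3a1 + k4a1)
            a2 += h / 6.0 * (k1a2 + 2.0 * k2a2 + 2.0 * k3a2 + k4a2)
            a3 += h / 6.0 * (k1a3 + 2.0 * k2a3 + 2.0 * k3a3 + k4a3)
            t += h
        out[0, i + 1] = a1
        out[1, i + 1] = a2
        out[2, i + 1] = a3
    return out


@njit(cache=True, inline="always")
def _rhs(t, a1, a2, a3, rate, cl_inf, cl_t, k_des, v1, q, v2, frac_ns, k_m):
    tt = t if t > 0.0 else 0.0
    cl = cl_inf + cl_t * math.exp(-k_des * tt)
    c_ac = a1 / v1
    da1 = rate - (cl + q) * c_ac + (q / v2) * a2
    da2 = q * c_ac - (q / v2) * a2
    da3 = frac_ns * cl * c_ac - k_m * a3
    return da1, da2, da3


def profile_plan(doses, times, dose_conv: float):
    """Precompute the integration grid for repeated solves on one design.

    Returns ``(nodes, seg_rate, idx)``: the merged node grid, the infusion
    input rate (ug/day) on each segment, and the node index of every
    requested time.  Reusing a plan across eta draws or optimiser iterations
    removes the per-call grid-construction overhead.
    """
    doses = _check_doses(doses)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise InputError("need at least one observation time")
    if np.any(np.diff(times) < 0):
        raise InputError("observation times must be sorted")
    if times[0] < 0:
        raise InputError("observation times must be non-negative")

    starts = np.array([d.time for d in doses], dtype=float)
    ends = np.array([d.time + d.duration for d in doses], dtype=float)
    nodes = np.unique(np.concatenate([np.array([0.0]), starts, ends, times]))
    nodes = nodes[nodes >= min(0.0, times[0])]

    seg_rate = np.zeros(nodes.size - 1)
    mids = 0.5 * (nodes[:-1] + nodes[1:])
    for d in doses:
        active = (mids > d.time) & (mids < d.time + d.duration)
        seg_rate[active] += d.amount * dose_conv / d.duration
    idx = np.searchsorted(nodes, times)
    return nodes, seg_rate, idx


def solve_plan(plan, params: IndividualParameters, h_max: float = 0.02) -> np.ndarray:
    """Solve a precomputed plan; returns (2, n_times) concentrations, ng/mL."""
    nodes, seg_rate, idx = plan
    amounts = _integrate(
        nodes, seg_rate,
        params.cl_inf, params.cl_t, params.k_des, params.v1, params.q,
        params.v2, params.frac_ns, params.cl_m / params.v_m, h_max,
    )
    if not np.all(np.isfinite(amounts)):
        raise SolverError("non-finite solution; check parameter magnitudes and h_max")
    scale = max(amounts.max(), 1.0)
    if amounts.min() < -_NEG_TOL * scale:
        raise SolverError(
            f"negative solution beyond tolerance (min={amounts.min():.3e}, "
            f"scale={scale:.3e})"
        )
    amounts = np.where(np.abs(amounts) < _NEG_TOL * scale, 0.0, amounts)
    conc = np.empty((2, idx.size))
    conc[0] = amounts[0, idx] / params.v1
    conc[1] = amounts[2, idx] / params.v_m
    return conc


def simulate_profile(params: IndividualParameters, doses, times, dose_conv: float,
                     h_max: float = 0.02) -> np.ndarray:
    """Simulate noise-free concentrations of both analytes.

    Parameters
    ----------
    params : IndividualParameters
    doses : sequence of DoseEvent
    times : array-like of float
        Observation times in days (non-negative, sorted).
    dose_conv : float
        ug of MMAE-equivalent conjugate reaching the central compartment per mg
        of administered drug.
    h_max : float
        Maximum RK4 step (days).

    Returns
    -------
    ndarray of shape (2, len(times))
        Concentrations in ng/mL; row 0 is the conjugate, row 1 unconjugated
        MMAE (order of :data:`ANALYTES`).  Exactly zero before the first dose.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        _check_doses(doses)
        return np.zeros((2, 0))
    return solve_plan(profile_plan(doses, times, dose_conv), params, h_max)


# ---------------------------------------------------------------------------
# shipped default model
# ---------------------------------------------------------------------------

def default_covariate_effects() -> tuple[CovariateEffect, ...]:
    """Default covariate table.

    Only the bodyweight power on conjugate clearance (0.73) and the +19%
    hepatic-impairment shift on the MMAE formation fraction are literature
    values; every other coefficient is a calibrated placeholder chosen to
    reproduce the qualitative covariate pattern (directions and approximate
    sensitivity magnitudes) of the drug.  Reference values: 75 kg bodyweight,
    39 g/L albumin, female sex, single-agent dosing, relapsed/refractory
    disease, ECOG 0, tumour SPD 2000 mm^2.
    """
    return (
        CovariateEffect("cl_inf", "bodyweight", "power", 0.73, 75.0),
        CovariateEffect("cl_inf", "albumin", "power", -0.30, 39.0),
        CovariateEffect("cl_inf", "male", "proportional", 0.10),
        CovariateEffect("cl_inf", "combo_rg", "proportional", -0.155),
        CovariateEffect("cl_inf", "treatment_naive", "proportional", 0.10),
        CovariateEffect("cl_inf", "tumor_spd", "power", 0.06, 2000.0),
        CovariateEffect("v1", "bodyweight", "power", 0.55, 75.0),
        CovariateEffect("v1", "male", "proportional", 0.08),
        CovariateEffect("k_des", "combo_rg", "proportional", 0.30),
        CovariateEffect("frac_ns", "hepatic_impaired", "proportional", 0.19),
        CovariateEffect("frac_ns", "albumin", "power", -0.75, 39.0),
        CovariateEffect("frac_ns", "male", "proportional", -0.08),
        CovariateEffect("frac_ns", "combo_rg", "proportional", -0.38),
        CovariateEffect("frac_ns", "treatment_naive", "proportional", -0.10),
        CovariateEffect("frac_ns", "ecog_ge1", "proportional", 0.08),
        CovariateEffect("cl_m", "bodyweight", "power", 0.75, 75.0),
    )


def default_model() -> PopulationModel:
    """Shipped default population model.

    Typical values are calibrated stand-ins (not estimates): they were chosen
    once so that a 75-kg reference patient dosed 1.8 mg/kg every 3 weeks for
    six cycles lands near the published geometric-mean Cycle-6 exposure
    magnitudes (conjugate AUC ~2.9e3 ng*day/mL and Cmax ~7.3e2 ng/mL;
    unconjugated MMAE AUC ~21 ng*day/mL and Cmax ~2 ng/mL).
    """
    omega = np.diag(np.array([0.20, 0.15, 0.30, 0.35, 0.30]) ** 2)
    return PopulationModel(
        cl_inf_ref=0.78,   # L/day
        cl_t_ref=0.30,     # L/day
        k_des_ref=0.12,    # 1/day
        v1_ref=3.2,        # L
        q_ref=0.55,        # L/day
        v2_ref=3.0,        # L
        frac_ns_ref=0.14,  # -
        cl_m_ref=15.0,     # L/day
        v_m_ref=45.0,      # L
        dose_conv=16.75,   # ug/mg (drug-to-antibody ratio x payload/antibody mass ratio)
        covariate_effects=default_covariate_effects(),
        omega=omega,
        sigma={"acmmae": 0.20 ** 2, "mmae": 0.25 ** 2},
    )
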