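"""Synthetic virtual-patient cohorts.

The clinically fitted subjects behind the original model are not published,
so cohorts here are sampled around a physiologically plausible template
(rates and sensitivities in the range reported for adults with type 1
diabetes in the compartmental-modelling literature).  Inter-subject
variability is log-normal for strictly positive parameters and truncated
normal for the two unit-interval fractions; intra-day variability enters
through the piecewise-linear diurnal fluxes, whose multipliers can be
redrawn each simulated day.

Each sampled patient also gets a self-consistent insulin therapy: the basal
rate is the infusion that holds the patient's fasting glucose at the target
(found from the model's own steady-state balance), and the insulin-to-carb
ratio follows the 500 rule from the implied total daily dose.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import (
    DiurnalFlux,
    Demographics,
    ModelError,
    PatientParameters,
    DAY_MIN,
    F01_SAT,
    egp,
)

# ---------------------------------------------------------------------------
# Template: (low, high) plausible ranges; the sampling median is the midpoint.
# Rates 1/min, sensitivities in their 1e-4 scale, volumes ml/kg.
# ---------------------------------------------------------------------------

DEFAULT_TEMPLATE: dict[str, tuple[float, float]] = {
    "w":     (55.0, 90.0),       # kg
    "pi":    (0.35, 0.65),       # slow-channel fraction
    "kis1":  (0.012, 0.028),
    "kis2":  (0.010, 0.022),
    "kif":   (0.020, 0.040),
    "ke":    (0.10, 0.18),
    "ci":    (0.0, 0.0),         # no residual endogenous insulin in T1D
    "ka1":   (0.004, 0.010),
    "ka2":   (0.04, 0.09),
    "ka3":   (0.02, 0.05),
    "tgmax": (15.0, 30.0),       # min
    "MCRg":  (7.0, 13.0),        # ml/kg/min
    "Cb":    (10.0, 20.0),       # mU/L
    "km":    (0.018, 0.032),
    "d":     (30.0, 60.0),       # min
    "pm":    (0.55, 0.85),
    "F01":   (8.0, 12.0),        # umol/kg/min
    "k12":   (0.05, 0.08),
    "St":    (35.0, 70.0),       # 1e-4 /min per mU/L
    "Sd":    (5.0, 12.0),
    "Se":    (350.0, 700.0),     # 1e-4 per mU/L
    "Sg":    (0.8, 1.4),         # umol/kg/min per mU/L
    "V":     (140.0, 180.0),     # ml/kg
    "ks":    (0.05, 0.09),
}

DEMOGRAPHIC_TEMPLATE: dict[str, tuple[float, float]] = {
    "age_yr": (30.0, 64.0),
    "bmi_kg_m2": (21.0, 29.0),
    "hba1c_pct": (6.8, 8.6),
    "diabetes_duration_yr": (12.0, 44.0),
}

_POSITIVE = [k for k in DEFAULT_TEMPLATE if k not in ("pi", "pm", "ci")]
_FRACTIONS = ("pi", "pm")

#: glucose held at this level when solving for the fasting basal rate, mmol/L
FASTING_TARGET = 6.5


class CohortError(ValueError):
    """Invalid cohort specification or sampling failure."""


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to (re)generate a cohort deterministically."""

    n_patients: int = 15
    seed: int = 0
    #: inter-subject coefficient of variation applied to every positive
    #: parameter (may be overridden per parameter via ``cv_overrides``)
    cv: float = 0.15
    cv_overrides: dict[str, float] = field(default_factory=dict)
    #: template (low, high) ranges; defaults to DEFAULT_TEMPLATE
    template: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATE))
    demographic_template: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEMOGRAPHIC_TEMPLATE))
    #: knots per 24 h for each diurnal flux
    flux_knots: int = 8
    #: sigma of the log-normal multipliers of Im and fm (median 1)
    flux_dispersion: float = 0.10
    #: sigma of the additive glucose flux Fg, umol/kg/min (median 0)
    fg_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise CohortError("n_patients must be >= 1")
        if self.cv < 0 or self.flux_dispersion < 0 or self.fg_amplitude < 0:
            raise CohortError("dispersions must be >= 0")
        if self.flux_knots < 2:
            raise CohortError("flux_knots must be >= 2")
        for k, (lo, hi) in self.template.items():
            if lo > hi:
                raise CohortError(f"template range for {k} has low > high")

    def cv_for(self, name: str) -> float:
        return self.cv_overrides.get(name, self.cv)


@dataclass(frozen=True)
class Cohort:
    """An ordered, reproducible list of virtual patients."""

    patients: tuple[PatientParameters, ...]
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientParameters]:
        return iter(self.patients)

    def __getitem__(self, i: int) -> PatientParameters:
        return self.patients[i]


# ---------------------------------------------------------------------------
# Flux construction
# ---------------------------------------------------------------------------

def build_flux(knot_times: Sequence[float],
               multipliers: Sequence[float]) -> DiurnalFlux:
    """Piecewise-linear, 1440-min-periodic flux through the given knots."""
    return DiurnalFlux(times=tuple(float(t) for t in knot_times),
                       values=tuple(float(v) for v in multipliers))


def sample_flux(rng: np.random.Generator, n_knots: int, sigma: float,
                median: float = 1.0, additive: bool = False) -> DiurnalFlux:
    """Random diurnal flux on an equally spaced knot grid.

    Multiplicative fluxes are sampled on the log scale (median ``median``,
    log-sd ``sigma``) so they stay strictly positive; the additive glucose
    flux is sampled as half-normal deviations of scale ``sigma`` above zero.
    """
    times = np.arange(n_knots) * (DAY_MIN / n_knots)
    if additive:
        values = np.abs(rng.normal(0.0, sigma, n_knots)) if sigma > 0 \
            else np.zeros(n_knots)
    else:
        values = median * np.exp(rng.normal(0.0, sigma, n_knots))
    return build_flux(times, values)


def resample_fluxes(patient: PatientParameters,
                    rng: np.random.Generator,
                    flux_knots: int = 8,
                    fg_amplitude: float = 0.0) -> PatientParameters:
    """Fresh diurnal fluxes for a new simulated day, drawn from the
    patient's own dispersion (day-to-day intra-patient variability)."""
    sigma = patient.flux_dispersion
    if sigma == 0 and fg_amplitude == 0:
        return patient
    return patient.with_fluxes(
        Im=sample_flux(rng, flux_knots, sigma),
        fm=sample_flux(rng, flux_knots, sigma),
        Fg=sample_flux(rng, flux_knots, fg_amplitude, additive=True),
    )


# ---------------------------------------------------------------------------
# Therapy derivation
# ---------------------------------------------------------------------------

def _fasting_net_flux(ip: float, G: float, p: PatientParameters) -> float:
    """Net dQ1/dt at plasma glucose G with all insulin states at the plasma
    concentration ``ip`` and Q2 at its conditional steady state."""
    Q1 = G * p.V
    st = p.St * 1e-4
    sd = p.Sd * 1e-4
    f01 = p.F01 * (Q1 / F01_SAT) / (1.0 + Q1 / F01_SAT)
    q2 = ip * st * Q1 / (p.k12 + ip * sd)
    return (-f01 - ip * st * Q1 + p.k12 * q2
            + egp(p.Cb, ip, p))


def fasting_basal_rate(p: PatientParameters,
                       target: float = FASTING_TARGET) -> float:
    """Basal infusion (U/min) that balances the fasting glucose equation at
    ``target`` mmol/L, via the steady-state insulin chain.  Zero if the
    patient's glucose falls below target even without insulin."""
    if _fasting_net_flux(0.0, target, p) <= 0.0:
        return 0.0
    ip = brentq(_fasting_net_flux, 0.0, 1e4, args=(target, p), xtol=1e-10)
    qi = ip * p.Vi * p.w / 1e6
    return max(0.0, qi * p.ke - p.ci)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_MAX_REDRAWS = 100


def _sample_positive(rng: np.random.Generator, median: float,
                     cv: float) -> float:
    if median == 0.0 or cv == 0.0:
        return median
    return float(median * np.exp(rng.normal(0.0, cv)))


def _sample_fraction(rng: np.random.Generator, mid: float, cv: float,
                     name: str) -> float:
    if cv == 0.0:
        return mid
    for _ in range(_MAX_REDRAWS):
        v = float(rng.normal(mid, cv * max(mid, 1e-12)))
        if 0.0 <= v <= 1.0:
            return v
    raise CohortError(f"could not sample {name} within [0,1] "
                      f"after {_MAX_REDRAWS} redraws")


def sample_patient(spec: CohortSpec, index: int,
                   rng: np.random.Generator) -> PatientParameters:
    """One virtual subject; parameters validated, therapy derived."""
    raw: dict[str, float] = {}
    for name, (lo, hi) in spec.template.items():
        mid = 0.5 * (lo + hi)
        if name in _FRACTIONS:
            raw[name] = _sample_fraction(rng, mid, spec.cv_for(name), name)
        else:
            raw[name] = _sample_positive(rng, mid, spec.cv_for(name))
    demo = {}
    for name, (lo, hi) in spec.demographic_template.items():
        demo[name] = float(rng.uniform(lo, hi))

    fluxes = {
        "Im": sample_flux(rng, spec.flux_knots, spec.flux_dispersion),
        "fm": sample_flux(rng, spec.flux_knots, spec.flux_dispersion),
        "Fg": sample_flux(rng, spec.flux_knots, spec.fg_amplitude,
                          additive=True),
    }
    try:
        patient = PatientParameters(
            patient_id=f"vp{index:03d}",
            flux_dispersion=spec.flux_dispersion,
            demographics=Demographics(
                age_yr=demo["age_yr"],
                bmi_kg_m2=demo["bmi_kg_m2"],
                hba1c_pct=demo["hba1c_pct"],
                diabetes_duration_yr=demo["diabetes_duration_yr"],
                total_daily_dose_U_per_kg=0.0,   # filled below
            ),
            **raw, **fluxes,
        )
    except ModelError as exc:
        raise CohortError(f"sampled patient {index} invalid: {exc}") from exc

    basal = fasting_basal_rate(patient)
    # basal is taken as half the total daily dose (the usual basal/bolus
    # split), and the insulin-to-carb ratio follows the 500 rule
    tdd = 2.0 * basal * DAY_MIN
    icr = 500.0 / tdd if tdd > 0 else 15.0
    from dataclasses import replace
    patient = replace(
        patient, basal_rate=basal, icr=float(np.clip(icr, 2.0, 30.0)),
        demographics=replace(patient.demographics,
                             total_daily_dose_U_per_kg=tdd / patient.w))
    return patient


def sample_cohort(spec: CohortSpec) -> Cohort:
    """Deterministic cohort generation: the same spec (including its seed)
    always reproduces the same cohort bit-for-bit."""
    rng = np.random.default_rng(spec.seed)
    patients = tuple(sample_patient(spec, i, rng)
                     for i in range(spec.n_patients))
    return Cohort(patients=patients, spec=spec)


# ---------------------------------------------------------------------------
# Baseline characteristics
# ---------------------------------------------------------------------------

def baseline_characteristics(cohort: Cohort | Sequence[PatientParameters]
                             ) -> pd.DataFrame:
    """Mean/SD and median/IQR of the five reported demographics."""
    patients = list(cohort)
    if not patients:
        raise CohortError("empty cohort")
    rows = {
        "age_yr": [p.demographics.age_yr for p in patients],
        "bmi_kg_m2": [p.demographics.bmi_kg_m2 for p in patients],
        "hba1c_pct": [p.demographics.hba1c_pct for p in patients],
        "diabetes_duration_yr":
            [p.demographics.diabetes_duration_yr for p in patients],
        "total_daily_dose_U_per_kg":
            [p.demographics.total_daily_dose_U_per_kg for p in patients],
    }
    out = []
    for name, vals in rows.items():
        v = np.asarray(vals, dtype=float)
        out.append({
            "characteristic": name,
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        })
    return pd.DataFrame(out).set_index("characteristic")


# ---------------------------------------------------------------------------
# Serialization (same JSON format consumed by the model layer)
# ---------------------------------------------------------------------------

def patient_to_dict(p: PatientParameters) -> dict:
    d = asdict(p)
    for fx in ("Im", "fm", "Fg"):
        d[fx] = {"times": list(p.__getattribute__(fx).times),
                 "values": list(p.__getattribute__(fx).values)}
    return d


def patient_from_dict(d: dict) -> PatientParameters:
    d = dict(d)
    for fx in ("Im", "fm", "Fg"):
        node = d[fx]
        d[fx] = DiurnalFlux(times=tuple(node["times"]),
                            values=tuple(node["values"]))
    d["demographics"] = Demographics(**d["demographics"])
    return PatientParameters(**d)


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    payload = {
        "spec": asdict(cohort.spec),
        "patients": [patient_to_dict(p) for p in cohort.patients],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_cohort(path: str | Path) -> Cohort:
    payload = json.loads(Path(path).read_text())
    spec_d = payload["spec"]
    spec_d["template"] = {k: tuple(v) for k, v in spec_d["template"].items()}
    spec_d["demographic_template"] = {
        k: tuple(v) for k, v in spec_d["demographic_template"].items()}
    spec = CohortSpec(**spec_d)
    patients = tuple(patient_from_dict(d) for d in payload["patients"])
    return Cohort(patients=patients, spec=spec)
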