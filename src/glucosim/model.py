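"""Glucoregulatory ODE model of a virtual type 1 diabetes patient.

Thirteen state variables organised in seven subsystems:

1. subcutaneous insulin absorption — two parallel channels, a slow
   two-compartment chain (``Qis1 -> Qis2``, rates ``kis1``/``kis2``) and a
   fast two-compartment chain (``Qif1 -> Qif2``, shared rate ``kif``);
2. plasma insulin kinetics — one compartment ``Qi`` fed by both channels,
   modulated by the diurnal multiplier ``Im(t)``, cleared at ``ke``, with a
   constant background appearance ``ci``;
3. insulin action — three first-order filters ``x1, x2, x3`` tracking plasma
   insulin concentration with time constants ``ka1..ka3`` (glucose
   distribution, disposal and EGP suppression respectively);
4. subcutaneous glucagon absorption — two compartments ``Qg1 -> Qg2`` with a
   single time constant ``tgmax`` (the time-to-peak of the impulse response);
5. gut glucose absorption — dual-channel gamma-shaped meal appearance with a
   delayed second channel, modulated by the diurnal multiplier ``fm(t)``;
6. plasma glucose — accessible/non-accessible compartments ``Q1, Q2`` with
   saturable non-insulin-dependent uptake, insulin-driven distribution and
   disposal, glucagon-driven endogenous glucose production and an additive
   diurnal flux ``Fg(t)``;
7. interstitial glucose ``Gs`` — first-order sensor lag behind plasma
   glucose.

Units: insulin masses in U, glucagon in units (1 mg = 1 unit), glucose
masses in umol/kg, concentrations in mmol/L (glucose) and mU/L (hormones),
time in minutes.  ``G = Q1 / V`` with ``V`` in ml/kg is already in mmol/L
because umol/ml = mmol/L.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger("glucosim")

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: insulin distribution volume, ml/kg (fixed by the model definition)
V_I = 190.0

#: umol of glucose per gram of carbohydrate
UMOL_PER_G_CHO = 5551.0

#: minutes in a day; period of every diurnal flux
DAY_MIN = 1440.0

#: half-saturation constant of non-insulin-dependent glucose uptake, umol/kg
F01_SAT = 160.0

#: 13 state variables, in integration order
STATE_NAMES = (
    "Qis1", "Qis2",          # slow-channel subcutaneous insulin, U
    "Qif1", "Qif2",          # fast-channel subcutaneous insulin, U
    "Qi",                    # plasma insulin mass, U
    "x1", "x2", "x3",        # remote insulin effects, mU/L scale
    "Qg1", "Qg2",            # subcutaneous glucagon, units
    "Q1", "Q2",              # glucose masses, umol/kg
    "Gs",                    # interstitial glucose, mmol/L
)
N_STATES = len(STATE_NAMES)


class ModelError(ValueError):
    """Contract violation in model inputs or state."""


# ---------------------------------------------------------------------------
# Diurnal fluxes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiurnalFlux:
    """Continuous piecewise-linear function of clock time, 1440-min periodic.

    ``times`` are knot positions in minutes within [0, 1440), strictly
    increasing; ``values`` are the knot values (unitless multipliers for
    Im/fm, umol/kg/min for the additive glucose flux Fg).  Evaluation wraps:
    the segment between the last knot and the first knot of the next day is
    interpolated linearly, so flux(t) == flux(t + 1440) for all t.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size < 2:
            raise ModelError("DiurnalFlux needs at least 2 knots")
        if t.size != v.size:
            raise ModelError("DiurnalFlux knot times and values differ in length")
        if np.any(t < 0) or np.any(t >= DAY_MIN):
            raise ModelError("DiurnalFlux knot times must lie in [0, 1440)")
        if np.any(np.diff(t) <= 0):
            raise ModelError("DiurnalFlux knot times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ModelError("DiurnalFlux values must be finite")

    def __call__(self, t):
        tm = np.asarray(t, dtype=float) % DAY_MIN
        t_ = np.asarray(self.times, dtype=float)
        v_ = np.asarray(self.values, dtype=float)
        # pad one wrapped knot on each side so interpolation is periodic
        xp = np.concatenate(([t_[-1] - DAY_MIN], t_, [t_[0] + DAY_MIN]))
        fp = np.concatenate(([v_[-1]], v_, [v_[0]]))
        out = np.interp(tm, xp, fp)
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def constant_flux(value: float = 1.0) -> DiurnalFlux:
    """A flat flux, used when no diurnal modulation is wanted."""
    return DiurnalFlux(times=(0.0, 720.0), values=(float(value), float(value)))


# ---------------------------------------------------------------------------
# Patient parameters and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Demographics:
    """Baseline characteristics reported in the trial summary table."""

    age_yr: float
    bmi_kg_m2: float
    hba1c_pct: float
    diabetes_duration_yr: float
    total_daily_dose_U_per_kg: float


@dataclass(frozen=True)
class PatientParameters:
    """Time-invariant constants plus diurnal fluxes for one virtual subject.

    Rate constants are 1/min; sensitivities ``St``/``Sd`` are stored in the
    customary 1e-4/min per mU/L scale and ``Se`` in 1e-4 per mU/L — the 1e-4
    factor is applied inside the equations, not here.
    """

    patient_id: str
    w: float                     # body weight, kg
    # subcutaneous insulin absorption
    pi: float                    # slow-channel fraction, unitless in [0,1]
    kis1: float
    kis2: float
    kif: float
    # plasma insulin
    ke: float
    ci: float                    # background insulin appearance, U/min
    # insulin action filters
    ka1: float
    ka2: float
    ka3: float
    # glucagon
    tgmax: float                 # min, time-to-peak of plasma glucagon
    MCRg: float                  # ml/kg/min metabolic clearance
    Cb: float                    # mU/L background plasma glucagon
    # meal absorption
    km: float
    d: float                     # min, second-channel delay
    pm: float                    # first-channel fraction, unitless in [0,1]
    # plasma glucose
    F01: float                   # umol/kg/min non-insulin-dependent uptake
    k12: float
    St: float                    # 1e-4 /min per mU/L
    Sd: float                    # 1e-4 /min per mU/L
    Se: float                    # 1e-4 per mU/L
    Sg: float                    # umol/kg/min per mU/L glucagon sensitivity
    V: float                     # ml/kg glucose distribution volume
    # sensor
    ks: float
    # diurnal fluxes
    Im: DiurnalFlux = field(default_factory=constant_flux)
    fm: DiurnalFlux = field(default_factory=constant_flux)
    Fg: DiurnalFlux = field(default_factory=lambda: constant_flux(0.0))
    # therapy settings used by the open-loop comparator
    basal_rate: float = 0.0      # U/min
    icr: float = 10.0            # g CHO per U insulin
    # day-to-day variability: sigma of log-scale flux multipliers redrawn per day
    flux_dispersion: float = 0.0
    demographics: Demographics = field(
        default_factory=lambda: Demographics(47.0, 25.0, 7.5, 28.0, 0.5)
    )
    Vi: float = V_I

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ModelError(f"pi={self.pi} outside [0,1]")
        if not (0.0 <= self.pm <= 1.0):
            raise ModelError(f"pm={self.pm} outside [0,1]")
        for name in ("kis1", "kis2", "kif", "ke", "ka1", "ka2", "ka3",
                     "km", "ks", "k12"):
            if getattr(self, name) <= 0:
                raise ModelError(f"rate constant {name} must be > 0")
        for name in ("w", "tgmax", "MCRg", "V"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be > 0")
        if self.d < 0:
            raise ModelError("meal delay d must be >= 0")
        if self.Vi != V_I:
            raise ModelError(f"Vi is fixed at {V_I} ml/kg")

    def with_fluxes(self, Im: DiurnalFlux, fm: DiurnalFlux,
                    Fg: DiurnalFlux) -> "PatientParameters":
        return replace(self, Im=Im, fm=fm, Fg=Fg)


@dataclass(frozen=True)
class ModelState:
    """The 13 ODE state variables.  See STATE_NAMES for order and units."""

    Qis1: float = 0.0
    Qis2: float = 0.0
    Qif1: float = 0.0
    Qif2: float = 0.0
    Qi: float = 0.0
    x1: float = 0.0
    x2: float = 0.0
    x3: float = 0.0
    Qg1: float = 0.0
    Qg2: float = 0.0
    Q1: float = 0.0
    Q2: float = 0.0
    Gs: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATES,):
            raise ModelError(f"state vector must have {N_STATES} components")
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self) -> None:
        for n in STATE_NAMES:
            v = getattr(self, n)
            if not np.isfinite(v):
                raise ModelError(f"state variable {n} is not finite: {v}")
            if v < 0:
                raise ModelError(f"state variable {n} is negative: {v}")


@dataclass(frozen=True)
class MealEvent:
    """One carbohydrate intake: what the gut receives vs what the patient
    announces to the controller (they differ under carb-counting error, and
    rescue carbohydrates are never announced)."""

    time_min: float
    cho_g: float                 # true carbohydrate, g
    announced_cho_g: float       # what the controller is told, g
    kind: str = "meal"           # "meal" | "snack" | "rescue"

    def __post_init__(self) -> None:
        if self.cho_g <= 0:
            raise ModelError("meal CHO must be > 0")
        if self.announced_cho_g < 0:
            raise ModelError("announced CHO must be >= 0")


@dataclass(frozen=True)
class ExogenousInputs:
    """Inputs held constant across one integration window, except the meal
    appearance which varies continuously in time."""

    ui: float = 0.0              # U/min insulin infusion rate
    ug: float = 0.0              # unit/min glucagon infusion rate
    meals: tuple[MealEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.ui < 0 or self.ug < 0:
            raise ModelError("infusion rates must be >= 0")


# ---------------------------------------------------------------------------
# Algebraic observables
# ---------------------------------------------------------------------------

def plasma_insulin(Qi: float, params: PatientParameters) -> float:
    """Plasma insulin concentration Ip (mU/L) from plasma insulin mass (U).

    Ip = Qi / (Vi * w) * 1e6 with Vi = 190 ml/kg.
    """
    if params.w <= 0:
        raise ModelError("patient weight must be > 0")
    return Qi / (params.Vi * params.w) * 1e6


def plasma_glucagon(Qg2: float, params: PatientParameters) -> float:
    """Plasma glucagon concentration Cp (mU/L) from the second subcutaneous
    compartment, plus the background concentration Cb."""
    if params.MCRg <= 0:
        raise ModelError("MCRg must be > 0")
    return Qg2 / (params.tgmax * params.w * params.MCRg) * 1e6 + params.Cb


def plasma_glucose(Q1: float, params: PatientParameters) -> float:
    """Plasma glucose G (mmol/L) = Q1 / V (umol/kg over ml/kg)."""
    return Q1 / params.V


def egp(Cp: float, x3: float, params: PatientParameters) -> float:
    """Endogenous glucose production, umol/kg/min.

    Proportional to plasma glucagon, linearly suppressed by the remote
    insulin effect x3; the suppression term (1 - x3*Se*1e-4) is clamped at
    zero so EGP can never go negative.
    """
    suppression = 1.0 - x3 * params.Se * 1e-4
    if suppression <= 0.0:
        return 0.0
    return Cp * params.Sg * suppression


def meal_appearance(t: float, meal: MealEvent, params: PatientParameters,
                    apply_fm: bool = True) -> float:
    """Gut glucose appearance Um (umol/kg/min) from one meal at time t.

    Dual-channel gamma kernel: Um1 = km^2 * tau * exp(-km*tau) * CHO*5551*pm/w
    with tau = t - ingestion time; the second channel is identical but delayed
    by d min and carries the (1-pm) fraction.  The diurnal multiplier fm is
    evaluated at clock time t.
    """
    tau = t - meal.time_min
    if tau < 0:
        return 0.0
    km = params.km
    scale = meal.cho_g * UMOL_PER_G_CHO / params.w
    um1 = km * km * tau * np.exp(-km * tau) * scale * params.pm
    tau2 = tau - params.d
    if tau2 > 0:
        um2 = km * km * tau2 * np.exp(-km * tau2) * scale * (1.0 - params.pm)
    else:
        um2 = 0.0
    fm = params.fm(t) if apply_fm else 1.0
    return (um1 + um2) * fm


def total_meal_appearance(t: float, meals: Sequence[MealEvent],
                          params: PatientParameters) -> float:
    """Sum of gut appearances over all active meals at time t."""
    um = 0.0
    fm = params.fm(t)
    for m in meals:
        um += meal_appearance(t, m, params, apply_fm=False)
    return um * fm


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def _rhs(t: float, y: np.ndarray, params: PatientParameters,
         inputs: ExogenousInputs) -> np.ndarray:
    """Raw right-hand side on a plain array.

    Evaluated at max(y, 0): adaptive solvers probe slightly negative trial
    states near zero, and evaluating the mass-action terms at the clamped
    state keeps every compartment's outflow vanishing at the origin without
    altering the dynamics in the physical (non-negative) region.
    """
    y = np.maximum(y, 0.0)
    (Qis1, Qis2, Qif1, Qif2, Qi, x1, x2, x3,
     Qg1, Qg2, Q1, Q2, Gs) = y
    p = params
    ui, ug = inputs.ui, inputs.ug

    dy = np.empty(N_STATES)
    # subcutaneous insulin, slow + fast channels
    dy[0] = ui * p.pi - Qis1 * p.kis1
    dy[1] = Qis1 * p.kis1 - Qis2 * p.kis2
    dy[2] = ui * (1.0 - p.pi) - Qif1 * p.kif
    dy[3] = Qif1 * p.kif - Qif2 * p.kif
    # plasma insulin; Im multiplies absorbed insulin only
    dy[4] = (Qis2 * p.kis2 + Qif2 * p.kif) * p.Im(t) - Qi * p.ke + p.ci
    # remote insulin effects
    Ip = plasma_insulin(Qi, p)
    dy[5] = p.ka1 * (Ip - x1)
    dy[6] = p.ka2 * (Ip - x2)
    dy[7] = p.ka3 * (Ip - x3)
    # subcutaneous glucagon
    dy[8] = ug - Qg1 / p.tgmax
    dy[9] = (Qg1 - Qg2) / p.tgmax
    # plasma glucose
    Cp = plasma_glucagon(Qg2, p)
    st = p.St * 1e-4
    sd = p.Sd * 1e-4
    Um = total_meal_appearance(t, inputs.meals, p)
    f01 = p.F01 * (Q1 / F01_SAT) / (1.0 + Q1 / F01_SAT)
    dy[10] = (-f01 - x1 * st * Q1 + p.k12 * Q2
              + egp(Cp, x3, p) + p.Fg(t) + Um)
    dy[11] = x1 * st * Q1 - (p.k12 + x2 * sd) * Q2
    # interstitial glucose
    G = Q1 / p.V
    dy[12] = p.ks * (G - Gs)
    return dy


def derivatives(state: ModelState, params: PatientParameters,
                inputs: ExogenousInputs, t: float = 0.0) -> ModelState:
    """Time-derivatives of all 13 state variables at time t (minutes).

    Raises :class:`ModelError` naming the offending variable if the state
    has a negative or non-finite component.
    """
    state.validate()
    return ModelState.from_array(_rhs(t, state.as_array(), params, inputs))


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def insulin_chain_steady(u: float, params: PatientParameters,
                         im: float = 1.0) -> dict[str, float]:
    """Analytic steady state of the insulin PK chain under constant infusion
    u (U/min) with the diurnal multiplier held at ``im``.

    Returns the five insulin masses plus the resulting plasma concentration;
    the remote effects x1..x3 equal Ip at steady state.
    """
    p = params
    Qis1 = u * p.pi / p.kis1
    Qis2 = u * p.pi / p.kis2
    Qif1 = u * (1.0 - p.pi) / p.kif
    Qif2 = Qif1
    Qi = (u * im + p.ci) / p.ke
    return {"Qis1": Qis1, "Qis2": Qis2, "Qif1": Qif1, "Qif2": Qif2,
            "Qi": Qi, "Ip": plasma_insulin(Qi, p)}


def subcutaneous_residence_time(params: PatientParameters) -> float:
    """Mean minutes a unit of infused insulin spends under the skin; the
    total depot mass at steady basal u is u times this."""
    p = params
    return p.pi * (1.0 / p.kis1 + 1.0 / p.kis2) + (1.0 - p.pi) * 2.0 / p.kif


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

class IntegrationError(RuntimeError):
    """Solver failure, carrying the patient and interval context."""


def integrate(state: ModelState, params: PatientParameters,
              inputs: ExogenousInputs, t0: float, t1: float,
              rtol: float = 1e-8, atol: float = 1e-10,
              _retried: bool = False) -> ModelState:
    """Advance the model from t0 to t1 (minutes) under piecewise-constant
    infusions and the continuous meal forcing.

    Uses an adaptive stiff-capable solver (LSODA).  Negative components in
    the accepted solution are handled by one retry at tighter tolerance,
    then clamped to zero with a logged warning — silent clamping could mask
    parameter pathologies.
    """
    if t1 <= t0:
        raise ModelError(f"integration window must be forward: [{t0}, {t1}]")
    y0 = state.as_array()
    sol = solve_ivp(_rhs, (t0, t1), y0, method="LSODA",
                    args=(params, inputs), rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"solver failed for patient {params.patient_id} "
            f"on [{t0}, {t1}]: {sol.message}")
    y1 = sol.y[:, -1]
    if np.any(y1 < 0):
        scale = max(1.0, float(np.max(np.abs(y1))))
        worst = float(np.min(y1))
        if worst < -1e-9 * scale and not _retried:
            return integrate(state, params, inputs, t0, t1,
                             rtol=rtol * 1e-2, atol=atol * 1e-2,
                             _retried=True)
        if worst < -1e-9 * scale:
            bad = STATE_NAMES[int(np.argmin(y1))]
            logger.warning(
                "clamping negative state %s=%.3e to 0 for patient %s at t=%.1f",
                bad, worst, params.patient_id, t1)
        y1 = np.maximum(y1, 0.0)
    return ModelState.from_array(y1)


def observe(state: ModelState, params: PatientParameters) -> dict[str, float]:
    """Derived observables from a state: plasma insulin Ip (mU/L), plasma
    glucagon Cp (mU/L), plasma glucose G and sensor glucose Gs (mmol/L)."""
    return {
        "Ip": plasma_insulin(state.Qi, params),
        "Cp": plasma_glucagon(state.Qg2, params),
        "G": plasma_glucose(state.Q1, params),
        "Gs": state.Gs,
    }
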