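"""Virtual clinical trial engine.

Turns a trial protocol into per-patient meal schedules, runs each virtual
patient against one independent controller instance in a repetitive
init/step loop, applies rescue carbohydrates when sensor glucose falls
below the safety threshold, and collects per-patient runs for the outcomes
report.

Fault isolation: an exception (or an invalid dose) raised by a controller
marks only that patient's run as failed; every other patient completes.
Determinism: all randomness is drawn from per-patient streams keyed by
(protocol seed, patient index), so runs are independent of execution order
and bit-for-bit reproducible.
"""
from __future__ import annotations

import logging
import math
import traceback
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Protocol as TypingProtocol, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import population
from .model import (
    DAY_MIN,
    STATE_NAMES,
    ExogenousInputs,
    MealEvent,
    ModelState,
    PatientParameters,
    insulin_chain_steady,
    observe,
    subcutaneous_residence_time,
    integrate,
)

logger = logging.getLogger("glucosim")

#: meals older than this contribute negligibly to gut appearance and are
#: dropped from the active set (exp(-km*tau) ~ 1e-8 at tau = 20/km)
_MEAL_HORIZON_FACTOR = 20.0


class Arm(str, Enum):
    OPEN_LOOP = "open-loop"
    SINGLE_HORMONE = "single-hormone"
    DUAL_HORMONE = "dual-hormone"


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------

def _parse_clock(s: str) -> float:
    """'HH:MM' -> minutes past midnight."""
    h, m = s.split(":")
    v = int(h) * 60 + int(m)
    if not (0 <= v < DAY_MIN):
        raise ValueError(f"clock time {s!r} outside the day")
    return float(v)


class MealSpec(BaseModel):
    """One recurring daily meal or snack in the protocol."""
    model_config = ConfigDict(extra="forbid")

    name: str
    clock_time: str                      # "HH:MM"
    cho_g: float = Field(gt=0)
    time_sd_min: float = Field(default=0.0, ge=0)
    amount_sd_g: float = Field(default=0.0, ge=0)

    @field_validator("clock_time")
    @classmethod
    def _check_clock(cls, v: str) -> str:
        _parse_clock(v)
        return v


class TrialProtocol(BaseModel):
    """Machine-readable experiment design for one virtual trial arm."""
    model_config = ConfigDict(extra="forbid")

    duration_days: int = Field(default=1, ge=0)
    duration_hours: float = Field(default=0.0, ge=0)
    start_time: str = "08:00"
    dosing_step_min: float = Field(default=10.0, ge=1)
    start_glucose: float = Field(default=7.0, gt=0)
    start_glucose_sd: float = Field(default=0.0, ge=0)
    insulin_on_board: float | None = Field(default=None, ge=0)
    meals: list[MealSpec] = Field(default_factory=list)
    carb_counting_error: bool = False
    rescue_threshold: float = Field(default=3.3, gt=0)
    rescue_cho_g: float = Field(default=16.0, gt=0)
    rescue_lockout_min: float = Field(default=15.0, ge=0)
    arm: Arm = Arm.OPEN_LOOP
    #: optional loop-loss window(s) [start_min, end_min) from trial start
    #: during which the controller is not consulted and the pump falls back
    #: to the patient's programmed basal (emulates a lost sensor/algorithm
    #: connection)
    loop_loss_windows: list[tuple[float, float]] = Field(default_factory=list)
    seed: int = 0

    @field_validator("start_time")
    @classmethod
    def _check_start(cls, v: str) -> str:
        _parse_clock(v)
        return v

    @property
    def duration_min(self) -> float:
        total = self.duration_days * DAY_MIN + self.duration_hours * 60.0
        if total <= 0:
            raise ValueError("trial duration must be > 0")
        return total

    @property
    def start_clock_min(self) -> float:
        return _parse_clock(self.start_time)

    @property
    def n_steps(self) -> int:
        return int(math.ceil(self.duration_min / self.dosing_step_min))


# ---------------------------------------------------------------------------
# Controller contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControllerSetup:
    """What a controller learns at trial start (patient-visible only)."""
    start_glucose: float          # mmol/L
    dosing_step_min: float
    insulin_on_board: float       # U
    arm: Arm
    basal_rate: float             # U/min, pump-programmed
    icr: float                    # g/U


class Controller(TypingProtocol):
    """Two-method contract every control algorithm implements.

    ``init`` receives the trial setup once; ``step`` is then called
    repeatedly, once per dosing interval, with the current sensor glucose
    (mmol/L), the carbohydrate announcement for this step (g, 0 if none)
    and the time since trial start (min).  It returns the total insulin (U)
    and glucagon (mg) to deliver over the coming interval.
    """

    def init(self, setup: ControllerSetup) -> None: ...

    def step(self, glucose: float, announced_meal_cho: float,
             t_min: float) -> tuple[float, float]: ...


ControllerFactory = Callable[[int], Controller]


# ---------------------------------------------------------------------------
# Reference controllers
# ---------------------------------------------------------------------------

class OpenLoopController:
    """Conventional pump therapy: constant basal plus carbohydrate-counted
    meal boluses (announced CHO / ICR).  Never delivers glucagon."""

    def init(self, setup: ControllerSetup) -> None:
        self.basal = setup.basal_rate
        self.icr = setup.icr
        self.dt = setup.dosing_step_min

    def step(self, glucose: float, announced_meal_cho: float,
             t_min: float) -> tuple[float, float]:
        insulin = self.basal * self.dt
        if announced_meal_cho > 0:
            insulin += announced_meal_cho / self.icr
        return insulin, 0.0


class SingleHormoneController(OpenLoopController):
    """Open-loop therapy augmented with a glucose-responsive basal:
    suspend below the low threshold, taper toward it, and scale up
    modestly during hyperglycemia.  A minimal but genuinely closed loop."""

    LOW_SUSPEND = 4.5     # mmol/L, basal off below this
    LOW_TAPER = 6.0       # mmol/L, basal linearly restored up to this
    HIGH = 10.0           # mmol/L, basal scaled up above this
    MAX_SCALE = 2.0

    def _basal_scale(self, glucose: float) -> float:
        if glucose < self.LOW_SUSPEND:
            return 0.0
        if glucose < self.LOW_TAPER:
            return (glucose - self.LOW_SUSPEND) / (self.LOW_TAPER - self.LOW_SUSPEND)
        if glucose > self.HIGH:
            return min(self.MAX_SCALE, 1.0 + 0.15 * (glucose - self.HIGH))
        return 1.0

    def step(self, glucose: float, announced_meal_cho: float,
             t_min: float) -> tuple[float, float]:
        insulin = self.basal * self.dt * self._basal_scale(glucose)
        if announced_meal_cho > 0:
            insulin += announced_meal_cho / self.icr
        return insulin, 0.0


class DualHormoneController(SingleHormoneController):
    """Single-hormone logic plus a glucagon-on-low rule: a small glucagon
    bolus whenever sensor glucose drops below the glucagon threshold,
    rate-limited by a lockout."""

    GLUCAGON_THRESHOLD = 4.3   # mmol/L
    GLUCAGON_DOSE_MG = 0.15
    GLUCAGON_LOCKOUT = 30.0    # min

    def init(self, setup: ControllerSetup) -> None:
        super().init(setup)
        self._last_glucagon = -np.inf

    def step(self, glucose: float, announced_meal_cho: float,
             t_min: float) -> tuple[float, float]:
        insulin, _ = super().step(glucose, announced_meal_cho, t_min)
        glucagon = 0.0
        if (glucose < self.GLUCAGON_THRESHOLD
                and t_min - self._last_glucagon >= self.GLUCAGON_LOCKOUT):
            glucagon = self.GLUCAGON_DOSE_MG
            self._last_glucagon = t_min
        return insulin, glucagon


def reference_controller_factory(arm: Arm) -> ControllerFactory:
    cls = {Arm.OPEN_LOOP: OpenLoopController,
           Arm.SINGLE_HORMONE: SingleHormoneController,
           Arm.DUAL_HORMONE: DualHormoneController}[arm]
    return lambda patient_index: cls()


# ---------------------------------------------------------------------------
# Schedules and initial state
# ---------------------------------------------------------------------------

_MAX_TIME_REDRAWS = 10


def build_schedule(protocol: TrialProtocol, patient_index: int,
                   rng: np.random.Generator,
                   log: list[dict] | None = None) -> list[MealEvent]:
    """Per-patient meal events for the whole trial.

    Meal times and amounts are perturbed by the configured SDs; with
    carb-counting error enabled the announced amount is the true amount
    times (1 + e), e uniform on [-0.20, +0.20], rounded to 1 g and floored
    at 0.  Perturbed times falling outside their day are redrawn a bounded
    number of times, then clamped with a log entry.
    """
    events: list[MealEvent] = []
    start_clock = protocol.start_clock_min
    n_days = int(math.ceil(protocol.duration_min / DAY_MIN))
    for day in range(n_days):
        for meal in protocol.meals:
            offset = (_parse_clock(meal.clock_time) - start_clock) % DAY_MIN
            nominal = day * DAY_MIN + offset
            t = nominal
            if meal.time_sd_min > 0:
                lo, hi = day * DAY_MIN, (day + 1) * DAY_MIN
                for attempt in range(_MAX_TIME_REDRAWS):
                    t = nominal + rng.normal(0.0, meal.time_sd_min)
                    if lo <= t < hi:
                        break
                else:
                    t = float(np.clip(t, lo, hi - 1.0))
                    if log is not None:
                        log.append({"event": "meal_time_clamped",
                                    "patient": patient_index,
                                    "meal": meal.name, "time_min": t})
            if t >= protocol.duration_min:
                continue
            cho = meal.cho_g
            if meal.amount_sd_g > 0:
                for _ in range(_MAX_TIME_REDRAWS):
                    cho = rng.normal(meal.cho_g, meal.amount_sd_g)
                    if cho > 0:
                        break
                else:
                    cho = meal.cho_g
            announced = cho
            if protocol.carb_counting_error:
                eps = rng.uniform(-0.20, 0.20)
                announced = max(0.0, round(cho * (1.0 + eps)))
                # rounding to 1 g must not push the announcement outside
                # the 0-20% error envelope
                lo_a, hi_a = math.ceil(0.8 * cho), math.floor(1.2 * cho)
                if lo_a <= hi_a:
                    announced = float(np.clip(announced, lo_a, hi_a))
            events.append(MealEvent(time_min=float(t), cho_g=float(cho),
                                    announced_cho_g=float(announced),
                                    kind="snack" if meal.name == "snack"
                                    else "meal"))
    events.sort(key=lambda e: e.time_min)
    return events


def init_state(patient: PatientParameters, protocol: TrialProtocol,
               rng: np.random.Generator) -> ModelState:
    """Initial model state for one patient.

    Starting glucose is the protocol level plus Gaussian noise (redrawn if
    non-positive); insulin compartments are preloaded at the steady state of
    a basal rate consistent with the configured insulin-on-board (or the
    patient's programmed basal when none is given); the non-accessible
    glucose pool sits at its conditional steady state; glucagon starts
    empty so plasma glucagon equals the background level.
    """
    g0 = protocol.start_glucose
    if protocol.start_glucose_sd > 0:
        for _ in range(_MAX_TIME_REDRAWS):
            g0 = rng.normal(protocol.start_glucose, protocol.start_glucose_sd)
            if g0 > 0:
                break
        else:
            g0 = protocol.start_glucose

    if protocol.insulin_on_board is not None:
        depot_time = subcutaneous_residence_time(patient)
        u0 = protocol.insulin_on_board / depot_time
    else:
        u0 = patient.basal_rate
    ss = insulin_chain_steady(u0, patient,
                              im=patient.Im(protocol.start_clock_min))
    ip = ss["Ip"]
    q1 = g0 * patient.V
    st = patient.St * 1e-4
    sd = patient.Sd * 1e-4
    q2 = ip * st * q1 / (patient.k12 + ip * sd)
    return ModelState(
        Qis1=ss["Qis1"], Qis2=ss["Qis2"], Qif1=ss["Qif1"], Qif2=ss["Qif2"],
        Qi=ss["Qi"], x1=ip, x2=ip, x3=ip,
        Qg1=0.0, Qg2=0.0, Q1=q1, Q2=q2, Gs=g0)


# ---------------------------------------------------------------------------
# Rescue carbohydrates
# ---------------------------------------------------------------------------

@dataclass
class RescueState:
    last_rescue_min: float = -np.inf


def apply_rescue(gs: float, t: float, rescue_state: RescueState,
                 protocol: TrialProtocol) -> MealEvent | None:
    """Emit an (unannounced) rescue carbohydrate when sensor glucose is
    below the threshold and the previous rescue's lockout has elapsed."""
    if gs >= protocol.rescue_threshold:
        return None
    if t - rescue_state.last_rescue_min < protocol.rescue_lockout_min:
        return None
    rescue_state.last_rescue_min = t
    return MealEvent(time_min=t, cho_g=protocol.rescue_cho_g,
                     announced_cho_g=0.0, kind="rescue")


# ---------------------------------------------------------------------------
# Per-patient run
# ---------------------------------------------------------------------------

@dataclass
class PatientRun:
    """Complete record of one patient's trial: states on the dosing grid,
    deliveries per step, meal and rescue events, and completion status."""

    patient_id: str
    patient_index: int
    times: np.ndarray                  # (n_steps+1,) min from start
    states: np.ndarray                 # (n_steps+1, 13)
    insulin_U: np.ndarray              # (n_steps,) delivered per step
    glucagon_mg: np.ndarray            # (n_steps,)
    meals: list[MealEvent]
    rescues: list[MealEvent]
    status: str                        # "completed" | "controller-failed..."
    weight_kg: float
    events: list[dict] = field(default_factory=list)

    @property
    def completed(self) -> bool:
        return self.status == "completed"

    @property
    def gs_trace(self) -> np.ndarray:
        return self.states[:, STATE_NAMES.index("Gs")]

    @property
    def g_trace(self) -> np.ndarray:
        return self.states[:, STATE_NAMES.index("Q1")] / self._V

    _V: float = 1.0

    def to_dataframe(self, patient: PatientParameters) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_min", self.times)
        obs = [observe(ModelState.from_array(s), patient)
               for s in self.states]
        for key in ("Ip", "Cp", "G"):
            df[key] = [o[key] for o in obs]
        # Gs already a state column; keep derived order Ip, Cp, G, Gs
        df["Gs_sensor"] = df["Gs"]
        return df


def _in_loop_loss(t: float, protocol: TrialProtocol) -> bool:
    return any(lo <= t < hi for lo, hi in protocol.loop_loss_windows)


def run_patient(patient: PatientParameters, patient_index: int,
                controller: Controller, protocol: TrialProtocol
                ) -> PatientRun:
    """Simulate one patient for the whole trial under one controller.

    All randomness (schedule, starting glucose, daily fluxes) comes from
    streams keyed by (protocol.seed, patient_index), independent of any
    other patient.
    """
    events: list[dict] = []
    rng_sched = np.random.default_rng([protocol.seed, patient_index, 1])
    rng_init = np.random.default_rng([protocol.seed, patient_index, 2])
    schedule = build_schedule(protocol, patient_index, rng_sched, events)
    state = init_state(patient, protocol, rng_init)

    dt = protocol.dosing_step_min
    n_steps = protocol.n_steps
    times = np.arange(n_steps + 1) * dt
    states = np.zeros((n_steps + 1, len(STATE_NAMES)))
    states[0] = state.as_array()
    insulin = np.zeros(n_steps)
    glucagon = np.zeros(n_steps)
    rescues: list[MealEvent] = []
    rescue_state = RescueState()
    horizon = _MEAL_HORIZON_FACTOR / patient.km + patient.d
    start_clock = protocol.start_clock_min

    setup = ControllerSetup(
        start_glucose=state.Gs, dosing_step_min=dt,
        insulin_on_board=(protocol.insulin_on_board
                          if protocol.insulin_on_board is not None else 0.0),
        arm=protocol.arm, basal_rate=patient.basal_rate, icr=patient.icr)

    status = "completed"
    day_params = patient
    current_day = -1
    try:
        controller.init(setup)
    except Exception as exc:  # noqa: BLE001 — fault isolation is the contract
        events.append({"event": "controller_failure", "t_min": 0.0,
                       "error": repr(exc)})
        logger.warning("controller init failed for %s: %s",
                       patient.patient_id, traceback.format_exc(limit=2))
        return PatientRun(patient.patient_id, patient_index, times, states,
                          insulin, glucagon, schedule, rescues,
                          f"controller-failed at t=0.0: {exc!r}",
                          patient.w, events)

    for k in range(n_steps):
        t = k * dt
        clock_t = start_clock + t

        day = int(t // DAY_MIN)
        if day != current_day:
            current_day = day
            if patient.flux_dispersion > 0 and day > 0:
                rng_day = np.random.default_rng(
                    [protocol.seed, patient_index, 3, day])
                day_params = population.resample_fluxes(
                    patient, rng_day,
                    flux_knots=max(2, len(patient.Im.times)))
                events.append({"event": "fluxes_resampled", "day": day})

        gs = float(states[k, STATE_NAMES.index("Gs")])

        rescue = apply_rescue(gs, t, rescue_state, protocol)
        if rescue is not None:
            rescues.append(rescue)
            events.append({"event": "rescue", "t_min": t,
                           "cho_g": rescue.cho_g})

        announced = sum(m.announced_cho_g for m in schedule
                        if t <= m.time_min < t + dt)
        for m in schedule:
            if t <= m.time_min < t + dt:
                events.append({"event": "meal", "t_min": m.time_min,
                               "cho_g": m.cho_g,
                               "announced_cho_g": m.announced_cho_g,
                               "kind": m.kind})

        if _in_loop_loss(t, protocol):
            dose_i, dose_g = patient.basal_rate * dt, 0.0
        else:
            try:
                dose_i, dose_g = controller.step(gs, float(announced), t)
            except Exception as exc:  # noqa: BLE001
                status = f"controller-failed at t={t}: {exc!r}"
                events.append({"event": "controller_failure", "t_min": t,
                               "error": repr(exc)})
                break
            if not (np.isfinite(dose_i) and np.isfinite(dose_g)
                    and dose_i >= 0 and dose_g >= 0):
                status = (f"controller-failed at t={t}: invalid doses "
                          f"({dose_i!r} U, {dose_g!r} mg)")
                events.append({"event": "controller_failure", "t_min": t,
                               "error": status})
                break
        if dose_g > 0 and protocol.arm != Arm.DUAL_HORMONE:
            events.append({"event": "glucagon_suppressed", "t_min": t,
                           "dose_mg": dose_g})
            logger.warning("glucagon dose in %s arm suppressed (patient %s)",
                           protocol.arm.value, patient.patient_id)
            dose_g = 0.0

        insulin[k] = dose_i
        glucagon[k] = dose_g
        events.append({"event": "dose", "t_min": t, "insulin_U": dose_i,
                       "glucagon_mg": dose_g})

        # clock-time forcing: the ODE clock is minutes past midnight so the
        # diurnal fluxes line up with wall-clock knots
        active = tuple(
            MealEvent(m.time_min + start_clock, m.cho_g, m.announced_cho_g,
                      m.kind)
            for m in [*schedule, *rescues]
            if m.time_min <= t + dt and t - m.time_min < horizon)
        inputs = ExogenousInputs(ui=dose_i / dt, ug=dose_g / dt,
                                 meals=active)
        state = ModelState.from_array(states[k])
        state = integrate(state, day_params, inputs,
                          clock_t, clock_t + dt)
        states[k + 1] = state.as_array()

    if status != "completed":
        # freeze the remainder of the traces at the failure point
        kfail = int(np.argmax(times >= t)) if n_steps else 0
        states[kfail:] = states[max(kfail - 1, 0)]

    run = PatientRun(patient.patient_id, patient_index, times, states,
                     insulin, glucagon, schedule, rescues, status,
                     patient.w, events)
    run._V = patient.V
    return run


# ---------------------------------------------------------------------------
# Cohort-level trial
# ---------------------------------------------------------------------------

def run_trial(cohort: population.Cohort | Sequence[PatientParameters],
              controller_factory: ControllerFactory,
              protocol: TrialProtocol) -> list[PatientRun]:
    """Run every patient in the cohort against its own controller instance.

    Patient runs are mutually independent; a controller failure for one
    patient never disturbs the others.  Returns runs in cohort order.
    """
    patients = list(cohort)
    if not patients:
        raise ValueError("cohort is empty")
    runs: list[PatientRun] = []
    for idx, patient in enumerate(patients):
        controller = controller_factory(idx)
        run = run_patient(patient, idx, controller, protocol)
        logger.info("patient %s: %s, mean Gs %.2f mmol/L, "
                    "insulin %.1f U, glucagon %.2f mg",
                    patient.patient_id, run.status,
                    float(np.mean(run.gs_trace)),
                    float(np.sum(run.insulin_U)),
                    float(np.sum(run.glucagon_mg)))
        runs.append(run)
    return runs
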