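"""Tests for scheduling, initial state, rescue logic, the controller loop,
fault isolation and determinism of the trial engine."""
import dataclasses

import numpy as np
import pytest

from glucosim.engine import (
    Arm,
    ControllerSetup,
    DualHormoneController,
    OpenLoopController,
    RescueState,
    TrialProtocol,
    apply_rescue,
    build_schedule,
    init_state,
    reference_controller_factory,
    run_patient,
    run_trial,
)
from glucosim.model import ExogenousInputs, constant_flux, integrate
from glucosim.cli import canonical_protocol


def make_protocol(**kw) -> TrialProtocol:
    defaults = dict(duration_days=1, start_time="08:00", dosing_step_min=10,
                    start_glucose=7.0, seed=0)
    defaults.update(kw)
    return TrialProtocol(**defaults)


FOUR_MEALS = [
    {"name": "breakfast", "clock_time": "08:00", "cho_g": 59.0},
    {"name": "lunch", "clock_time": "12:00", "cho_g": 70.0},
    {"name": "dinner", "clock_time": "17:00", "cho_g": 95.0},
    {"name": "snack", "clock_time": "21:00", "cho_g": 20.0},
]


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

class TestBuildSchedule:
    def test_canonical_four_meals_no_variability(self, rng):
        proto = make_protocol(meals=FOUR_MEALS)
        events = build_schedule(proto, 0, rng)
        assert [(e.time_min, e.cho_g) for e in events] == [
            (0.0, 59.0), (240.0, 70.0), (540.0, 95.0), (780.0, 20.0)]

    def test_announced_equals_true_without_carb_error(self, rng):
        proto = make_protocol(meals=FOUR_MEALS, carb_counting_error=False)
        for e in build_schedule(proto, 0, rng):
            assert e.announced_cho_g == e.cho_g

    def test_carb_error_envelope(self, rng):
        # 10^4 meals: every announced/true ratio within the 0-20% band and
        # the mean ratio within 3 SE of 1 (uniform error model)
        proto = make_protocol(
            duration_days=2500, carb_counting_error=True,
            meals=FOUR_MEALS)
        events = build_schedule(proto, 0, rng)
        assert len(events) == 10_000
        ratios = np.array([e.announced_cho_g / e.cho_g for e in events])
        assert ratios.min() >= 0.80 - 1e-12
        assert ratios.max() <= 1.20 + 1e-12
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * se

    def test_meal_time_variability_stays_in_day(self, rng):
        proto = make_protocol(
            duration_days=30,
            meals=[{"name": "late", "clock_time": "07:50", "cho_g": 40.0,
                    "time_sd_min": 300.0}])
        events = build_schedule(proto, 0, rng)
        for e in events:
            day = e.time_min // 1440
            assert 0 <= e.time_min - day * 1440 < 1440

    def test_schedule_is_deterministic_per_stream(self):
        proto = make_protocol(meals=FOUR_MEALS, carb_counting_error=True)
        e1 = build_schedule(proto, 0, np.random.default_rng(5))
        e2 = build_schedule(proto, 0, np.random.default_rng(5))
        assert e1 == e2


# ---------------------------------------------------------------------------
# Initial state
# ---------------------------------------------------------------------------

class TestInitState:
    def test_starting_glucose_exact_without_noise(self, fixture_cohort, rng):
        proto = make_protocol(start_glucose=7.0)
        for p in fixture_cohort:
            s = init_state(p, proto, rng)
            assert s.Q1 / p.V == pytest.approx(7.0)
            assert s.Gs == pytest.approx(7.0)

    def test_zero_iob_zero_compartments(self, template_patient, rng):
        proto = make_protocol(insulin_on_board=0.0)
        s = init_state(template_patient, proto, rng)
        for name in ("Qis1", "Qis2", "Qif1", "Qif2", "Qi"):
            assert getattr(s, name) == 0.0

    def test_basal_preload_matches_chain_steady_state(self, template_patient,
                                                      rng):
        p = dataclasses.replace(template_patient, Im=constant_flux(1.0))
        proto = make_protocol()
        s = init_state(p, proto, rng)
        assert s.Qi == pytest.approx((p.basal_rate + p.ci) / p.ke)

    def test_noisy_start_glucose_positive(self, template_patient):
        proto = make_protocol(start_glucose=3.0, start_glucose_sd=2.0)
        for seed in range(30):
            s = init_state(template_patient, proto,
                           np.random.default_rng(seed))
            assert s.Gs > 0


# ---------------------------------------------------------------------------
# Rescue carbohydrates
# ---------------------------------------------------------------------------

class TestRescue:
    def test_no_rescue_above_threshold(self):
        proto = make_protocol()
        rs = RescueState()
        for t in range(0, 100, 10):
            assert apply_rescue(3.3, float(t), rs, proto) is None
            assert apply_rescue(5.0, float(t), rs, proto) is None

    def test_single_dip_single_rescue(self):
        proto = make_protocol()
        rs = RescueState()
        ev = apply_rescue(3.1, 50.0, rs, proto)
        assert ev is not None and ev.cho_g == 16.0 and ev.kind == "rescue"
        assert ev.announced_cho_g == 0.0

    def test_lockout_prevents_double_dosing(self):
        proto = make_protocol(rescue_lockout_min=15.0)
        rs = RescueState()
        assert apply_rescue(3.0, 0.0, rs, proto) is not None
        assert apply_rescue(2.9, 10.0, rs, proto) is None   # within lockout
        assert apply_rescue(2.9, 15.0, rs, proto) is not None

    def test_rescues_emitted_in_trial_when_hypoglycemic(self, fixture_cohort):
        # a controller that floods insulin drives everyone low -> rescues
        class Flood(OpenLoopController):
            def step(self, glucose, announced, t):
                return 2.0, 0.0

        proto = make_protocol(duration_hours=6, duration_days=0)
        runs = run_trial(list(fixture_cohort)[:3], lambda i: Flood(), proto)
        for run in runs:
            below = run.gs_trace < proto.rescue_threshold
            if below.any():
                assert len(run.rescues) >= 1


# ---------------------------------------------------------------------------
# Controller loop
# ---------------------------------------------------------------------------

class ZeroController:
    def init(self, setup):
        pass

    def step(self, glucose, announced, t):
        return 0.0, 0.0


class TestRunTrial:
    def test_zero_dose_engine_matches_bare_integrator(self, template_patient):
        """With no meals, no background hormones and a zero-dose controller,
        the engine's trace must equal direct model integration."""
        p = dataclasses.replace(template_patient, ci=0.0, Cb=0.0, Sg=0.0,
                                Fg=constant_flux(0.0))
        # start high and keep the window short so non-insulin-dependent
        # uptake never pulls glucose down to the rescue threshold
        proto = make_protocol(duration_days=0, duration_hours=2,
                              start_glucose=10.0,
                              insulin_on_board=0.0, rescue_threshold=0.1)
        run = run_patient(p, 0, ZeroController(), proto)
        # oracle: direct integration from the same initial state
        state = init_state(p, proto, np.random.default_rng([0, 0, 2]))
        clock0 = proto.start_clock_min
        expected = [state.as_array()]
        for k in range(proto.n_steps):
            state = integrate(state, p, ExogenousInputs(),
                              clock0 + k * 10.0, clock0 + (k + 1) * 10.0)
            expected.append(state.as_array())
        assert np.allclose(run.states, np.array(expected), rtol=1e-9,
                           atol=1e-12)

    def test_seed_determinism(self, fixture_cohort):
        proto = canonical_protocol(arm=Arm.OPEN_LOOP, seed=11)
        factory = reference_controller_factory(Arm.OPEN_LOOP)
        r1 = run_trial(fixture_cohort, factory, proto)
        r2 = run_trial(fixture_cohort, factory, proto)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.states, b.states)
            assert np.array_equal(a.insulin_U, b.insulin_U)
            assert a.meals == b.meals and a.status == b.status

    def test_patient_order_independence(self, fixture_cohort):
        proto = canonical_protocol(arm=Arm.OPEN_LOOP, seed=11)
        patients = list(fixture_cohort)
        forward = [run_patient(p, i, OpenLoopController(), proto)
                   for i, p in enumerate(patients)]
        backward = {i: run_patient(patients[i], i, OpenLoopController(),
                                   proto)
                    for i in reversed(range(len(patients)))}
        for i, f in enumerate(forward):
            assert np.array_equal(f.states, backward[i].states)
            assert np.array_equal(f.insulin_U, backward[i].insulin_U)

    def test_fault_isolation(self, fixture_cohort):
        failing = {2, 7, 11}

        class Throws(OpenLoopController):
            def __init__(self, idx):
                self.idx = idx
                self.calls = 0

            def step(self, glucose, announced, t):
                self.calls += 1
                if self.idx in failing and self.calls == 3:
                    raise RuntimeError("boom")
                return super().step(glucose, announced, t)

        proto = canonical_protocol(arm=Arm.OPEN_LOOP, seed=0)
        runs = run_trial(fixture_cohort, lambda i: Throws(i), proto)
        completed = {r.patient_index for r in runs if r.completed}
        assert completed == set(range(15)) - failing
        for r in runs:
            if r.patient_index in failing:
                assert r.status.startswith("controller-failed at t=20")

    def test_invalid_doses_fail_that_patient(self, fixture_cohort):
        class Negative(OpenLoopController):
            def step(self, glucose, announced, t):
                return -1.0, 0.0

        proto = make_protocol(duration_days=0, duration_hours=2)
        runs = run_trial(list(fixture_cohort)[:2], lambda i: Negative(),
                         proto)
        assert all("invalid doses" in r.status for r in runs)

    def test_delivery_bookkeeping_exact(self, fixture_cohort):
        """Total recorded insulin equals the sum of controller returns."""
        returned = []

        class Recording(OpenLoopController):
            def step(self, glucose, announced, t):
                dose = super().step(glucose, announced, t)
                returned.append(dose[0])
                return dose

        proto = canonical_protocol(arm=Arm.OPEN_LOOP, seed=3)
        run = run_patient(list(fixture_cohort)[0], 0, Recording(), proto)
        assert np.array_equal(run.insulin_U, np.array(returned))

    def test_single_hormone_arm_records_no_glucagon(self, fixture_cohort):
        class Rogue(OpenLoopController):
            def step(self, glucose, announced, t):
                ins, _ = super().step(glucose, announced, t)
                return ins, 0.5    # illegal glucagon in this arm

        proto = make_protocol(duration_days=0, duration_hours=3,
                              arm=Arm.SINGLE_HORMONE)
        run = run_patient(list(fixture_cohort)[0], 0, Rogue(), proto)
        assert run.completed
        assert np.all(run.glucagon_mg == 0.0)

    def test_loop_loss_window_falls_back_to_basal(self, template_patient):
        class Marker(OpenLoopController):
            def __init__(self):
                self.times = []

            def step(self, glucose, announced, t):
                self.times.append(t)
                return super().step(glucose, announced, t)

        ctrl = Marker()
        proto = make_protocol(duration_days=0, duration_hours=3,
                              loop_loss_windows=[(60.0, 120.0)])
        run = run_patient(template_patient, 0, ctrl, proto)
        assert all(not (60 <= t < 120) for t in ctrl.times)
        # basal delivered during the outage
        steps_in_window = slice(6, 12)
        assert np.allclose(run.insulin_U[steps_in_window],
                           template_patient.basal_rate * 10.0)


# ---------------------------------------------------------------------------
# Reference controllers
# ---------------------------------------------------------------------------

class TestReferenceControllers:
    def _setup(self, basal=0.012, icr=10.0):
        return ControllerSetup(start_glucose=7.0, dosing_step_min=10.0,
                               insulin_on_board=0.0, arm=Arm.OPEN_LOOP,
                               basal_rate=basal, icr=icr)

    def test_open_loop_basal_only_without_meals(self):
        c = OpenLoopController()
        c.init(self._setup())
        for t in range(0, 120, 10):
            ins, glu = c.step(7.0, 0.0, float(t))
            assert ins == pytest.approx(0.012 * 10.0)
            assert glu == 0.0

    def test_open_loop_meal_bolus_follows_icr(self):
        c = OpenLoopController()
        c.init(self._setup(icr=10.0))
        ins, _ = c.step(7.0, 60.0, 0.0)
        assert ins == pytest.approx(0.012 * 10.0 + 6.0)

    def test_bolus_follows_announced_not_true_cho(self, template_patient):
        # the controller sees only the announced amount; the model receives
        # the true amount
        proto = make_protocol(
            duration_days=0, duration_hours=4, carb_counting_error=True,
            meals=[{"name": "m", "clock_time": "08:30", "cho_g": 60.0}])
        run = run_patient(template_patient, 0, OpenLoopController(), proto)
        meal = run.meals[0]
        assert meal.announced_cho_g != meal.cho_g  # error drawn for seed 0
        step = int(meal.time_min // 10)
        bolus = run.insulin_U[step] - template_patient.basal_rate * 10.0
        assert bolus == pytest.approx(meal.announced_cho_g /
                                      template_patient.icr)

    def test_dual_hormone_glucagon_on_low_with_lockout(self):
        c = DualHormoneController()
        c.init(self._setup())
        assert c.step(5.0, 0.0, 0.0)[1] == 0.0
        assert c.step(4.0, 0.0, 10.0)[1] == pytest.approx(0.15)
        assert c.step(3.8, 0.0, 20.0)[1] == 0.0      # lockout
        assert c.step(3.8, 0.0, 40.0)[1] == pytest.approx(0.15)

    def test_single_hormone_suspends_when_low(self):
        from glucosim.engine import SingleHormoneController
        c = SingleHormoneController()
        c.init(self._setup())
        assert c.step(4.0, 0.0, 0.0)[0] == 0.0
        assert c.step(7.0, 0.0, 10.0)[0] == pytest.approx(0.12)
        assert c.step(12.0, 0.0, 20.0)[0] > 0.12


# ---------------------------------------------------------------------------
# Protocol validation
# ---------------------------------------------------------------------------

def test_protocol_rejects_bad_values():
    with pytest.raises(Exception):
        make_protocol(dosing_step_min=0)
    with pytest.raises(Exception):
        make_protocol(start_time="25:00")
    with pytest.raises(Exception):
        TrialProtocol(unknown_field=1)
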