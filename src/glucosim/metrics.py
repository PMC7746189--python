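"""Clinical outcome battery for sensor-glucose traces.

Implements the standard glycemic report: percentage time in target (4-8 and
4-10 mmol/L), hypoglycemia exposure (% time and AUC below 4.0 / 3.5 / 3.3 /
3.1 mmol/L), hyperglycemia exposure (% time and AUC above 8 and 10 mmol/L),
incidence counts with a hysteresis rule, glycemic variability (mean and SD
of sensor glucose), hormone delivery totals, a nocturnal sub-report on a
configurable overnight clock window, and cohort aggregation as median, IQR,
mean and SD.

Conventions (documented so results are reproducible bit-for-bit):
%time attributes one sampling interval to each sample; AUC uses exact
linear interpolation at threshold crossings; a new hypo-/hyperglycemic
event requires prior recovery past the threshold by the hysteresis band
(default 0.6 mmol/L).  AUC is reported in mmol/L*min.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import DAY_MIN
from .population import Cohort, baseline_characteristics

HYSTERESIS_MMOL_L = 0.6

#: default overnight window, minutes past midnight (23:00 -> 07:00)
NOCTURNAL_WINDOW = (23 * 60.0, 7 * 60.0)


class TraceError(ValueError):
    pass


@dataclass(frozen=True)
class GlucoseTrace:
    """Uniformly sampled sensor glucose (mmol/L)."""

    times: np.ndarray          # min
    values: np.ndarray         # mmol/L

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size < 2 or v.size != t.size:
            raise TraceError("trace needs >= 2 matching samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0]):
            raise TraceError("trace must be uniformly sampled")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise TraceError("glucose values must be finite and > 0")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


# ---------------------------------------------------------------------------
# Core metrics
# ---------------------------------------------------------------------------

def time_in_range(trace: GlucoseTrace, lo: float, hi: float) -> float:
    """Percent of time with lo <= Gs <= hi, one interval per sample."""
    if lo >= hi:
        raise TraceError("lo must be < hi")
    v = trace.values
    return 100.0 * float(np.mean((v >= lo) & (v <= hi)))


def time_below(trace: GlucoseTrace, threshold: float) -> float:
    return 100.0 * float(np.mean(trace.values < threshold))


def time_above(trace: GlucoseTrace, threshold: float) -> float:
    return 100.0 * float(np.mean(trace.values > threshold))


def auc_outside(trace: GlucoseTrace, threshold: float,
                side: Literal["below", "above"]) -> float:
    """Area (mmol/L*min) between the trace and a threshold, one-sided.

    Trapezoidal on the piecewise-linear trace with exact interpolation at
    threshold crossings, so a segment partially past the threshold
    contributes exactly its triangular tip.
    """
    if threshold <= 0:
        raise TraceError("threshold must be > 0")
    v = trace.values
    if side == "below":
        dev = threshold - v
    elif side == "above":
        dev = v - threshold
    else:
        raise TraceError(f"unknown side {side!r}")
    dt = trace.dt
    a, b = dev[:-1], dev[1:]
    area = np.zeros_like(a)
    both_pos = (a > 0) & (b > 0)
    area[both_pos] = 0.5 * (a[both_pos] + b[both_pos]) * dt
    # one endpoint past the threshold: triangular tip of width dt*pos/(pos-neg)
    cross = (a > 0) ^ (b > 0)
    pos = np.where(a > 0, a, b)[cross]
    neg = np.where(a > 0, b, a)[cross]
    area[cross] = 0.5 * pos * dt * pos / (pos - neg)
    return float(np.sum(area))


def count_events(trace: GlucoseTrace, threshold: float,
                 hysteresis: float = HYSTERESIS_MMOL_L,
                 side: Literal["below", "above"] = "below") -> int:
    """Number of maximal excursions past the threshold.

    After an event begins, a new one is only counted once glucose has first
    recovered beyond threshold +/- hysteresis (above it for hypoglycemia,
    below it for hyperglycemia); a partial recovery inside the band does
    not re-arm the counter.
    """
    if threshold <= 0:
        raise TraceError("threshold must be > 0")
    v = trace.values
    if side == "above":
        v = -v
        threshold = -threshold
    count = 0
    armed = True
    for x in v:
        if armed and x < threshold:
            count += 1
            armed = False
        elif not armed and x >= threshold + hysteresis:
            armed = True
    return count


# ---------------------------------------------------------------------------
# Per-patient battery
# ---------------------------------------------------------------------------

METRIC_NAMES = (
    "pct_time_4_8", "pct_time_4_10",
    "pct_time_below_4.0", "pct_time_below_3.5",
    "pct_time_below_3.3", "pct_time_below_3.1",
    "auc_below_4.0", "auc_below_3.5", "auc_below_3.1",
    "hypo_events",
    "pct_time_above_8", "pct_time_above_10",
    "auc_above_8", "auc_above_10",
    "hyper_events",
    "mean_glucose", "sd_glucose",
    "insulin_U_per_h", "insulin_U_per_kg_day", "glucagon_mg",
    "n_rescues",
)


def patient_metrics(trace: GlucoseTrace, *, insulin_total_U: float = 0.0,
                    glucagon_total_mg: float = 0.0, weight_kg: float = 70.0,
                    n_rescues: int = 0,
                    hypo_threshold: float = 3.3,
                    hysteresis: float = HYSTERESIS_MMOL_L) -> dict[str, float]:
    """The full outcome battery for one glucose trace."""
    hours = trace.duration / 60.0
    days = trace.duration / DAY_MIN
    v = trace.values
    return {
        "pct_time_4_8": time_in_range(trace, 4.0, 8.0),
        "pct_time_4_10": time_in_range(trace, 4.0, 10.0),
        "pct_time_below_4.0": time_below(trace, 4.0),
        "pct_time_below_3.5": time_below(trace, 3.5),
        "pct_time_below_3.3": time_below(trace, 3.3),
        "pct_time_below_3.1": time_below(trace, 3.1),
        "auc_below_4.0": auc_outside(trace, 4.0, "below"),
        "auc_below_3.5": auc_outside(trace, 3.5, "below"),
        "auc_below_3.1": auc_outside(trace, 3.1, "below"),
        "hypo_events": float(count_events(trace, hypo_threshold, hysteresis)),
        "pct_time_above_8": time_above(trace, 8.0),
        "pct_time_above_10": time_above(trace, 10.0),
        "auc_above_8": auc_outside(trace, 8.0, "above"),
        "auc_above_10": auc_outside(trace, 10.0, "above"),
        "hyper_events": float(count_events(trace, 10.0, hysteresis,
                                           side="above")),
        "mean_glucose": float(np.mean(v)),
        "sd_glucose": float(np.std(v, ddof=1)),
        "insulin_U_per_h": insulin_total_U / hours if hours else 0.0,
        "insulin_U_per_kg_day":
            insulin_total_U / weight_kg / days if days else 0.0,
        "glucagon_mg": glucagon_total_mg,
        "n_rescues": float(n_rescues),
    }


# ---------------------------------------------------------------------------
# Cohort aggregation and report
# ---------------------------------------------------------------------------

def summarize(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Cohort statistics per metric: median, IQR bounds, mean, SD."""
    if per_patient.empty:
        raise TraceError("no patients to summarize")
    rows = []
    for metric in per_patient.columns:
        v = per_patient[metric].to_numpy(float)
        rows.append({
            "metric": metric,
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        })
    return pd.DataFrame(rows).set_index("metric")


def nocturnal_mask(times_min: np.ndarray, start_clock_min: float,
                   window: tuple[float, float] = NOCTURNAL_WINDOW
                   ) -> np.ndarray:
    """True where the sample's wall-clock time lies in the overnight
    window; the window may wrap past midnight."""
    clock = (start_clock_min + np.asarray(times_min, float)) % DAY_MIN
    lo, hi = window
    if lo <= hi:
        return (clock >= lo) & (clock < hi)
    return (clock >= lo) | (clock < hi)


def nocturnal_trace(trace: GlucoseTrace, start_clock_min: float,
                    window: tuple[float, float] = NOCTURNAL_WINDOW
                    ) -> GlucoseTrace | None:
    """Overnight samples re-laid on a uniform grid (the window is
    contiguous each night, so concatenating nights keeps spacing uniform
    at the sampling interval for metric purposes)."""
    mask = nocturnal_mask(trace.times, start_clock_min, window)
    if int(mask.sum()) < 2:
        return None
    vals = trace.values[mask]
    times = np.arange(vals.size) * trace.dt
    return GlucoseTrace(times=times, values=vals)


@dataclass
class TrialReport:
    """Per-patient and cohort-aggregated clinical outcomes for one arm."""

    arm: str
    per_patient: pd.DataFrame           # index patient_id, columns metrics
    cohort: pd.DataFrame                # summarize() output
    nocturnal_per_patient: pd.DataFrame
    nocturnal_cohort: pd.DataFrame
    baseline: pd.DataFrame
    statuses: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        """Long format: patient, metric, value (plus the overnight block)."""
        blocks = []
        for period, df in (("full", self.per_patient),
                           ("nocturnal", self.nocturnal_per_patient)):
            if df.empty:
                continue
            t = df.reset_index().melt(id_vars="patient_id",
                                      var_name="metric", value_name="value")
            t.insert(0, "period", period)
            blocks.append(t)
        if not blocks:
            return pd.DataFrame(columns=["period", "patient_id",
                                         "metric", "value"])
        return pd.concat(blocks, ignore_index=True)

    def to_json_dict(self) -> dict:
        return {
            "arm": self.arm,
            "metadata": self.metadata,
            "statuses": self.statuses,
            "cohort": self.cohort.reset_index().to_dict(orient="records"),
            "nocturnal_cohort":
                self.nocturnal_cohort.reset_index().to_dict(orient="records"),
            "baseline": self.baseline.reset_index().to_dict(orient="records"),
        }


def build_report(runs: Sequence, cohort: Cohort, protocol,
                 metadata: dict | None = None) -> TrialReport:
    """Assemble the trial report from engine runs (completed patients only
    enter the outcome tables; failures are listed in ``statuses``)."""
    per, noct = {}, {}
    statuses = {}
    start_clock = protocol.start_clock_min
    for run, patient in zip(runs, cohort):
        statuses[run.patient_id] = run.status
        if not run.completed:
            continue
        trace = GlucoseTrace(times=run.times, values=run.gs_trace)
        per[run.patient_id] = patient_metrics(
            trace,
            insulin_total_U=float(np.sum(run.insulin_U)),
            glucagon_total_mg=float(np.sum(run.glucagon_mg)),
            weight_kg=run.weight_kg,
            n_rescues=len(run.rescues))
        ntrace = nocturnal_trace(trace, start_clock)
        if ntrace is not None:
            nmask = nocturnal_mask(run.times[:-1], start_clock)
            noct[run.patient_id] = patient_metrics(
                ntrace,
                insulin_total_U=float(np.sum(run.insulin_U[nmask])),
                glucagon_total_mg=float(np.sum(run.glucagon_mg[nmask])),
                weight_kg=run.weight_kg,
                n_rescues=sum(1 for r in run.rescues
                              if nocturnal_mask(np.array([r.time_min]),
                                                start_clock)[0]))
    if not statuses:
        raise TraceError("no patient runs to report")
    per_df = pd.DataFrame.from_dict(per, orient="index")
    per_df.index.name = "patient_id"
    noct_df = pd.DataFrame.from_dict(noct, orient="index")
    noct_df.index.name = "patient_id"
    return TrialReport(
        arm=protocol.arm.value,
        per_patient=per_df,
        cohort=summarize(per_df) if not per_df.empty else pd.DataFrame(),
        nocturnal_per_patient=noct_df,
        nocturnal_cohort=summarize(noct_df) if not noct_df.empty
            else pd.DataFrame(),
        baseline=baseline_characteristics(cohort),
        statuses=statuses,
        metadata=metadata or {},
    )
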