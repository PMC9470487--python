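"""Thermocouple-trace segmentation and heating metrics.

A trial alternates 5-min illumination and cooling phases (initial cooling,
TOTAL, cooling, NIR, cooling, VIS, cooling) while a thermocouple logs the
sample temperature every 20 s.  Two features summarise each illumination
phase:

* ΔT₅ — the temperature change over the first 300 s of the phase (a proxy
  for the steady-state excess temperature, since samples plateau by 5 min);
* maxHR — the maximum slope between two adjacent samples of the heating
  curve (°C/s), computed from the actual timestamp gaps with no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ThermalTrace",
    "TrialPlan",
    "Phase",
    "HeatingMetrics",
    "ILLUMINATION_LABELS",
    "canonical_plan",
    "segment_trial",
    "delta_t5",
    "max_heating_rate",
    "compute_heating_metrics",
    "read_trace",
    "read_plan",
    "check_reference_channel",
]

ILLUMINATION_LABELS = ("TOTAL", "NIR", "VIS")
PHASE_LABELS = ("COOL",) + ILLUMINATION_LABELS


@dataclass(frozen=True)
class ThermalTrace:
    """A time-stamped temperature series from one thermocouple channel."""

    times_s: np.ndarray
    temps_C: np.ndarray
    channel: str = "T1"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        T = np.asarray(self.temps_C, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "temps_C", T)
        if t.ndim != 1 or T.ndim != 1 or t.size != T.size:
            raise ValueError("times and temperatures must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(T))):
            raise ValueError("times and temperatures must be finite")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class Phase:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}; expected one of {PHASE_LABELS}")
        if not self.start_s < self.end_s:
            raise ValueError(f"phase {self.label}: start must precede end")


@dataclass(frozen=True)
class TrialPlan:
    """Ordered, contiguous, non-overlapping illumination/cooling phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        phases = tuple(
            p if isinstance(p, Phase) else Phase(*p) for p in self.phases
        )
        object.__setattr__(self, "phases", phases)
        if not phases:
            raise ValueError("trial plan needs at least one phase")
        for a, b in zip(phases, phases[1:]):
            if b.start_s != a.end_s:
                raise ValueError(
                    f"phases must be contiguous: {a.label} ends at {a.end_s} "
                    f"but {b.label} starts at {b.start_s}"
                )

    @property
    def span(self) -> tuple[float, float]:
        return self.phases[0].start_s, self.phases[-1].end_s

    def illumination_phases(self) -> list[Phase]:
        return [p for p in self.phases if p.label != "COOL"]


def canonical_plan(
    phase_s: float = 300.0,
    initial_cool_s: float | None = None,
    start_s: float = 0.0,
) -> TrialPlan:
    """The seven-phase cycle: cool, TOTAL, cool, NIR, cool, VIS, cool."""
    if initial_cool_s is None:
        initial_cool_s = phase_s
    labels = ["COOL", "TOTAL", "COOL", "NIR", "COOL", "VIS", "COOL"]
    durations = [initial_cool_s] + [phase_s] * 6
    phases, t = [], start_s
    for lab, dur in zip(labels, durations):
        phases.append(Phase(lab, t, t + dur))
        t += dur
    return TrialPlan(tuple(phases))


def segment_trial(
    trace: ThermalTrace, plan: TrialPlan
) -> list[tuple[Phase, ThermalTrace]]:
    """Slice a trace by the trial plan.

    A sample on a shared phase boundary is assigned to the later phase; each
    slice is additionally padded with the first sample at or beyond its end
    boundary (when one exists) so that interpolation at onset + 300 s is
    always possible.

    Raises
    ------
    ValueError
        If the plan extends beyond the trace, or an illumination phase
        captures fewer than two samples.
    """
    t = trace.times_s
    lo, hi = plan.span
    if lo < t[0] or hi > t[-1]:
        raise ValueError(
            f"plan span [{lo}, {hi}] s exceeds trace span [{t[0]}, {t[-1]}] s"
        )
    out: list[tuple[Phase, ThermalTrace]] = []
    for phase in plan.phases:
        i0 = int(np.searchsorted(t, phase.start_s, side="left"))
        i1 = int(np.searchsorted(t, phase.end_s, side="left"))
        # pad with the bracketing sample at/after the end boundary
        i1_pad = min(i1 + 1, t.size)
        n_members = i1 - i0
        if n_members < 2:
            raise ValueError(
                f"phase {phase.label} [{phase.start_s}, {phase.end_s}) s "
                f"contains {n_members} samples; need at least 2"
            )
        out.append(
            (phase, ThermalTrace(t[i0:i1_pad], trace.temps_C[i0:i1_pad], trace.channel))
        )
    return out


def _value_at(slice_: ThermalTrace, t_target: float, tol_s: float = 1.0) -> float:
    """Temperature at t_target: the sample within ±tol_s if one exists,
    else linear interpolation from bracketing samples."""
    t, T = slice_.times_s, slice_.temps_C
    j = int(np.argmin(np.abs(t - t_target)))
    if abs(t[j] - t_target) <= tol_s:
        return float(T[j])
    if t_target < t[0] or t_target > t[-1]:
        raise ValueError(
            f"target time {t_target} s outside slice span [{t[0]}, {t[-1]}] s"
        )
    return float(np.interp(t_target, t, T))


def delta_t5(slice_: ThermalTrace, window_s: float = 300.0) -> float:
    """Temperature change over the first ``window_s`` (default 5 min) of a phase.

    Onset is the slice's first sample; the value at onset + window is taken
    from the sample within ±1 s of that time, or linearly interpolated from
    the bracketing samples otherwise.
    """
    if len(slice_) < 2:
        raise ValueError("need at least two samples")
    onset_t = slice_.times_s[0]
    target = onset_t + window_s
    if slice_.times_s[-1] < target - 1.0:
        raise ValueError(
            f"slice spans {slice_.times_s[-1] - onset_t:.0f} s from onset; "
            f"{window_s:.0f} s required"
        )
    return _value_at(slice_, target) - float(slice_.temps_C[0])


def max_heating_rate(slice_: ThermalTrace) -> float:
    """Maximum slope between adjacent samples, in °C/s.

    Uses the actual timestamp gap of each pair.  Ties go to the earliest
    pair.  The maximum is returned even when negative (a cooling trace).
    """
    rate, _ = max_heating_rate_with_time(slice_)
    return rate


def max_heating_rate_with_time(slice_: ThermalTrace) -> tuple[float, float]:
    """As :func:`max_heating_rate`, also returning the left timestamp of the
    winning pair."""
    if len(slice_) < 2:
        raise ValueError("need at least two samples to compute a slope")
    dt = np.diff(slice_.times_s)
    slopes = np.diff(slice_.temps_C) / dt
    j = int(np.argmax(slopes))  # argmax returns the earliest maximal index
    return float(slopes[j]), float(slice_.times_s[j])


@dataclass(frozen=True)
class HeatingMetrics:
    """Per-phase heating summary."""

    phase_label: str
    delta_t5_C: float
    max_hr_C_per_s: float
    onset_temp_C: float


def compute_heating_metrics(
    phase: Phase, slice_: ThermalTrace, window_s: float = 300.0
) -> HeatingMetrics:
    return HeatingMetrics(
        phase_label=phase.label,
        delta_t5_C=delta_t5(slice_, window_s=window_s),
        max_hr_C_per_s=max_heating_rate(slice_),
        onset_temp_C=float(slice_.temps_C[0]),
    )


def read_trace(path: str | Path, channel: str | None = None) -> ThermalTrace:
    """Read a CSV trace with columns (time_s, temp_C[, channel])."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_s" not in cols or "temp_c" not in cols:
        raise ValueError(f"{path}: expected columns time_s and temp_C, got {list(df.columns)}")
    if channel is not None and "channel" in cols:
        df = df[df[cols["channel"]] == channel]
    chan = channel or (str(df[cols["channel"]].iloc[0]) if "channel" in cols else "T1")
    df = df.sort_values(cols["time_s"], kind="stable")
    return ThermalTrace(
        df[cols["time_s"]].to_numpy(float), df[cols["temp_c"]].to_numpy(float), chan
    )


def read_plan(path: str | Path) -> TrialPlan:
    """Read a trial plan from YAML/JSON: a list of {label, start_s, end_s}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    items = raw["phases"] if isinstance(raw, dict) else raw
    return TrialPlan(tuple(Phase(p["label"], float(p["start_s"]), float(p["end_s"])) for p in items))


def write_plan(plan: TrialPlan, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "phases": [
                    {"label": p.label, "start_s": p.start_s, "end_s": p.end_s}
                    for p in plan.phases
                ]
            },
            fh,
            sort_keys=False,
        )


def check_reference_channel(trace: ThermalTrace, max_drift_C: float = 0.5) -> list[str]:
    """QC for chamber/water channels, which should stay constant in a trial.

    Returns a list of warning strings (empty when within tolerance).
    """
    drift = float(np.ptp(trace.temps_C))
    if drift > max_drift_C:
        return [
            f"reference channel {trace.channel!r} drifted {drift:.2f} C "
            f"(tolerance {max_drift_C} C)"
        ]
    return []
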