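"""Threshold alarms with per-vital validation times and advisory reassessment.

A patient monitor raises a threshold alarm when the measurements of a vital
sign stay strictly outside a configured limit for at least the vital- and
direction-specific *validation time* (e.g. blood pressure must violate for
4 consecutive seconds; a single heart-rate value below the lower limit
alarms immediately).  Runs of violating seconds are bridged across a single
missing second; two or more consecutive missing seconds end the run.  No
alarm onset is placed inside an "alarms off" period (stretches during which
staff deactivated the monitor's alarms).

Advisory alarms (technically true but not requiring immediate action) are
reassessed as true or false from the *alarm length* -- the time the
measurements stay outside the limit: short violations are considered
clinically irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AlarmLimits",
    "AlarmEvent",
    "AlarmsOffPeriod",
    "threshold_alarms",
    "alarm_length",
    "reassess_advisory",
    "DEFAULT_VALIDATION_TIMES",
    "DEFAULT_ADVISORY_THRESHOLDS",
]

# vital -> (upper-limit validation seconds, lower-limit validation seconds);
# "immediately" = 1 sample at 1 Hz
DEFAULT_VALIDATION_TIMES: dict[str, tuple[int, int]] = {
    "HR": (2, 1),
    "PULSE": (2, 1),
    "ART.S": (4, 4),
    "ART.M": (4, 4),
    "ART.D": (4, 4),
    "SpO2": (4, 10),
}

# advisory alarms shorter than these lengths (seconds, strict) are irrelevant
DEFAULT_ADVISORY_THRESHOLDS: dict[str, int] = {
    "ART.S": 10,
    "ART.M": 10,
    "ART.D": 10,
    "HR": 5,
    "PULSE": 5,
    "SpO2": 15,
}


@dataclass(frozen=True)
class AlarmsOffPeriod:
    """Closed interval of seconds during which the monitor raises no alarms."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("alarms-off period must have start <= end")

    def __contains__(self, t: int) -> bool:
        return self.start <= t <= self.end


@dataclass
class AlarmLimits:
    """Per-vital alarm limits and validation times.

    ``limits`` maps vital name -> (lower, upper) in measurement units;
    ``validation`` maps vital name -> (upper seconds, lower seconds), with
    validation time counted in consecutive violating seconds including the
    onset second.  Values exactly on a limit do not violate it.
    """

    limits: dict[str, tuple[float, float]]
    validation: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for vital, (lo, hi) in self.limits.items():
            if not lo < hi:
                raise ValueError(f"{vital}: lower limit must be below upper limit")
        for vital in self.limits:
            self.validation.setdefault(
                vital, DEFAULT_VALIDATION_TIMES.get(vital, (1, 1))
            )
        for vital, (up, lo) in self.validation.items():
            if up < 0 or lo < 0:
                raise ValueError(f"{vital}: validation times must be >= 0")

    def validation_samples(self, vital: str, direction: str) -> int:
        up, lo = self.validation[vital]
        v = up if direction == "upper" else lo
        return max(1, int(v))  # validation time 0 alarms at the first sample

    def violates(self, vital: str, values, direction: str | None = None) -> np.ndarray:
        """Boolean mask of strict limit violations; NaN never violates."""
        lo, hi = self.limits[vital]
        v = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            upper = v > hi
            lower = v < lo
        if direction == "upper":
            return upper
        if direction == "lower":
            return lower
        return upper | lower


@dataclass(frozen=True)
class AlarmEvent:
    """One threshold alarm.

    ``time`` is the onset second (the second the violation run first meets
    the validation time); ``length`` is the duration in seconds of the
    maximal violation run containing the onset; ``label`` is the annotation
    (true / false / advisory).
    """

    time: int
    vital: str
    direction: str  # "upper" | "lower"
    length: int
    label: str = "unlabelled"

    def __post_init__(self):
        if self.direction not in ("upper", "lower"):
            raise ValueError("direction must be 'upper' or 'lower'")
        if self.length < 1:
            raise ValueError("alarm length must be >= 1 second")


def _violation_runs(violates: np.ndarray, observed: np.ndarray) -> list[tuple[int, int]]:
    """Maximal violation runs as (start, end) index pairs.

    A single interior missing second is bridged when both neighbouring
    observed seconds violate; >= 2 consecutive missing seconds end the run.
    """
    runs: list[tuple[int, int]] = []
    T = violates.size
    t = 0
    while t < T:
        if not (observed[t] and violates[t]):
            t += 1
            continue
        start = t
        end = t
        j = t + 1
        while j < T:
            if observed[j] and violates[j]:
                end = j
                j += 1
            elif (not observed[j]) and j + 1 < T and observed[j + 1] and violates[j + 1]:
                end = j + 1  # bridge one missing second
                j += 2
            else:
                break
        runs.append((start, end))
        t = j
    return runs


def threshold_alarms(series: pd.DataFrame, limits: AlarmLimits,
                     off: list[AlarmsOffPeriod] | None = None) -> list[AlarmEvent]:
    """Generate threshold alarms from a regularly sampled 1 Hz series.

    Each maximal violation run produces at most one alarm, at the second
    its duration first reaches the validation time for that vital and
    direction.  Runs whose onset falls inside an alarms-off period produce
    no event.

    Parameters
    ----------
    series : pandas.DataFrame
        Index = integer seconds, one column per vital, NaN missing.
    limits : AlarmLimits
    off : list of AlarmsOffPeriod, optional

    Returns
    -------
    list of AlarmEvent, sorted by (time, vital).
    """
    off = off or []
    times = np.asarray(series.index)
    events: list[AlarmEvent] = []
    for vital in series.columns:
        if vital not in limits.limits:
            raise KeyError(f"no alarm limits configured for vital {vital!r}")
        values = series[vital].to_numpy(dtype=float)
        observed = np.isfinite(values)
        for direction in ("upper", "lower"):
            viol = limits.violates(vital, values, direction)
            need = limits.validation_samples(vital, direction)
            for start, end in _violation_runs(viol, observed):
                run_len = end - start + 1
                if run_len < need:
                    continue
                onset = int(times[start + need - 1])
                if any(onset in p for p in off):
                    continue
                events.append(AlarmEvent(
                    time=onset, vital=vital, direction=direction, length=run_len,
                ))
    events.sort(key=lambda e: (e.time, e.vital, e.direction))
    return events


def alarm_length(series: pd.DataFrame, limits: AlarmLimits, event: AlarmEvent) -> int:
    """Length in seconds of the maximal violation run containing the onset."""
    values = series[event.vital].to_numpy(dtype=float)
    observed = np.isfinite(values)
    viol = limits.violates(event.vital, values, event.direction)
    times = np.asarray(series.index)
    pos = int(np.searchsorted(times, event.time))
    for start, end in _violation_runs(viol, observed):
        if start <= pos <= end:
            return end - start + 1
    raise ValueError(
        f"alarm onset t={event.time} ({event.vital}, {event.direction}) "
        "does not lie inside a violation run of this series"
    )


def reassess_advisory(events: list[AlarmEvent],
                      thresholds: dict[str, int] | None = None) -> list[AlarmEvent]:
    """Relabel advisory alarms as true or false by their alarm length.

    An advisory alarm shorter (strictly) than the vital-specific threshold
    is considered clinically irrelevant and relabelled false; otherwise it
    becomes true.  True and false labels pass through unchanged, so the
    operation is idempotent.
    """
    thr = thresholds if thresholds is not None else DEFAULT_ADVISORY_THRESHOLDS
    out: list[AlarmEvent] = []
    for e in events:
        if e.label != "advisory":
            out.append(e)
            continue
        if e.vital not in thr:
            raise KeyError(f"no advisory-length threshold for vital {e.vital!r}")
        label = "false" if e.length < thr[e.vital] else "true"
        out.append(AlarmEvent(e.time, e.vital, e.direction, e.length, label))
    return out
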