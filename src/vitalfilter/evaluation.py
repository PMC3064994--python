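"""Interval-based scoring of a filter-driven alarm system.

Annotated alarms of the existing ("old") monitor are the reference: every
true alarm at time ``t`` opens a detection interval ``{t, ..., t + D}`` and
every false alarm a suppression interval ``{t, ..., t + S}`` (closed, whole
seconds).  A true alarm is *detected* when the filtered estimates violate
the alarm limit somewhere inside its interval; a false alarm is *suppressed*
when they violate no limit of that vital anywhere inside its interval.
False alarms whose intervals overlap a true-alarm interval of the same
vital are excluded, because detection takes precedence over suppression.

  SE   = detected true alarms / all true alarms
  FARR = suppressed false alarms / all (non-excluded) false alarms

The suppression tolerance ``S`` must exceed the filter's tracing delay
(about ``n_min / 2`` seconds), otherwise late limit violations of the
estimates would be missed and suppression overstated.  The identity filter
(estimates = raw measurements) reproduces the old system: SE = 1, FARR = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alarm_system import AlarmEvent, AlarmLimits, AlarmsOffPeriod
from .aorm import FilterParams, aorm_filter
from .aotrmls import aotrmls_filter

__all__ = [
    "IntervalConfig",
    "EvaluationResult",
    "build_intervals",
    "exclude_overlaps",
    "score_filter",
    "specificity_estimate",
    "false_share",
    "sweep_nmin",
]

#: detection tolerance D in seconds: 60 for pressures and SpO2, 30 for HR
DEFAULT_DETECTION_TOLERANCE: dict[str, int] = {
    "ART.S": 60, "ART.M": 60, "ART.D": 60, "SpO2": 60, "HR": 30, "PULSE": 30,
}


@dataclass(frozen=True)
class IntervalConfig:
    """Alarm-interval scoring configuration.

    Attributes
    ----------
    detection_tolerance : dict
        Per-vital detection tolerance D (seconds after a true alarm).
    suppression_tolerance : int
        Suppression tolerance S (seconds after a false alarm); must exceed
        the filter's tracing delay.
    direction_match : bool
        If True (default), detection requires the estimates to violate the
        same limit direction as the annotated alarm.  Suppression is always
        direction-agnostic.
    alarms_off_mode : str
        "report": estimate violations inside alarms-off periods do not void
        suppression but are counted separately; "strict": they count
        against suppression.
    """

    detection_tolerance: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_TOLERANCE))
    suppression_tolerance: int = 60
    direction_match: bool = True
    alarms_off_mode: str = "report"

    def __post_init__(self):
        if self.suppression_tolerance <= 0:
            raise ValueError("suppression tolerance S must be positive")
        if any(v <= 0 for v in self.detection_tolerance.values()):
            raise ValueError("detection tolerances D must be positive")
        if self.alarms_off_mode not in ("report", "strict"):
            raise ValueError("alarms_off_mode must be 'report' or 'strict'")

    def D(self, vital: str) -> int:
        return int(self.detection_tolerance.get(vital, 60))


@dataclass(frozen=True)
class Interval:
    """Closed interval of whole seconds attached to one alarm event."""

    start: int
    end: int
    event: AlarmEvent

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class EvaluationResult:
    """SE / FARR scores of one filter configuration."""

    SE: float
    FARR: float
    M: int                      # true alarms
    N: int                      # false alarms after overlap exclusion
    detected: int
    suppressed: int
    excluded_false: int
    per_vital: dict[str, dict[str, float]] = field(default_factory=dict)
    off_period_violations: int = 0

    def to_dict(self) -> dict:
        return {
            "SE": self.SE, "FARR": self.FARR, "M": self.M, "N": self.N,
            "detected": self.detected, "suppressed": self.suppressed,
            "excluded_false": self.excluded_false,
            "off_period_violations": self.off_period_violations,
            "per_vital": self.per_vital,
        }


def build_intervals(events: list[AlarmEvent], cfg: IntervalConfig,
                    series_end: int | None = None
                    ) -> tuple[list[Interval], list[Interval]]:
    """True- and false-alarm intervals for labelled events.

    A true alarm at ``t`` gives ``{t, ..., t + D(vital)}``; a false alarm
    ``{t, ..., t + S}``.  Intervals are clipped at the series end.  Events
    still labelled advisory must be reassessed first.
    """
    true_iv: list[Interval] = []
    false_iv: list[Interval] = []
    for e in events:
        if e.label == "true":
            end = e.time + cfg.D(e.vital)
        elif e.label == "false":
            end = e.time + cfg.suppression_tolerance
        else:
            raise ValueError(
                f"event at t={e.time} has label {e.label!r}; reassess advisory "
                "alarms before building intervals")
        if series_end is not None:
            end = min(end, series_end)
        iv = Interval(e.time, end, e)
        (true_iv if e.label == "true" else false_iv).append(iv)
    return true_iv, false_iv


def exclude_overlaps(false_intervals: list[Interval],
                     true_intervals: list[Interval]
                     ) -> tuple[list[Interval], int]:
    """Drop false intervals sharing >= 1 second with a same-vital true interval.

    Detection of true alarms is never affected; only the FARR denominator
    shrinks.
    """
    kept: list[Interval] = []
    excluded = 0
    for f in false_intervals:
        if any(f.overlaps(t) for t in true_intervals
               if t.event.vital == f.event.vital):
            excluded += 1
        else:
            kept.append(f)
    return kept, excluded


def _slice(mask: np.ndarray, times: np.ndarray, start: int, end: int) -> np.ndarray:
    lo = int(np.searchsorted(times, start, side="left"))
    hi = int(np.searchsorted(times, end, side="right"))
    return mask[lo:hi]


def score_filter(estimates: pd.DataFrame, raw: pd.DataFrame,
                 events: list[AlarmEvent], limits: AlarmLimits,
                 cfg: IntervalConfig | None = None,
                 off: list[AlarmsOffPeriod] | None = None) -> EvaluationResult:
    """Score filtered estimates against annotated alarms of the raw series.

    Parameters
    ----------
    estimates : pandas.DataFrame
        Filter output, aligned 1:1 with ``raw`` (same index and columns for
        the scored vitals); missing estimate seconds count as
        non-violating.
    raw : pandas.DataFrame
        The raw measurement series the events come from.
    events : list of AlarmEvent
        Labelled true/false (advisory already reassessed).
    limits : AlarmLimits
    cfg : IntervalConfig
    off : list of AlarmsOffPeriod, optional
        Used by the alarms-off scoring mode.
    """
    cfg = cfg or IntervalConfig()
    off = off or []
    if len(estimates) != len(raw):
        raise ValueError("estimates and raw series must have equal length")
    times = np.asarray(raw.index)
    series_end = int(times[-1]) if len(times) else 0

    off_mask = np.zeros(len(times), dtype=bool)
    for p in off:
        off_mask |= (times >= p.start) & (times <= p.end)

    true_iv, false_iv = build_intervals(events, cfg, series_end=series_end)
    kept_false, excluded = exclude_overlaps(false_iv, true_iv)

    viol: dict[tuple[str, str], np.ndarray] = {}
    for vital in {e.event.vital for e in true_iv + kept_false}:
        v = estimates[vital].to_numpy(dtype=float)
        for direction in ("upper", "lower"):
            viol[(vital, direction)] = limits.violates(vital, v, direction)

    detected = 0
    off_violations = 0
    per_vital: dict[str, dict[str, float]] = {}

    def _pv(vital: str) -> dict[str, float]:
        return per_vital.setdefault(
            vital, {"M": 0, "N": 0, "detected": 0, "suppressed": 0, "excluded": 0})

    for iv in true_iv:
        pv = _pv(iv.event.vital)
        pv["M"] += 1
        if cfg.direction_match:
            mask = viol[(iv.event.vital, iv.event.direction)]
        else:
            mask = viol[(iv.event.vital, "upper")] | viol[(iv.event.vital, "lower")]
        if _slice(mask, times, iv.start, iv.end).any():
            detected += 1
            pv["detected"] += 1

    suppressed = 0
    for iv in kept_false:
        pv = _pv(iv.event.vital)
        pv["N"] += 1
        mask = viol[(iv.event.vital, "upper")] | viol[(iv.event.vital, "lower")]
        hit = _slice(mask, times, iv.start, iv.end)
        hit_off = _slice(mask & off_mask, times, iv.start, iv.end)
        n_off = int(hit_off.sum())
        if cfg.alarms_off_mode == "report":
            off_violations += n_off
            any_hit = bool((hit & ~_slice(off_mask, times, iv.start, iv.end)).any())
        else:
            any_hit = bool(hit.any())
        if not any_hit:
            suppressed += 1
            pv["suppressed"] += 1

    for f in false_iv:
        if f not in kept_false:
            _pv(f.event.vital)["excluded"] += 1

    M = len(true_iv)
    N = len(kept_false)
    for vital, pv in per_vital.items():
        pv["SE"] = pv["detected"] / pv["M"] if pv["M"] else float("nan")
        pv["FARR"] = pv["suppressed"] / pv["N"] if pv["N"] else float("nan")

    return EvaluationResult(
        SE=detected / M if M else float("nan"),
        FARR=suppressed / N if N else float("nan"),
        M=M, N=N, detected=detected, suppressed=suppressed,
        excluded_false=excluded, per_vital=per_vital,
        off_period_violations=off_violations,
    )


def specificity_estimate(FP: int, FP_max: int) -> float:
    """Alternative specificity estimate from false-positive counts.

    ``(FP_max - FP) / FP_max`` when ``FP <= FP_max``, else 0, where
    ``FP_max`` is the highest expected number of false positives.  Always
    lies in [0, 1].
    """
    if FP_max <= 0:
        raise ValueError("FP_max must be positive")
    if FP < 0:
        raise ValueError("FP must be non-negative")
    if FP > FP_max:
        return 0.0
    return (FP_max - FP) / FP_max


def false_share(n_true: int, n_false: int) -> float:
    """Share of false alarms among all true + false alarms, in [0, 1]."""
    total = n_true + n_false
    if total <= 0:
        raise ValueError("need at least one alarm")
    return n_false / total


def sweep_nmin(series: pd.DataFrame, events: list[AlarmEvent],
               limits: AlarmLimits, cfg: IntervalConfig | None = None,
               grid=(10, 20, 30, 40, 50, 60, 70, 80, 90),
               filter_kind: str = "aorm", n_max: int = 300,
               blocks=None, off=None) -> pd.DataFrame:
    """Score a filter over a grid of minimum window widths.

    For each ``n_min`` in the grid the filter is run with ``m = n_min // 2``
    and ``n_max = 300`` (the study protocol) and scored; the returned table
    (one row per grid point and vital, plus an ``overall`` row) supports the
    FARR-versus-SE trade-off plot: larger ``n_min`` suppresses more false
    alarms at the cost of slower tracing of genuine changes.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("n_min grid must be non-empty")
    if filter_kind not in ("aorm", "aotrmls"):
        raise ValueError("filter_kind must be 'aorm' or 'aotrmls'")
    rows = []
    for n_min in grid:
        params = FilterParams(n_min=n_min, n_max=n_max, m=max(1, n_min // 2))
        if filter_kind == "aorm":
            est = series.apply(
                lambda col: aorm_filter(col.to_numpy(dtype=float), params))
        else:
            est = aotrmls_filter(series, blocks=blocks, params=params)
        result = score_filter(est, series, events, limits, cfg, off=off)
        rows.append({"n_min": n_min, "vital": "overall",
                     "SE": result.SE, "FARR": result.FARR,
                     "M": result.M, "N": result.N})
        for vital, pv in result.per_vital.items():
            rows.append({"n_min": n_min, "vital": vital, "SE": pv["SE"],
                         "FARR": pv["FARR"], "M": pv["M"], "N": pv["N"]})
    return pd.DataFrame(rows)
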