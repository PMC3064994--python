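"""Synthetic annotated vital-sign scenarios.

Real annotated ICU monitoring data are not redistributable, so the test
bench generates 1 Hz multivariate series with the structure assumed by the
filters: a piecewise-linear signal per vital (level shifts, trends), additive
zero-median noise with per-vital scale and within-block cross-correlation,
and an impulsive outlier mechanism producing short artefact patches, plus
missing-value gaps and alarms-off periods.  Every injected structure is
recorded in a ground-truth object, and alarms raised on the raw series are
labelled true / false / advisory by matching them to the injected events --
a stand-in for retrospective physician annotation.

All randomness flows from a single scenario seed through named substreams
(noise, outliers, gaps), so individual components can be toggled without
changing the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alarm_system import (
    AlarmEvent,
    AlarmLimits,
    AlarmsOffPeriod,
    threshold_alarms,
)

__all__ = [
    "Segment",
    "TruthEvent",
    "SpikeSpec",
    "ScenarioConfig",
    "GroundTruth",
    "generate_scenario",
    "annotate_scenario",
    "example_scenario",
]


@dataclass(frozen=True)
class Segment:
    """One piecewise-linear signal segment: level + slope * (t - start)."""

    start: int
    end: int  # exclusive
    level: float
    slope: float = 0.0


@dataclass(frozen=True)
class TruthEvent:
    """An intended alarm-relevant structure injected into the scenario.

    kind: 'relevant_shift' (sustained excursion beyond a limit -> true
    alarm), 'artefact' (short outlier patch -> false alarm), or
    'advisory_drift' (moderate excursion annotated advisory).
    """

    time: int
    vital: str
    kind: str
    duration: int
    direction: str  # "upper" | "lower"


@dataclass(frozen=True)
class SpikeSpec:
    """Random artefact-patch mechanism for one vital.

    ``n_patches`` patches with lengths uniform in ``length_range`` and
    additive magnitudes uniform in ``magnitude_range`` (signed; negative for
    downward spikes) are placed uniformly in the allowed quiet zones with at
    least ``min_separation`` seconds between patch starts.
    """

    n_patches: int
    magnitude_range: tuple[float, float]
    length_range: tuple[int, int]
    min_separation: int = 90


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic monitoring scenario."""

    duration: int
    variables: list[str]
    segments: dict[str, list[Segment]]
    noise_sigma: dict[str, float]
    correlation: dict[tuple[str, ...], np.ndarray] = field(default_factory=dict)
    spikes: dict[str, SpikeSpec] = field(default_factory=dict)
    events: list[TruthEvent] = field(default_factory=list)
    limits: AlarmLimits | None = None
    off_periods: list[AlarmsOffPeriod] = field(default_factory=list)
    missing_gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    heavy_tail_df: float | None = None  # scaled-t noise for robustness tests
    seed: int = 0

    def __post_init__(self):
        for members, R in self.correlation.items():
            R = np.asarray(R, dtype=float)
            if not np.allclose(R, R.T) or np.any(np.linalg.eigvalsh(R) <= 0):
                raise ValueError(
                    f"correlation matrix for block {members} must be "
                    "symmetric positive definite")


@dataclass
class GroundTruth:
    """Everything the generator injected, for use as a test oracle."""

    clean: pd.DataFrame
    outlier_mask: pd.DataFrame
    events: list[TruthEvent]


def _signal(cfg: ScenarioConfig, vital: str) -> np.ndarray:
    out = np.full(cfg.duration, np.nan)
    for seg in cfg.segments[vital]:
        t = np.arange(seg.start, min(seg.end, cfg.duration))
        out[t] = seg.level + seg.slope * (t - seg.start)
    if np.any(np.isnan(out)):
        raise ValueError(f"segments for {vital!r} do not cover the full duration")
    return out


def _noise(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    T = cfg.duration
    noise = pd.DataFrame(0.0, index=range(T), columns=cfg.variables)
    covered: set[str] = set()
    for members, R in cfg.correlation.items():
        R = np.asarray(R, dtype=float)
        L = np.linalg.cholesky(R)
        Z = _draw(rng, (T, len(members)), cfg.heavy_tail_df)
        corr = Z @ L.T
        for j, v in enumerate(members):
            noise[v] = corr[:, j] * cfg.noise_sigma[v]
            covered.add(v)
    for v in cfg.variables:
        if v not in covered:
            noise[v] = _draw(rng, (T,), cfg.heavy_tail_df) * cfg.noise_sigma[v]
    return noise


def _draw(rng: np.random.Generator, shape, df: float | None) -> np.ndarray:
    if df is None:
        return rng.standard_normal(shape)
    # scaled t: unit variance, heavy tails, still zero median
    return rng.standard_t(df, size=shape) / np.sqrt(df / (df - 2.0))


def _place_patches(cfg: ScenarioConfig, vital: str, spec: SpikeSpec,
                   rng: np.random.Generator) -> list[tuple[int, int, float]]:
    """(start, length, magnitude) triples inside quiet zones.

    Quiet zones keep artefacts clear of injected relevant/advisory events so
    that false-alarm intervals do not overlap true-alarm intervals.
    """
    guard = 130  # > suppression tolerance S = 60 plus detection D = 60
    blocked = np.zeros(cfg.duration, dtype=bool)
    blocked[: max(100, guard)] = True  # leave room for filter initialization
    blocked[-guard:] = True
    for e in cfg.events:
        # only same-vital events matter: overlap exclusion is per vital
        if e.vital == vital and e.kind in ("relevant_shift", "advisory_drift"):
            lo = max(0, e.time - guard)
            hi = min(cfg.duration, e.time + e.duration + guard)
            blocked[lo:hi] = True
    patches: list[tuple[int, int, float]] = []
    candidates = np.flatnonzero(~blocked)
    for _ in range(spec.n_patches):
        if candidates.size == 0:
            break
        start = int(rng.choice(candidates))
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        mag = float(rng.uniform(*spec.magnitude_range))
        patches.append((start, length, mag))
        lo = start - spec.min_separation
        hi = start + length + spec.min_separation
        candidates = candidates[(candidates < lo) | (candidates >= hi)]
    return sorted(patches)


def generate_scenario(cfg: ScenarioConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one annotated scenario: series = signal + noise + outliers.

    Deterministic per seed; returns the observed series and the ground
    truth (clean signal, outlier mask, injected event list).
    """
    root = np.random.SeedSequence(cfg.seed)
    rng_noise, rng_out, rng_gaps = (
        np.random.default_rng(s) for s in root.spawn(3))

    T = cfg.duration
    index = pd.RangeIndex(T, name="time")
    clean = pd.DataFrame(
        {v: _signal(cfg, v) for v in cfg.variables}, index=index)
    series = clean + _noise(cfg, rng_noise).to_numpy()
    mask = pd.DataFrame(False, index=index, columns=cfg.variables)

    events = list(cfg.events)
    for vital in cfg.variables:
        spec = cfg.spikes.get(vital)
        if spec is None:
            continue
        for start, length, mag in _place_patches(cfg, vital, spec, rng_out):
            end = min(T, start + length)
            series.loc[start:end - 1, vital] += mag
            mask.loc[start:end - 1, vital] = True
            events.append(TruthEvent(
                time=start, vital=vital, kind="artefact", duration=end - start,
                direction="upper" if mag > 0 else "lower"))

    for vital, gaps in cfg.missing_gaps.items():
        for lo, hi in gaps:
            series.loc[lo:hi, vital] = np.nan

    events.sort(key=lambda e: (e.time, e.vital))
    return series, GroundTruth(clean=clean, outlier_mask=mask, events=events)


def annotate_scenario(series: pd.DataFrame, truth: GroundTruth,
                      limits: AlarmLimits,
                      off: list[AlarmsOffPeriod] | None = None,
                      match_tolerance: int = 30) -> list[AlarmEvent]:
    """Label raw-series threshold alarms from the ground truth.

    Each alarm is matched to the nearest injected event of the same vital
    whose active span (padded by ``match_tolerance`` seconds) contains the
    alarm onset: relevant shifts give true, artefacts false, advisory
    drifts advisory labels.  Unmatched alarms are labelled false.
    """
    kind_to_label = {
        "relevant_shift": "true",
        "artefact": "false",
        "advisory_drift": "advisory",
    }
    alarms = threshold_alarms(series, limits, off=off)
    labelled: list[AlarmEvent] = []
    for a in alarms:
        best: TruthEvent | None = None
        best_dist = None
        for e in truth.events:
            if e.vital != a.vital:
                continue
            lo, hi = e.time - match_tolerance, e.time + e.duration + match_tolerance
            if lo <= a.time <= hi:
                dist = abs(a.time - e.time)
                if best is None or dist < best_dist:
                    best, best_dist = e, dist
        label = kind_to_label[best.kind] if best is not None else "false"
        labelled.append(AlarmEvent(a.time, a.vital, a.direction, a.length, label))
    return labelled


def example_scenario(seed: int = 0, duration: int = 900):
    """A canonical annotated ICU scenario exercising the whole pipeline.

    Four vitals at 1 Hz for 15 minutes: systolic and mean arterial pressure
    (correlated block), heart rate, and oxygen saturation.  Injected
    structures:

    * a sustained correlated hypotensive shift in both pressures (true),
    * a sustained tachycardic shift in heart rate (true),
    * a sustained oxygen desaturation (true),
    * a 12 s advisory drift in mean pressure (reassessed true: >= 10 s),
    * a 12 s advisory dip in SpO2 (reassessed false: < 15 s),
    * short artefact patches crossing the limits in every vital (false).

    Returns ``(series, truth, limits, off_periods, config)``.
    """
    variables = ["ART.S", "ART.M", "HR", "SpO2"]
    segments = {
        "ART.S": [Segment(0, 320, 120.0), Segment(320, 440, 75.0),
                  Segment(440, duration, 120.0)],
        "ART.M": [Segment(0, 320, 82.0), Segment(320, 440, 50.0),
                  Segment(440, 560, 82.0), Segment(560, 572, 120.0),
                  Segment(572, duration, 82.0)],
        "HR": [Segment(0, 150, 80.0), Segment(150, 250, 135.0),
               Segment(250, duration, 80.0)],
        "SpO2": [Segment(0, 600, 97.0), Segment(600, 612, 87.0),
                 Segment(612, 700, 97.0), Segment(700, 800, 85.0),
                 Segment(800, duration, 97.0)],
    }
    events = [
        TruthEvent(320, "ART.S", "relevant_shift", 120, "lower"),
        TruthEvent(320, "ART.M", "relevant_shift", 120, "lower"),
        TruthEvent(150, "HR", "relevant_shift", 100, "upper"),
        TruthEvent(560, "ART.M", "advisory_drift", 12, "upper"),
        TruthEvent(600, "SpO2", "advisory_drift", 12, "lower"),
        TruthEvent(700, "SpO2", "relevant_shift", 100, "lower"),
    ]
    spikes = {
        "ART.S": SpikeSpec(3, (48.0, 65.0), (4, 8)),
        "ART.M": SpikeSpec(2, (-45.0, -30.0), (4, 8)),
        "HR": SpikeSpec(3, (-55.0, -35.0), (2, 6)),
        "SpO2": SpikeSpec(3, (-14.0, -10.0), (10, 14)),
    }
    limits = AlarmLimits(limits={
        "ART.S": (90.0, 160.0),
        "ART.M": (60.0, 110.0),
        "HR": (50.0, 120.0),
        "SpO2": (90.0, 104.0),
    })
    cfg = ScenarioConfig(
        duration=duration,
        variables=variables,
        segments=segments,
        noise_sigma={"ART.S": 2.0, "ART.M": 1.5, "HR": 1.0, "SpO2": 0.4},
        correlation={("ART.S", "ART.M"): np.array([[1.0, 0.7], [0.7, 1.0]])},
        spikes=spikes,
        events=events,
        limits=limits,
        missing_gaps={"HR": [(640, 645)]},
        seed=seed,
    )
    series, truth = generate_scenario(cfg)
    return series, truth, limits, list(cfg.off_periods), cfg
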