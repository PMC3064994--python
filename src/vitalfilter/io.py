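"""CSV / YAML readers and writers for series, events, and configuration.

Series files are delimited text with a header row: a ``time`` column of
integer seconds plus one column per vital sign; missing values are empty
fields or ``NA``.  On load the series is rebuilt on a regular 1 Hz grid, so
gaps in the time column materialize as missing rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alarm_system import AlarmEvent, AlarmLimits, AlarmsOffPeriod
from .aorm import FilterParams
from .aotrmls import CorrelationBlock

__all__ = [
    "read_series", "write_series",
    "read_events", "write_events",
    "read_off_periods", "write_off_periods",
    "load_config",
]

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "NA", "NaN", "nan"}


def read_series(path, time_column: str = "time") -> pd.DataFrame:
    """Load a 1 Hz series file onto a regular integer-second grid.

    Gaps in the time column become missing rows, so the returned frame has
    one row per second over the file's time span.  Raises on non-monotone
    time or unparseable values (with the offending line).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, na_values=list(_NA_TOKENS), keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        logger.warning("read_series: %s is empty", path)
        return pd.DataFrame(
            index=pd.RangeIndex(0, name=time_column)).rename_axis(time_column)
    if time_column not in df.columns:
        raise ValueError(f"{path}: missing required time column {time_column!r}")
    t = df[time_column].to_numpy()
    try:
        t = t.astype(np.int64)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-integer time values: {err}") from None
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2  # +1 header, +1 next row
        raise ValueError(f"{path}: time column not strictly increasing at line {bad}")
    for col in df.columns:
        if col == time_column:
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"{path}: unparseable value in column {col!r} at line {line}"
            ) from None
    df = df.set_index(time_column)
    df.index = t
    full = pd.RangeIndex(t[0], t[-1] + 1, name=time_column)
    return df.reindex(full).astype(float)


def write_series(df: pd.DataFrame, path, time_column: str = "time") -> None:
    """Write a series frame with ``NA`` for missing values (round-trip safe)."""
    out = df.copy()
    out.index.name = time_column
    out.to_csv(path, na_rep="NA")


def read_events(path) -> list[AlarmEvent]:
    """Load alarm annotations: columns time, vital, direction, length, label."""
    df = pd.read_csv(path)
    return [
        AlarmEvent(int(r.time), str(r.vital), str(r.direction),
                   int(r.length), str(r.label))
        for r in df.itertuples(index=False)
    ]


def write_events(events: list[AlarmEvent], path) -> None:
    pd.DataFrame(
        [{"time": e.time, "vital": e.vital, "direction": e.direction,
          "length": e.length, "label": e.label} for e in events]
    ).to_csv(path, index=False)


def read_off_periods(path) -> list[AlarmsOffPeriod]:
    """Load alarms-off periods: columns start, end (inclusive seconds)."""
    df = pd.read_csv(path)
    return [AlarmsOffPeriod(int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def write_off_periods(periods: list[AlarmsOffPeriod], path) -> None:
    pd.DataFrame([{"start": p.start, "end": p.end} for p in periods]
                 ).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a structured YAML configuration.

    Recognized top-level keys: ``filter`` (n_min, n_max, m, adequacy_level),
    ``limits`` (vital -> [lower, upper]), ``validation`` (vital ->
    [upper_s, lower_s]), ``blocks`` (name -> member list), ``evaluation``
    (detection_tolerance, suppression_tolerance, direction_match).  Returns
    a dict with parsed objects under the keys ``params``, ``limits``,
    ``blocks``, and ``evaluation``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {"raw": raw}
    if "filter" in raw:
        out["params"] = FilterParams(**raw["filter"])
    if "limits" in raw:
        validation = {k: tuple(v) for k, v in raw.get("validation", {}).items()}
        out["limits"] = AlarmLimits(
            limits={k: tuple(v) for k, v in raw["limits"].items()},
            validation=validation)
    if "blocks" in raw:
        out["blocks"] = [CorrelationBlock(name, tuple(members))
                         for name, members in raw["blocks"].items()]
    if "evaluation" in raw:
        out["evaluation"] = dict(raw["evaluation"])
    logger.info("loaded configuration from %s: %s", path, raw)
    return out
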