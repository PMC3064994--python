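"""Adaptive online Repeated Median (aoRM) filter for one univariate series.

The filter estimates the signal at the current time point by repeated-median
regression in a moving window whose width adapts to the data: while the fit
is adequate the width grows by one per step up to ``n_max``; when the ``m``
rightmost residuals show a sign imbalance (evidence of a structural change
such as a level shift) the width resets to ``n_min`` and the window is
refitted.  The emitted estimate is clipped to the range of the ``m`` most
recent observations (restrict-to-range rule), which prevents overshooting
estimates from crossing an alarm limit the raw data do not cross.

The minimum width ``n_min`` sets the trade-off between outlier resistance
and reaction speed: outlier patches shorter than half the window are
ignored, and a genuine level shift is traced with a delay of approximately
``n_min / 2`` time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import binom

from .rm_core import RMFit, repeated_median_fit, rm_residuals

__all__ = [
    "FilterParams",
    "AoRMState",
    "adequacy_test",
    "restrict_to_range",
    "aorm_step",
    "aorm_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Tuning parameters of the adaptive window machinery.

    Attributes
    ----------
    n_min : int
        Minimum window width in time points.  Governs both outlier
        resistance (patches shorter than ``n_min / 2`` are ignored) and the
        tracing delay after level shifts (about ``n_min / 2`` points).
    n_max : int
        Maximum window width; bounds memory and computing time.
        Default 300.
    m : int
        Width of the rightmost subsample used for the fit-adequacy test and
        the restrict-to-range rule.  Must satisfy ``m <= n_min / 2``;
        defaults to ``n_min // 2``.
    adequacy_level : float
        Significance level of the two-sided binomial sign-balance test.
    missing_floor_frac : float
        Fraction of the window that must be non-missing for an estimate to
        be emitted; below it the output is a missing value.
    """

    n_min: int
    n_max: int = 300
    m: int | None = None
    adequacy_level: float = 0.10
    missing_floor_frac: float = 0.5

    def __post_init__(self):
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if self.n_max < self.n_min:
            raise ValueError("n_max must be >= n_min")
        if self.m is None:
            object.__setattr__(self, "m", max(1, self.n_min // 2))
        if not 1 <= self.m <= max(1, self.n_min // 2):
            raise ValueError(f"m must satisfy 1 <= m <= n_min/2, got m={self.m}")
        if not 0.0 <= self.adequacy_level < 1.0:
            raise ValueError("adequacy_level must lie in [0, 1)")


@dataclass
class AoRMState:
    """Per-variable bookkeeping of the adaptive window."""

    params: FilterParams
    buffer: list = field(default_factory=list)
    width: int = 0  # adapted window width n(t) to use at the next step
    time: int = 0

    def window(self) -> np.ndarray:
        w = min(self.width, len(self.buffer))
        return np.asarray(self.buffer[-w:], dtype=float)


@lru_cache(maxsize=None)
def _binom_reject_region(m: int, level: float) -> tuple[int, int]:
    """Critical counts (lo, hi) of the two-sided Binomial(m, 1/2) test.

    A positive-residual count k is rejected iff k <= lo or k >= hi.
    """
    k = np.arange(m + 1)
    cdf = binom.cdf(k, m, 0.5)
    sf = binom.sf(k - 1, m, 0.5)
    pval = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    reject = pval < level
    lo = int(k[reject & (k <= m / 2)].max()) if np.any(reject & (k <= m / 2)) else -1
    hi = int(k[reject & (k >= m / 2)].min()) if np.any(reject & (k >= m / 2)) else m + 1
    return lo, hi


def adequacy_test(residuals, m: int, level: float = 0.10) -> bool:
    """Sign-balance adequacy test on the ``m`` rightmost residuals.

    A repeated-median fit yields equally many positive and negative
    residuals when the linear approximation holds; a surplus of one sign in
    the most recent residuals indicates a structural change.  The decision
    is a two-sided binomial sign test: the count of strictly positive
    residuals among the ``m`` rightmost non-missing residuals is compared
    with Binomial(m, 1/2).  Zero residuals alternate between the positive
    and negative tallies, so an exact fit is adequate deterministically.

    Returns True (ADEQUATE) if the count lies in the central acceptance
    region, False otherwise.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        return True
    r = r[-m:]
    pos = int(np.sum(r > 0))
    zeros = int(np.sum(r == 0))
    # alternate ties: first zero counts positive, second negative, ...
    pos += (zeros + 1) // 2
    n_eff = r.size
    lo, hi = _binom_reject_region(n_eff, float(_level_key(level)))
    return not (pos <= lo or pos >= hi)


def _level_key(level: float) -> float:
    return round(float(level), 12)


def restrict_to_range(estimate: float, recent) -> float:
    """Clip an estimate to the range of the most recent observations.

    ``recent`` holds the ``m`` most recent raw values (NaN allowed).  The
    clipped estimate can violate an alarm limit only if at least one of
    those raw values violates it, so the filter never creates a limit
    violation the data do not show.  If every recent value is missing the
    estimate passes through unclipped (with a warning).
    """
    r = np.asarray(recent, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        logger.warning("restrict-to-range: all recent observations missing; "
                       "estimate passed through unclipped")
        return estimate
    return float(np.clip(estimate, r.min(), r.max()))


def aorm_step(state: AoRMState, y_t: float, params: FilterParams | None = None):
    """Advance the filter by one observation; return (estimate, state).

    The step (i) appends the observation, (ii) fits the RM on the current
    window, (iii) tests fit adequacy on the ``m`` rightmost residuals and on
    rejection resets the width to ``n_min`` and refits, (iv) clips the level
    by restrict-to-range, and (v) schedules width ``min(n + 1, n_max)`` for
    the next step.  Degenerate inputs yield a missing estimate, never an
    exception.
    """
    p = params if params is not None else state.params
    state.buffer.append(float(y_t) if y_t is not None else np.nan)
    if len(state.buffer) > p.n_max:
        del state.buffer[: len(state.buffer) - p.n_max]
    state.time += 1

    if state.time < p.n_min:
        return np.nan, state
    if state.width == 0:
        state.width = p.n_min
    state.width = min(state.width, len(state.buffer))

    window = state.window()
    fit = _safe_fit(window)
    if fit is None:
        state.width = min(state.width + 1, p.n_max)
        return np.nan, state

    residuals = rm_residuals(window, fit)
    if not adequacy_test(residuals, p.m, p.adequacy_level) and state.width > p.n_min:
        state.width = p.n_min
        window = state.window()
        fit = _safe_fit(window)
        if fit is None:
            state.width = min(state.width + 1, p.n_max)
            return np.nan, state

    n_t = window.size
    floor = max(2, int(np.ceil(n_t * p.missing_floor_frac)))
    if fit.n_used < floor:
        estimate = np.nan
    else:
        recent = np.asarray(state.buffer[-p.m:], dtype=float)
        estimate = restrict_to_range(fit.level, recent)

    state.width = min(state.width + 1, p.n_max)
    return estimate, state


def _safe_fit(window: np.ndarray) -> RMFit | None:
    from .rm_core import InsufficientDataError

    try:
        return repeated_median_fit(window)
    except InsufficientDataError:
        return None


def aorm_filter(series, params: FilterParams) -> np.ndarray:
    """Apply the aoRM filter offline to a whole univariate series.

    Parameters
    ----------
    series : array-like or pandas.Series
        Regularly sampled (1 Hz) measurements, NaN for missing.
    params : FilterParams

    Returns
    -------
    numpy.ndarray
        Signal estimates aligned 1:1 with the input; the first
        ``n_min - 1`` outputs are missing (initialization).
    """
    y = np.asarray(series, dtype=float)
    out = np.full(y.shape, np.nan)
    state = AoRMState(params=params)
    for t in range(y.size):
        out[t], state = aorm_step(state, y[t], params)
    return out
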