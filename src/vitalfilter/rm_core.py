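"""Repeated Median straight-line regression on a single moving window.

The Repeated Median (RM) estimator fits a line ``y ~ level + slope * (s - n)``
to the window sample ``y_1 .. y_n`` observed at equidistant integer time
offsets ``s = 1 .. n``; the level is anchored at the rightmost window
position, which in an online application is the current time point.  The
slope is the median over points of the median pairwise slope to every other
point, which gives the estimator a 50% finite-sample replacement breakdown
point: fewer than half the window points may be replaced by arbitrary values
without the fit following them.

Missing values (NaN) are skipped in both nested medians.  Medians of
even-length samples are the mean of the two central order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RMFit", "InsufficientDataError", "repeated_median_fit", "rm_residuals"]


class InsufficientDataError(ValueError):
    """Raised when a window holds fewer than two non-missing values."""


@dataclass(frozen=True)
class RMFit:
    """Level and slope of a repeated-median window regression.

    Attributes
    ----------
    level : float
        Estimated signal level at the rightmost window position, in
        measurement units.
    slope : float
        Estimated slope per time step.
    n_used : int
        Number of non-missing observations that entered the fit.
    """

    level: float
    slope: float
    n_used: int


def repeated_median_fit(values) -> RMFit:
    """Fit a repeated-median regression line to one window sample.

    Parameters
    ----------
    values : array-like
        Window observations at consecutive integer time offsets
        ``s = 1 .. n``; NaN marks a missing value.

    Returns
    -------
    RMFit
        Level at the rightmost window position and slope per time step.

    Raises
    ------
    InsufficientDataError
        If fewer than two values are non-missing.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("window sample must be one-dimensional")
    n = y.size
    ok = np.isfinite(y)
    n_used = int(ok.sum())
    if n_used < 2:
        raise InsufficientDataError(
            f"repeated median needs >= 2 non-missing values, got {n_used}"
        )

    s = np.arange(1.0, n + 1.0)
    # pairwise slopes (y_s - y_v) / (s - v); diagonal and missing pairs -> NaN
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = (y[:, None] - y[None, :]) / (s[:, None] - s[None, :])
    inner = np.nanmedian(slopes[ok], axis=1)
    slope = float(np.median(inner))
    # back-extrapolate each point to the rightmost window position s = n
    level = float(np.median(y[ok] - slope * (s[ok] - n)))
    return RMFit(level=level, slope=slope, n_used=n_used)


def rm_residuals(values, fit: RMFit) -> np.ndarray:
    """Residuals of a window sample about its repeated-median line.

    Missing positions stay NaN.  An RM fit balances the signs of its
    residuals: the counts of strictly positive and strictly negative
    residuals can differ only through ties at zero.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    s = np.arange(1.0, n + 1.0)
    return y - (fit.level + fit.slope * (s - n))
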