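"""Adaptive online Trimmed Repeated Median-Least Squares (aoTRM-LS) filter.

Multivariate extension of the aoRM for blocks of highly positively
correlated vital signs (e.g. systolic / mean / diastolic arterial pressure).
Each step determines an overall window width shared by the block via the
aoRM adequacy machinery, fits per-variable repeated-median lines, estimates
the local error scatter of the residual vectors robustly, removes
observation vectors whose squared Mahalanobis-type distance exceeds a bound
``d``, and finally fits ordinary least-squares lines on the outlier-free
sample.  The LS step makes the estimator efficient while the trimming keeps
it robust to outliers relative to the local covariance structure.

A single-variable block is filtered by the univariate aoRM exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from statsmodels.robust.scale import qn_scale

from .aorm import FilterParams, adequacy_test, aorm_filter, restrict_to_range
from .rm_core import InsufficientDataError, repeated_median_fit, rm_residuals

__all__ = [
    "CorrelationBlock",
    "ScatterEstimate",
    "TrimmedWindow",
    "overall_window_width",
    "robust_scatter",
    "trim_outliers",
    "trmls_fit",
    "aotrmls_filter",
    "default_blocks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationBlock:
    """A named group of jointly filtered, positively correlated variables."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError("a correlation block must have at least one member")
        object.__setattr__(self, "members", tuple(self.members))


def default_blocks(columns) -> list[CorrelationBlock]:
    """Standard ICU block layout: arterial pressures, heart rate + pulse,
    and oxygen saturation on its own; unknown columns become singletons."""
    layout = [
        ("pressure", ("ART.S", "ART.M", "ART.D")),
        ("rate", ("HR", "PULSE")),
        ("spo2", ("SpO2",)),
    ]
    cols = list(columns)
    blocks: list[CorrelationBlock] = []
    used: set[str] = set()
    for name, members in layout:
        present = tuple(c for c in members if c in cols)
        if present:
            blocks.append(CorrelationBlock(name, present))
            used.update(present)
    for c in cols:
        if c not in used:
            blocks.append(CorrelationBlock(c, (c,)))
    return blocks


@dataclass(frozen=True)
class ScatterEstimate:
    """Robust k x k scatter of a residual-vector sample."""

    matrix: np.ndarray
    k: int


@dataclass(frozen=True)
class TrimmedWindow:
    """Outcome of Mahalanobis-type trimming of window time offsets."""

    kept_times: np.ndarray
    removed_times: np.ndarray
    distances: np.ndarray
    d: float


def overall_window_width(individual_widths) -> int:
    """Overall block window width: the minimum of the individual widths."""
    widths = list(individual_widths)
    if not widths:
        raise ValueError("need at least one individual window width")
    return int(min(widths))


def _robust_scale(x: np.ndarray) -> float:
    """Qn scale with MAD and std fallbacks for tiny or degenerate samples."""
    x = x[np.isfinite(x)]
    if x.size < 2:
        return 0.0
    s = float(qn_scale(x))
    if not np.isfinite(s) or s <= 0:
        s = float(1.4826 * np.median(np.abs(x - np.median(x))))
    if s <= 0:
        s = float(np.std(x))
    return s


def robust_scatter(residual_matrix, ridge: float = 1e-8,
                   reweight: float | None = 0.9) -> ScatterEstimate:
    """Orthogonalized pairwise-robust (Gnanadesikan-Kettenring) scatter.

    Parameters
    ----------
    residual_matrix : array-like, shape (n, k)
        One residual vector per row.  Rows with any missing entry are
        dropped.
    ridge : float
        Relative ridge added to keep the estimate invertible.
    reweight : float or None
        Quantile of the hard-rejection reweighting step (None disables it).

    Notes
    -----
    Pairwise covariances are built from the identity
    ``cov(u, v) = (sigma(u + v)^2 - sigma(u - v)^2) / 4`` with the Qn scale,
    then the raw pairwise matrix is orthogonalized: the data are projected
    onto its eigenvectors, the projected variances are re-estimated
    robustly, and the matrix is rebuilt.  A one-step hard-rejection
    reweighting (sample covariance of the rows whose raw squared distance
    falls below a scaled chi-square quantile, with the usual truncation
    consistency correction) sharpens both efficiency and outlier
    resistance.  The result is symmetric positive semi-definite by
    construction and is ridge-regularized to invertibility.
    """
    X = np.asarray(residual_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("residual matrix must be 2-dimensional (n, k)")
    complete = np.all(np.isfinite(X), axis=1)
    X = X[complete]
    n, k = X.shape
    if n < k + 2:
        raise InsufficientDataError(
            f"robust scatter needs >= k + 2 = {k + 2} complete residual vectors, got {n}"
        )

    scales = np.array([_robust_scale(X[:, j]) for j in range(k)])
    degenerate = scales <= 0
    if np.any(degenerate):
        logger.warning("robust_scatter: %d degenerate variable(s); ridge applied",
                       int(degenerate.sum()))
        scales[degenerate] = 1.0
    Z = X / scales

    U = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sp = _robust_scale(Z[:, i] + Z[:, j])
            sm = _robust_scale(Z[:, i] - Z[:, j])
            U[i, j] = U[j, i] = 0.25 * (sp**2 - sm**2)

    eigvals, E = np.linalg.eigh(U)
    V = Z @ E
    gamma = np.array([_robust_scale(V[:, j]) ** 2 for j in range(k)])
    D = np.diag(scales)
    sigma = D @ E @ np.diag(gamma) @ E.T @ D
    sigma = 0.5 * (sigma + sigma.T)

    if reweight is not None and np.all(np.isfinite(sigma)):
        try:
            d2 = np.einsum("ij,jk,ik->i", X, np.linalg.inv(sigma), X)
            cut = chi2.ppf(reweight, k) * np.median(d2) / chi2.ppf(0.5, k)
            keep = d2 <= cut
            if keep.sum() >= k + 2:
                Xw = X[keep] - X[keep].mean(axis=0)
                sw = (Xw.T @ Xw) / (keep.sum() - 1)
                consistency = chi2.cdf(chi2.ppf(reweight, k), k + 2) / reweight
                sigma = sw / consistency
        except np.linalg.LinAlgError:
            pass

    # regularize to invertibility
    scale_ref = max(np.trace(sigma) / k, 1e-12)
    w, Q = np.linalg.eigh(sigma)
    floor = ridge * scale_ref
    if np.any(w < floor):
        w = np.maximum(w, floor)
        sigma = Q @ np.diag(w) @ Q.T
    return ScatterEstimate(matrix=sigma, k=k)


def trim_outliers(residual_matrix, scatter: ScatterEstimate, d: float,
                  min_keep: int | None = None) -> TrimmedWindow:
    """Remove window time offsets whose residual vector is locally outlying.

    A time offset ``s`` is removed iff ``r_s' Sigma^-1 r_s > d``.  Rows with
    missing entries get an undefined (NaN) distance and are never removed
    here (they are excluded from the LS step separately).  If removal would
    leave fewer than ``min_keep`` rows, removed rows are retained back in
    order of increasing distance until the minimum holds.
    """
    if d <= 0:
        raise ValueError("trimming bound d must be positive")
    X = np.asarray(residual_matrix, dtype=float)
    n = X.shape[0]
    inv = np.linalg.inv(scatter.matrix)
    dist = np.full(n, np.nan)
    complete = np.all(np.isfinite(X), axis=1)
    Xc = X[complete]
    dist[complete] = np.einsum("ij,jk,ik->i", Xc, inv, Xc)

    removed = np.zeros(n, dtype=bool)
    removed[complete] = dist[complete] > d
    if min_keep is not None:
        n_kept = int(n - removed.sum())
        if n_kept < min_keep:
            order = np.argsort(dist[removed])  # increasing distance
            back = np.flatnonzero(removed)[order][: min_keep - n_kept]
            removed[back] = False
    times = np.arange(n)
    return TrimmedWindow(
        kept_times=times[~removed],
        removed_times=times[removed],
        distances=dist,
        d=float(d),
    )


def trmls_fit(window, d: float | None = None, min_keep: int | None = None) -> np.ndarray:
    """Trimmed Repeated Median-Least Squares level vector for one window.

    Per-variable RM lines give a residual-vector sample; its robust scatter
    identifies outlying observation vectors via the quadratic-form rule;
    LS lines on the kept observations give the level vector at the
    rightmost window position.  Falls back to the RM levels when the
    trimmed LS step is undetermined.

    Parameters
    ----------
    window : array-like, shape (n, k)
        Block window sample, one row per time offset.
    d : float, optional
        Trimming bound on the squared Mahalanobis-type distance; default is
        the 0.95 chi-square quantile with k degrees of freedom.
    min_keep : int, optional
        Minimum retained sample size; default ``n // 2 + 2``.
    """
    Y = np.asarray(window, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = Y.shape
    if d is None:
        d = float(chi2.ppf(0.95, df=k))
    if min_keep is None:
        min_keep = n // 2 + 2
    s = np.arange(1.0, n + 1.0)
    x = s - n  # level is the intercept at the rightmost position

    rm_levels = np.full(k, np.nan)
    residuals = np.full((n, k), np.nan)
    for j in range(k):
        try:
            fit = repeated_median_fit(Y[:, j])
        except InsufficientDataError:
            continue
        rm_levels[j] = fit.level
        residuals[:, j] = rm_residuals(Y[:, j], fit)

    try:
        scatter = robust_scatter(residuals)
    except InsufficientDataError:
        logger.warning("trmls_fit: too few complete residual vectors; "
                       "falling back to RM levels")
        return rm_levels

    trimmed = trim_outliers(residuals, scatter, d, min_keep=min_keep)
    complete = np.all(np.isfinite(Y), axis=1)
    kept = np.zeros(n, dtype=bool)
    kept[trimmed.kept_times] = True
    use = kept & complete

    levels = np.full(k, np.nan)
    if use.sum() < max(3, k + 1):
        logger.warning("trmls_fit: insufficient kept observations (%d); "
                       "falling back to RM levels", int(use.sum()))
        return rm_levels
    A = np.column_stack([np.ones(int(use.sum())), x[use]])
    coef, *_ = np.linalg.lstsq(A, Y[use], rcond=None)
    levels = coef[0]
    for j in range(k):
        if not np.isfinite(levels[j]):
            levels[j] = rm_levels[j]
    return levels


def aotrmls_filter(series, blocks=None, params: FilterParams | None = None,
                   d: float | None = None, return_widths: bool = False):
    """Apply the aoTRM-LS filter block-wise to a multivariate series.

    Parameters
    ----------
    series : pandas.DataFrame
        Regularly sampled (1 Hz) measurements, one column per vital sign,
        NaN for missing.
    blocks : list of CorrelationBlock, optional
        Must partition the filtered columns; default is the standard ICU
        layout (arterial pressures / heart rate + pulse / SpO2).
    params : FilterParams
    d : float, optional
        Trimming bound; default is the 0.95 chi-square quantile per block.

    return_widths : bool
        If True, also return a DataFrame of the per-block overall window
        widths used at each time step (diagnostics).

    Returns
    -------
    pandas.DataFrame
        Estimates aligned 1:1 with the input, same columns and index.
        With ``return_widths=True``, a ``(estimates, widths)`` tuple.
    """
    import pandas as pd

    if params is None:
        raise ValueError("params is required")
    df = series if isinstance(series, pd.DataFrame) else pd.DataFrame(series)
    if blocks is None:
        blocks = default_blocks(df.columns)
    seen: set[str] = set()
    for b in blocks:
        for v in b.members:
            if v not in df.columns:
                raise ValueError(f"block {b.name!r} references unknown variable {v!r}")
            if v in seen:
                raise ValueError(f"variable {v!r} appears in more than one block")
            seen.add(v)

    out = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
    widths = pd.DataFrame(np.nan, index=df.index, columns=[b.name for b in blocks])
    for b in blocks:
        if len(b.members) == 1:
            # singleton blocks reduce to the univariate aoRM exactly
            col = b.members[0]
            out[col] = aorm_filter(df[col].to_numpy(dtype=float), params)
        else:
            est, w = _filter_block(df[list(b.members)].to_numpy(dtype=float), params, d)
            out[list(b.members)] = est
            widths[b.name] = w
    if return_widths:
        return out, widths
    return out


def _filter_block(Y: np.ndarray, p: FilterParams, d: float | None):
    T, k = Y.shape
    out = np.full((T, k), np.nan)
    width_trace = np.full(T, np.nan)
    width = p.n_min
    for t in range(p.n_min - 1, T):
        width = min(width, t + 1)
        window = Y[t - width + 1 : t + 1]

        # step (1): individual widths via the aoRM adequacy machinery
        individual = []
        for j in range(k):
            n_j = width
            try:
                fit = repeated_median_fit(window[:, j])
                res = rm_residuals(window[:, j], fit)
                if not adequacy_test(res, p.m, p.adequacy_level):
                    n_j = p.n_min
            except InsufficientDataError:
                pass
            individual.append(n_j)
        n_ov = overall_window_width(individual)

        # step (2): TRM-LS regression on the overall window
        w = Y[t - n_ov + 1 : t + 1]
        levels = trmls_fit(w, d=d)

        floor = max(2, int(np.ceil(n_ov * p.missing_floor_frac)))
        for j in range(k):
            n_used = int(np.isfinite(w[:, j]).sum())
            if n_used < floor or not np.isfinite(levels[j]):
                out[t, j] = np.nan
            else:
                recent = Y[max(0, t - p.m + 1) : t + 1, j]
                out[t, j] = restrict_to_range(levels[j], recent)

        # step (3)
        width_trace[t] = n_ov
        width = min(n_ov + 1, p.n_max)
    return out, width_trace
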