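"""Multivariate filter: robust scatter, trimming, trimmed LS, block logic."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from vitalfilter.aorm import FilterParams, aorm_filter
from vitalfilter.aotrmls import (
    CorrelationBlock,
    aotrmls_filter,
    default_blocks,
    overall_window_width,
    robust_scatter,
    trim_outliers,
    trmls_fit,
)
from vitalfilter.rm_core import InsufficientDataError, repeated_median_fit


class TestOverallWidth:
    @pytest.mark.parametrize("widths,expected", [
        ((300, 40, 120), 40),
        ((50, 50, 50), 50),
        ((77,), 77),
    ])
    def test_minimum(self, widths, expected):
        assert overall_window_width(widths) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            overall_window_width([])


class TestRobustScatter:
    def test_bivariate_normal_accuracy(self, rng):
        true_cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        X = rng.standard_normal((500, 2)) @ np.linalg.cholesky(true_cov).T
        S = robust_scatter(X).matrix
        rel = np.linalg.norm(S - true_cov) / np.linalg.norm(true_cov)
        assert rel < 0.15

    def test_uncorrelated_identity(self, rng):
        X = rng.standard_normal((800, 3))
        S = robust_scatter(X).matrix
        assert np.allclose(np.diag(S), 1.0, atol=0.2)
        off = S[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.15)

    def test_contamination_bounded(self, rng):
        true_cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        X = rng.standard_normal((500, 2)) @ np.linalg.cholesky(true_cov).T
        S_clean = robust_scatter(X).matrix
        Xc = X.copy()
        Xc[rng.choice(500, 50, replace=False)] = 1e4  # 10% huge outliers
        S_cont = robust_scatter(Xc).matrix
        rel = np.linalg.norm(S_cont - S_clean) / np.linalg.norm(S_clean)
        assert rel < 0.25

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            robust_scatter(np.zeros((3, 2)))

    def test_rank_deficient_regularized(self, rng):
        x = rng.standard_normal(100)
        X = np.column_stack([x, x])  # perfectly collinear
        S = robust_scatter(X).matrix
        assert np.all(np.isfinite(np.linalg.inv(S)))


class TestTrimOutliers:
    def test_all_zero_nothing_removed(self):
        from vitalfilter.aotrmls import ScatterEstimate
        X = np.zeros((20, 2))
        tw = trim_outliers(X, ScatterEstimate(np.eye(2), 2), d=5.99)
        assert tw.removed_times.size == 0
        assert tw.kept_times.size == 20

    def test_single_extreme_vector_removed(self, rng):
        X = rng.standard_normal((100, 2))
        X[42] = [100.0, 100.0]
        S = robust_scatter(X)
        d = float(chi2.ppf(0.95, 2))
        tw = trim_outliers(X, S, d=d)
        assert 42 in tw.removed_times
        assert tw.distances[42] > d

    def test_infinite_bound_keeps_all(self, rng):
        X = rng.standard_normal((50, 3))
        tw = trim_outliers(X, robust_scatter(X), d=np.inf)
        assert tw.removed_times.size == 0

    def test_monotone_in_d(self, rng):
        """Increasing the bound never removes more observations."""
        X = rng.standard_normal((80, 2)) * 3
        X[::9] *= 10
        S = robust_scatter(X)
        removed = [trim_outliers(X, S, d=d).removed_times.size
                   for d in (1.0, 2.0, 4.0, 8.0, 16.0, np.inf)]
        assert removed == sorted(removed, reverse=True)

    def test_min_keep_enforced(self, rng):
        X = rng.standard_normal((30, 2))
        S = robust_scatter(X)
        tw = trim_outliers(X, S, d=1e-6, min_keep=17)
        assert tw.kept_times.size >= 17


class TestTrmlsFit:
    def test_noise_free_exact(self):
        t = np.arange(1.0, 61.0)
        Y = np.column_stack([100 + 0.5 * t, 80 - 0.2 * t])
        levels = trmls_fit(Y)
        assert levels == pytest.approx([100 + 0.5 * 60, 80 - 0.2 * 60], abs=1e-9)

    def test_common_spike_trimmed(self, rng):
        t = np.arange(1.0, 81.0)
        noise = rng.standard_normal((80, 2)) * 0.5
        Y = np.column_stack([100 + 0.1 * t, 70 + 0.1 * t]) + noise
        Yspiked = Y.copy()
        Yspiked[40] += [30.0, 30.0]
        clean = trmls_fit(Y)
        spiked = trmls_fit(Yspiked)
        assert np.all(np.abs(spiked - clean) < 1.0)  # within noise scale

    def test_k1_equals_univariate_trimmed_ls(self, rng):
        """For k = 1 the fit is univariate RM + trimmed univariate LS."""
        y = rng.standard_normal(50) + 10
        level = trmls_fit(y[:, None])[0]
        fit = repeated_median_fit(y)
        r = y - (fit.level + fit.slope * (np.arange(1.0, 51.0) - 50))
        S = robust_scatter(r[:, None])
        tw = trim_outliers(r[:, None], S, d=float(chi2.ppf(0.95, 1)),
                           min_keep=50 // 2 + 2)
        x = np.arange(1.0, 51.0) - 50
        A = np.column_stack([np.ones(tw.kept_times.size), x[tw.kept_times]])
        coef, *_ = np.linalg.lstsq(A, y[tw.kept_times], rcond=None)
        assert level == pytest.approx(coef[0], abs=1e-9)


class TestBlockFilter:
    def test_singleton_block_identical_to_aorm(self, scenario):
        params = FilterParams(n_min=30, m=15)
        series = scenario["series"][["SpO2"]]
        est = aotrmls_filter(series, blocks=[CorrelationBlock("spo2", ("SpO2",))],
                             params=params)
        uni = aorm_filter(series["SpO2"].to_numpy(dtype=float), params)
        assert np.array_equal(est["SpO2"].to_numpy(), uni, equal_nan=True)

    def test_correlated_noise_free_lines_exact(self):
        t = np.arange(300.0)
        df = pd.DataFrame({"ART.S": 120 + 0.05 * t, "ART.M": 80 + 0.05 * t})
        params = FilterParams(n_min=20, m=10)
        est = aotrmls_filter(
            df, blocks=[CorrelationBlock("p", ("ART.S", "ART.M"))], params=params)
        sl = slice(params.n_min - 1, None)
        assert np.allclose(est["ART.S"].to_numpy()[sl],
                           df["ART.S"].to_numpy()[sl], atol=1e-6)
        assert np.allclose(est["ART.M"].to_numpy()[sl],
                           df["ART.M"].to_numpy()[sl], atol=1e-6)

    def test_width_reset_is_per_block(self, rng):
        """A step change in one block resets its window width while the
        unchanged block's width keeps growing."""
        T = 200
        noise = rng.standard_normal((T, 4)) * 0.3
        a = np.full(T, 50.0)
        b = np.full(T, 60.0)
        a[120:] += 30.0
        b[120:] += 30.0
        c = np.full(T, 80.0)
        d = np.full(T, 90.0)
        df = pd.DataFrame(np.column_stack([a, b, c, d]) + noise,
                          columns=["a", "b", "c", "d"])
        params = FilterParams(n_min=20, m=10)
        _, widths = aotrmls_filter(
            df, blocks=[CorrelationBlock("shifted", ("a", "b")),
                        CorrelationBlock("stable", ("c", "d"))],
            params=params, return_widths=True)
        at = 135  # after the sign imbalance has accumulated
        assert widths["shifted"].iloc[at] <= params.n_min + 15  # reset occurred
        # the unchanged block kept a much wider window than the shifted one
        assert widths["stable"].iloc[at] >= 2 * widths["shifted"].iloc[at]
        # and the shifted block did grow again between t = 120 and the reset
        assert (widths["shifted"].iloc[121:126].diff().dropna() == 1).all()

    def test_unknown_variable_errors(self, scenario):
        with pytest.raises(ValueError, match="unknown variable"):
            aotrmls_filter(scenario["series"],
                           blocks=[CorrelationBlock("x", ("nope",))],
                           params=FilterParams(n_min=20, m=10))

    def test_default_blocks_partition(self):
        blocks = default_blocks(["ART.S", "ART.M", "HR", "SpO2", "TEMP"])
        members = [v for b in blocks for v in b.members]
        assert sorted(members) == sorted(["ART.S", "ART.M", "HR", "SpO2", "TEMP"])


def test_efficiency_on_clean_gaussian(rng):
    """On clean correlated Gaussian noise around a line, the trimmed-LS
    level is at least as efficient as the pure RM level (5% slack)."""
    n, reps = 50, 150
    t = np.arange(1.0, n + 1.0)
    R = np.linalg.cholesky(np.array([[1.0, 0.6], [0.6, 1.0]]))
    trm, rm = [], []
    for _ in range(reps):
        noise = rng.standard_normal((n, 2)) @ R.T
        Y = np.column_stack([10 + 0.1 * t, 20 + 0.1 * t]) + noise
        trm.append(trmls_fit(Y)[0])
        rm.append(repeated_median_fit(Y[:, 0]).level)
    assert np.var(trm) <= np.var(rm) * 1.05
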