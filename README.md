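# vitalfilter

Robust online signal extraction and threshold-alarm evaluation for
vital-sign monitoring time series.

Intensive-care monitors raise *threshold alarms* whenever a measured vital
sign (arterial pressure, heart rate, oxygen saturation, ...) stays outside
its configured limits for a short validation time. Because 1 Hz monitoring
data are riddled with artefacts and spiky outliers, most of these alarms
are clinically irrelevant. One remedy is to compare *filtered signal
estimates* to the alarm limits instead of the raw measurements. This
package is for researchers and engineers who want to build and evaluate
such filter-based alarm systems without access to clinical data: it
implements the filters, a monitor-style alarm generator, an interval-based
evaluation of alarm quality, and a synthetic-scenario generator that stands
in for annotated patient recordings.

## The method

The observed series is modelled as `y(t) = μ(t) + ε(t) + η(t)`: a
piecewise-linear signal `μ`, zero-median noise `ε` with time-varying
variance (possibly correlated between related vitals), and an impulsive
outlier process `η`.

**Repeated Median (RM) regression** fits a line to a moving window
`{t−n+1, …, t}` with

```
β̂(t) = med_s { med_{v≠s} (y_s − y_v)/(s − v) },   μ̂(t) = med_s { y_s − β̂(t)·(s − n) },
```

estimating the signal level at the window's right edge (the current time
point). The RM has a 50% replacement breakdown point: fewer than half the
window points may be arbitrary without moving the fit.

**aoRM** (adaptive online RM) chooses the window width `n(t)` on the fly:
while the `m` rightmost residuals keep balanced signs (two-sided binomial
sign test) the window grows by one per step up to `n_max = 300`; on
imbalance — evidence of a level shift — it resets to `n_min`. The emitted
estimate is clipped to the range of the `m = n_min/2` most recent
observations (*restrict-to-range*), so the filter can never trigger an
alarm the raw data would not. The price of robustness is a *tracing delay*
of about `n_min/2` time points after genuine level shifts.

**aoTRM-LS** extends this to blocks of positively correlated vitals (e.g.
systolic/mean/diastolic pressure): a shared adaptive window, per-variable
RM residuals, a robust OGK scatter estimate `Σ̂(t)` of the residual
vectors, removal of observation vectors with `rᵀΣ̂⁻¹r > d` (default: 0.95
chi-square quantile), and a final multivariate least-squares fit on the
kept sample — robust *and* efficient.

**Evaluation.** Against annotated alarms of a conventional monitor, a true
alarm at `t` is *detected* if the filtered estimates violate the limit
within `{t, …, t+D}` (D = 60 s, 30 s for heart rate); a false alarm is
*suppressed* if they violate nothing within `{t, …, t+S}` (S = 60 s >
tracing delay). Sensitivity SE = detected/all true; false alarm reduction
rate FARR = suppressed/all false, after excluding false alarms whose
intervals overlap same-vital true intervals. Advisory alarms are first
reassessed true/false by their alarm length.

## Worked example

```python
import numpy as np
from vitalfilter import FilterParams, aorm_filter

# noise-free level shift: 0 for 150 s, then 10
y = np.concatenate([np.zeros(150), np.full(150, 10.0)])
est = aorm_filter(y, FilterParams(n_min=40, m=20))
delay = int(np.argmax(est[150:] > 5.0)) + 1
print(delay)            # -> 20   (tracing delay ≈ n_min/2 time points)
```

End to end on a synthetic annotated scenario:

```python
from vitalfilter import (IntervalConfig, annotate_scenario, example_scenario,
                         reassess_advisory, score_filter, sweep_nmin)

series, truth, limits, off, cfg = example_scenario(seed=1)
events = reassess_advisory(annotate_scenario(series, truth, limits, off=off))

baseline = score_filter(series, series, events, limits)   # identity filter
print(baseline.SE, baseline.FARR)   # -> 1.0 0.0  (the raw alarm system)

table = sweep_nmin(series, events, limits, IntervalConfig(),
                   grid=range(10, 91, 10), filter_kind="aorm")
print(table[table.vital == "overall"][["n_min", "SE", "FARR"]])
#    n_min   SE      FARR
#       10  1.0  0.166667
#       20  1.0  0.666667
#       30  0.8  1.000000
#      ...
#       90  0.6  1.000000
```

Larger minimum window widths suppress more artefact-driven false alarms
(FARR rises) but trace genuine changes later, so short-lived true alarms
are missed (SE falls) — the central trade-off when tuning `n_min`.

The same functionality is available from the shell:

```bash
vitalfilter simulate --seed 1 --series-out series.csv --events-out events.csv
vitalfilter filter series.csv --out est.csv --n-min 40
vitalfilter evaluate est.csv series.csv events.csv --config cfg.yaml --out report.json
vitalfilter sweep series.csv events.csv --config cfg.yaml --out sweep.csv
```

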