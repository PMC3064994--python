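# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `vitalfilter`. It is written for users who want to know
exactly what the package computes and what its tests do and do not show.

## Signal model

All components assume regularly sampled (1 Hz) measurements decomposed as

```
y(t) = μ(t) + ε(t) + η(t)
```

per vital sign: a signal `μ` that is approximately linear within short
windows (so level shifts and trend changes appear as breaks between
locally-linear stretches), noise `ε` with zero median and possibly
time-varying scale and within-block cross-correlation, and an impulsive
outlier process `η` producing isolated spikes and short patches. Missing
values may occur at single seconds or in long stretches.

## Repeated Median kernel (`rm_core`)

For a window `y_1 … y_n` at integer offsets `s = 1 … n`, the slope is the
median over `s` of the median over `v ≠ s` of the pairwise slopes
`(y_s − y_v)/(s − v)`; the level is the median over `s` of the
back-extrapolated values `y_s − slope·(s − n)`, anchoring the estimate at
the rightmost window position (the current time point, so the online
estimate has no lookahead and no intrinsic lag on stable data). Missing
values are skipped in both medians; a fit needs at least two observed
points.

Numerical choices:

* Median of an even-length sample = mean of the two central order
  statistics.
* The pairwise slope matrix is computed densely (O(n²)); with
  `n_max = 300` one fit costs a 300×300 `nanmedian`, a few milliseconds.
  Any faster scheme would have to match this reference exactly; none is
  provided.
* The level uses back-extrapolation `y_s − slope·(s − n)`: this is the
  form under which a noise-free line is recovered exactly (the level
  equals the last point of the line), which the test suite asserts to
  machine precision.

Every fit with `n ≤ 12` is checked against an independent brute-force
oracle that enumerates all pairwise slopes in pure-Python loops and takes
nested `statistics.median`s.

## Adaptive window univariate filter (`aorm`)

Parameters (defaults chosen to mirror the standard protocol):

| name | meaning | default |
|------|---------|---------|
| `n_min` | minimum window width (time points); sets outlier resistance and the tracing delay ≈ `n_min/2` | required, ≥ 2 |
| `n_max` | maximum window width | 300 |
| `m` | rightmost subsample for the adequacy test and restrict-to-range; must be ≤ `n_min/2` | `n_min // 2` |
| `adequacy_level` | significance level of the sign-balance test | 0.10 |
| `missing_floor_frac` | minimum observed fraction of the window for an estimate | 0.5 |

Each step appends the new observation, fits the RM on the current window
of width `n(t)`, and tests whether the fit is still adequate: the count of
strictly positive residuals among the `m` rightmost non-missing residuals
is referred to a two-sided Binomial(m, ½) test. Zero residuals alternate
deterministically between the positive and negative tallies, so an exact
fit is always adequate. On rejection the width resets fully to `n_min` and
the window is refitted; otherwise the width is kept, and in either case
the next step uses `min{n(t)+1, n_max}`. The critical region per `(m,
level)` is cached.

The published description of the adaptive filter defers the exact
adequacy statistic to external work; the binomial sign test used here is
this package's fixed operationalization of the residual-balance idea, and
the refit-after-reset behaviour within the same step is likewise a fixed
choice. Both are deliberate, documented stand-ins.

The emitted estimate is clipped to `[min, max]` of the `m` most recent
observations (*restrict-to-range*). Consequences:

* the filter can never produce a limit violation unless at least one of
  the `m` most recent raw values violates that limit (range safety, tested
  as an invariant), and
* on a large noise-free level shift the estimate crosses the half-shift
  level exactly `m = n_min/2` steps after the shift — the clip forces the
  crossing even before the RM majority flips — giving tracing delays of
  20 points at `n_min = 40` and 45 s at `n_min = 90` (1 Hz),
  deterministically.

A window emits a missing value when fewer than
`max(2, ⌈n(t)/2⌉)` observations are present, preserving the majority
logic; degenerate inputs never raise. If all `m` recent values are missing
the estimate passes through unclipped with a logged warning.

## Multivariate filter (`aotrmls`)

Blocks of positively correlated vitals (default layout: systolic/mean/
diastolic arterial pressure; heart rate + pulse; SpO2 alone) are filtered
jointly. Per step: individual widths per member variable via the aoRM
adequacy machinery, overall width `n_ov = min_i n_i`, then a trimmed
RM–LS fit on the overall window:

1. per-variable RM lines and residuals;
2. robust scatter `Σ̂` of the residual vectors: orthogonalized
   Gnanadesikan–Kettenring (OGK) with the Qn scale — pairwise covariances
   from `¼[σ(z_i+z_j)² − σ(z_i−z_j)²]`, eigen-orthogonalization,
   robust re-estimation of the projected variances — followed by one
   hard-rejection reweighting step (sample covariance of rows whose raw
   squared distance is below the 0.9 chi-square quantile scaled by the
   distance median, with the standard truncation-consistency correction).
   The reweighting is what keeps the estimate within a few percent under
   10% gross contamination; the raw OGK alone drifts several times more.
   The result is symmetrized and eigenvalue-floored (relative ridge 1e-8)
   to guarantee invertibility;
3. removal of observation vectors with `rᵀΣ̂⁻¹r > d`; `d` defaults to the
   0.95 chi-square quantile with `k` degrees of freedom (the quadratic
   form is a squared Mahalanobis-type distance). If trimming would leave
   fewer than `⌊n*/2⌋ + 2` rows, removed rows are restored in increasing
   distance order until the floor holds — so the LS step stays determined
   and majority-based;
4. ordinary least squares per variable on the kept complete rows; levels
   at the right edge, then restrict-to-range per variable.

Rows with a missing member are excluded from scatter and LS but still
contribute to their own variable's RM. When the scatter or the LS step is
undetermined the fit falls back to the per-variable RM levels with a
warning. A single-variable block is dispatched to the univariate aoRM, so
its output is bit-identical to `aorm_filter` (asserted in the tests).

Trimming is monotone in `d` by construction, and on clean correlated
Gaussian noise the trimmed-LS level is at least as efficient as the pure
RM level (Monte-Carlo variance comparison with 5% slack in the suite).

## Alarm system (`alarm_system`)

Strict limit comparison (`value > upper` or `value < lower`; a value
exactly on a limit does not violate). A maximal violation run produces at
most one alarm, at the second its duration first reaches the vital- and
direction-specific validation time (counted including the onset second;
"immediately" = 1 sample). Defaults: heart rate 2 s upper / immediate
lower; blood pressures 4 s / 4 s; oxygen saturation 4 s / 10 s.

Tie-breaks fixed for determinism (monitors differ and the behaviour is
otherwise unspecified): a single interior missing second is bridged when
both neighbours violate — the bridged second counts toward run length and
validation — while two or more consecutive missing seconds end the run. A
run yields no alarm if its validation threshold is met inside an
alarms-off period; one alarm per run, no re-alarming.

Advisory alarms (technically true, not requiring immediate action) are
reassessed by alarm length: strictly shorter than 10 s (arterial
pressures), 5 s (heart rate), 15 s (SpO2) becomes false, otherwise true.
Reassessment is idempotent and never touches true/false labels.

## Evaluation (`evaluation`)

Detection intervals `{t, …, t+D}` extend only forward from a true alarm —
the filters react with a tracing delay and do not forecast, so seconds
before the alarm are uninformative. `D` = 60 s (30 s for heart rate),
suppression tolerance `S` = 60 s, chosen to exceed the largest tracing
delay on the default `n_min` grid (45 s at `n_min = 90`). Intervals are
closed, in whole seconds, clipped at the series end.

A false alarm whose interval shares at least one second with a same-vital
true interval is excluded from the FARR denominator (detection takes
precedence); detection is never affected by exclusion. Detection requires
the estimates to violate the same limit direction as the annotated alarm
(configurable off); suppression is direction-agnostic — the stricter,
non-flattering reading. Missing estimate seconds never count as
violations. Estimate violations inside alarms-off periods are, by
default, excluded from suppression scoring but reported as a separate
count (`report` mode); `strict` mode counts them against suppression —
neither the raw nor the filtered system is silently favoured.

The identity filter (estimates = raw) satisfies `SE = 1`, `FARR = 0`
exactly whenever every alarm arises from a raw limit violation, since each
alarm's onset second lies in its own interval. `specificity_estimate`
implements the alternative specificity `(FP_max − FP)/FP_max` (0 when
`FP > FP_max`); it is provided for completeness but no default rule for
choosing `FP_max` is imposed.

`sweep_nmin` runs a filter over `n_min = 10, 20, …, 90` with
`m = n_min/2` and `n_max = 300` per point and tabulates SE/FARR per vital
for the trade-off plot.

## Synthetic scenarios (`synthetic`)

The generator emulates the signal model directly: piecewise-linear
segments per vital, Gaussian noise (optionally scaled-t for heavy-tailed
robustness checks — the model only requires zero median) with per-vital
scale and within-block correlation via Cholesky, additive artefact
patches, missing gaps, and alarms-off periods. All randomness derives from
one seed through named substreams (noise / outliers / gaps), so toggling
one component leaves the others bit-identical.

Ground truth records the clean signal, the outlier mask, and every
injected event; `annotate_scenario` labels raw-series alarms by matching
them to the nearest same-vital event (relevant shift → true, artefact →
false, advisory drift → advisory; unmatched → false), standing in for
retrospective physician annotation.

The canonical scenario (`example_scenario`) spans 900 s and four vitals
with typical adult ICU baselines and limits: sustained excursions beyond a
limit (120 s hypotensive shift in both pressures, 100 s tachycardia, 100 s
desaturation) as true alarms; short artefact patches (2–8 s, SpO2 10–14 s
to clear its 10 s validation time) as false alarms; two 12 s advisory
drifts that reassess to true (mean pressure, ≥ 10 s) and false (SpO2,
< 15 s); a 6 s heart-rate dropout. Noise scales (2.0 / 1.5 / 1.0 / 0.4
measurement units) leave ≥ 5σ margins between baselines and limits, so
the annotated alarm list is structurally stable across seeds. Artefacts
are placed in quiet zones ≥ 130 s away from same-vital true events so
false intervals never overlap true intervals. Scenario sizes (hundreds of
seconds, single-digit alarm counts per vital) are desk-scale by design;
they exercise every code path while keeping the full test suite around a
minute.

What passing tests on these scenarios do **not** show: performance on real
monitoring data, whose artefacts are not purely additive, whose noise is
non-Gaussian and autocorrelated, whose alarm annotations carry inter-rater
uncertainty, and whose alarm mix is far more heterogeneous. The clinical
SE/FARR levels reported for filter-based alarm systems in the literature
cannot be reproduced here; the suite verifies the algorithmic properties
(delays, breakdown, identities, monotone trade-off), not clinical numbers.

## Known limitations

* The adequacy statistic and the robust scatter are declared stand-ins
  for procedures whose originals are specified only by reference; both
  are configurable at the call sites.
* The dense O(n²) RM makes a 300-wide window cost a few ms per step;
  long recordings (days) would want the incremental-update literature.
* Correlation blocks are static; time-varying block discovery is out of
  scope.
* No trend/slope-based alarms, no technical-alarm taxonomy, no waveform
  (high-rate) analysis.
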