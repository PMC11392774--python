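# Methods

## Scope and data model

The package analyzes spike timestamp sequences of single sorted units
within fixed-duration records (default 60 s, matching one-minute baseline
and stimulation epochs). A `SpikeTrain` carries strictly increasing
timestamps in `[0, duration]` plus condition (`baseline` / `stimulation`)
and cell-type labels; an `ISISequence` is its ordered sequence of
consecutive differences. All statistics are computed on these two objects.
Spike detection and sorting from continuous voltage are out of scope; the
package starts from point events.

Conventions used everywhere: sample standard deviation with the N−1
denominator (CV, ApEn tolerance, Fano variance, R/S segment SD), and
half-open interval membership `[lo, hi)` for ISI-range fractions.

## Estimators

### Fano factor and scaling exponent α

For each window size `T` on a log-spaced grid (default 10 points per
decade, 0.1–10 s), the record is partitioned into `floor(duration/T)`
contiguous non-overlapping windows anchored at `t = 0`; the remainder
beyond the last complete window is discarded, and `F(T)` is the sample
variance over windows of the spike counts divided by their mean. Window
sizes with fewer than 4 complete windows, or with zero mean count, are
dropped from the curve and reported. α is the ordinary-least-squares slope
of `log₁₀ F(T)` against `log₁₀ T` restricted to the scaling region,
default `10^-0.5` s (≈0.32 s) to 10 s — the onset below which count
statistics are dominated by the refractory/entrainment microstructure
rather than long-range correlation. Both the grid and the fit range are
exposed as options (CLI flags `--t-min/--t-max/--fano-fit-lo/--fano-fit-hi`).

Numerical detail: window edges are evaluated with a relative tolerance of
`1e-9·T` — a spike lying within that distance below an edge is assigned to
the upper window. The tolerance is many orders of magnitude below any
physical spike-timing resolution; it exists so that a strictly periodic
train whose period divides `T` yields identical counts in every window
(hence `F(T) = 0` exactly) regardless of how the binary floating-point
representation of its timestamps rounds at window boundaries.

### Rescaled-range Hurst exponent

For each segment length `d` on a log-spaced integer grid (~15 unique
values from 4 to `floor(N/3)`), the first `M·d` intervals (`M = floor(N/d)`,
trailing remainder discarded) form `M` adjacent segments. Per segment the
cumulative deviation from the segment mean is accumulated; its range `R`
is divided by the segment sample SD `S`, and `(R/S)_d` is the mean over
segments. Segments whose SD is zero (to within `1e-10` of the segment
scale — identical intervals can carry rounding noise) are excluded from
the average and counted; a `d` where every segment is degenerate is
dropped. `H` is the OLS slope of `log₁₀ (R/S)_d` versus `log₁₀ d` over
the full grid. Estimates slightly outside `[0, 1]` are reported, never
clipped.

The raw R/S estimator is biased upward for short series when small `d`
are included: its expected slope for *independent* data over this exact
grid at `N = 4096` is ≈0.578 (this matches the Anis–Lloyd closed-form
expectation, which the test suite checks per `d`). No bias correction is
applied — the analysis convention here is the raw estimator with `d` from
4 — so "independent" reads as ≈0.58 rather than 0.50 at these lengths,
and antipersistent inputs are compressed toward 0.5 from below.
Interpretation of direction is therefore most reliable relative to the
estimator's own independent-ISI reference (e.g. via shuffle surrogates),
which is how the direction-semantics tests are written.

### Approximate entropy

Classic ApEn(m, r): `Φ^m(r) − Φ^{m+1}(r)` with Chebyshev distance between
embedded templates and self-matches included (not SampEn), computed on the
ISI sequence — the per-unit scalar series this pipeline constructs.
Defaults `m = 2` and `r = 0.15 × sample SD` of the sequence; the
relative-to-SD reading of the tolerance is the standard amplitude-invariant
convention (an absolute `r = 0.15` in seconds would make the metric depend
on firing rate). A constant sequence has zero SD, hence `r = 0`; since all
templates are then identical the result is defined as 0 rather than an
error. The implementation is vectorized; the test suite pins it exactly
(1e-10) to an independent double-loop implementation.

### ISI statistics

Firing rate is spike count over record duration. ISI-range fractions use
half-open bins, so the Table-style ranges "0–8 ms" and "19–21 ms" are
`[0, 8)` and `[19, 21)`. The ISI histogram is probability-normalized with
1 ms bins *centered* on integer milliseconds (edges at half-widths): a
symmetric jittered peak at one stimulation period (20 ms) then falls inside
a single bin and the dominant-peak location is stable across realizations,
which edge-aligned bins cannot guarantee (a peak at 20 ms would straddle
the 19–20/20–21 edge and flip between neighbors). The first bin is
half-width (`[0, w/2)`) as ISIs are positive.

## Synthetic generators

The generators emulate the firing regimes the estimators are meant to
distinguish; each is deterministic under a fixed seed, and every config
carries its seed.

- **Poisson** — i.i.d. exponential ISIs at a given rate; the `F(T) ≈ 1`,
  `CV = 1`, `H ≈ 0.5` control.
- **Periodic** — spikes at `k·period` for `k·period < duration`, optional
  Gaussian timing jitter; the `F(T) → 0`, `CV = 0` control.
- **Fractional Gaussian noise** — exact synthesis by circulant embedding
  (Davies–Harte): the target autocovariance
  `γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})` is embedded in a
  circulant matrix whose eigenvalues are obtained by FFT; a negative
  eigenvalue raises an explicit error rather than silently truncating.
  Output is exact-in-distribution, zero mean, unit variance.
- **Fractal ISI trains** — `ISIᵢ = mean_isi · exp(σ gᵢ − σ²/2)` with
  `g = fGn(target_H)`; the lognormal link guarantees positive intervals
  with expectation `mean_isi`, and the monotone transform approximately
  preserves long-range dependence (recovery is validated to within ±0.1,
  not exactness). Default dispersion σ = 0.5, a moderately variable unit.
- **Entrained trains** — each 20 ms cycle of the 50 Hz stimulus either
  elicits one spike or fails; the success indicator is
  `fGn(failure_H) ≥ z₁₋ₚ`, which gives exact marginal probability `p` with
  long-range-correlated successes. This mirrors intermittent axonal
  conduction block producing nested spike clusters at n×20 ms without a
  biophysical membrane model. Spikes sit at a preferred phase, default
  three-quarters of the cycle (the negative peak of a sine starting at
  phase 0), plus Gaussian jitter (default 1 ms). Note the *realized*
  coupling ratio of a single 60 s train fluctuates far more than a
  binomial count when `failure_H` is high — the mean of correlated
  indicators converges slowly — so single-train rates of 0.60–0.77 at
  `p = 0.65` are expected behavior, not a calibration error.
- **Baseline firing** — a two-component ISI mixture: with probability
  `burst_fraction` a short lognormal "burst" interval (mode ≈5 ms), else a
  long-range-correlated lognormal interval whose mean is set so the
  overall rate matches the target. Pyramidal-like defaults: 2.4 spikes/s,
  burst fraction 0.35; interneuron-like: 9.1 spikes/s, burst fraction
  0.05. The burst component is drawn independently (bursts dilute, not
  carry, the long-range correlation); the non-burst component uses
  `target_H = 0.55`, a weakly persistent baseline. No quantitative model
  of baseline bursting is claimed as ground truth; the burst fraction is
  an exposed parameter.
- **Shuffle surrogate** — a seeded random permutation of the intervals:
  preserves the ISI distribution exactly while destroying temporal order,
  the standard control that sends `H` to the independent reference and
  `α` to ≈0.

What the generators do *not* emulate: extracellular waveforms, spike
sorting errors and doublet contamination, nonstationary rate drift within
an epoch, refractory interactions between the burst and slow components,
and network covariation between units. Passing tests therefore demonstrate
estimator correctness and sensitivity under controlled long-range
structure — not robustness to every artifact of in-vivo recordings.

## Cohort pipeline

`run_experiment` generates per unit a baseline and a stimulation train
(defaults: 25 pyramidal-like and 14 interneuron-like units; stimulation =
50 Hz entrainment with `p = 0.10` for pyramidal and `p = 0.65` for
interneuron units, `failure_H = 0.8`), computes all metrics (rate, CV,
ApEn, 0–8 ms and 19–21 ms fractions, α, H), and assembles mean ± SD
summaries plus per-metric group tests: Shapiro–Wilk per condition followed
by a paired *t*-test on per-unit differences (stimulation − baseline).
Raw p-values are reported without multiple-testing correction, matching
the analysis convention the tables follow; two-sided by default with a
one-sided option for directional hypotheses. An unpaired comparison
between cell types is available with Welch's test as the default (pooled
variance optional). Units failing a metric (e.g. too few spikes for R/S)
are excluded pairwise per metric; a test needs ≥3 complete pairs, and the
run fails only if no metric has them. Shapiro–Wilk is reported as NaN for
constant samples, where normality is undefined. Per-unit seeds derive from
one `SeedSequence`, so a cohort is fully reproducible from (config, seed),
and every saved run logs seed, config hash and package version.

With these defaults the synthetic cohort reproduces the qualitative
stimulation effects the estimators are designed to detect — higher rate,
higher 19–21 ms fraction, higher α and higher H under stimulation for both
cell types — which the acceptance-style tests assert at one-sided
p < 0.05.

## Problem sizes and runtime choices

Simulation sizes in tests balance statistical power against a small
runtime: fGn exactness uses n = 16384 with 4 Bartlett standard errors;
Hurst loop-closure uses N = 4096 with 20 seeds (at N = 2048 the raw-R/S
bias already shifts the independent reference to ≈0.59); the null
calibration of the paired tests uses 40 replicate 8-unit cohorts on the
fast metrics. The full default suite runs in well under a minute.

## Known limitations

- Raw R/S bias (above): absolute H values at N ≲ a few thousand carry a
  +0.05–0.1 offset for weakly correlated inputs; comparisons against
  surrogates or between conditions are the reliable use.
- The lognormal link attenuates the driving fGn correlation slightly
  (more for antipersistent targets), so recovered H underestimates the
  distance from 0.5 on the antipersistent side.
- Fano α for a single 60 s record uses at most ~190 windows at the small-T
  end and 6 at T = 10 s; per-unit α estimates are correspondingly noisy,
  which the cohort statistics absorb by pairing.
- ApEn is O(N²) in memory and time; fine for one-minute trains
  (N ≲ 3000), not for hour-long recordings.
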