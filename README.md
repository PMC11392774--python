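# spikefractal

Fractal analysis of neuronal spike trains: Fano-factor scaling exponents,
rescaled-range Hurst exponents, approximate entropy and inter-spike-interval
(ISI) pattern statistics, together with seeded synthetic spike-train
generators and a cohort pipeline with paired group statistics.

## The problem

Sustained sinusoidal electrical stimulation of afferent axons (e.g. 50 Hz at
hippocampal Schaffer collaterals) entrains downstream neurons: units fire
near a preferred phase of the stimulation cycle, but they skip cycles —
intermittent conduction block and synaptic failure prevent one-spike-per-cycle
following. The resulting ISI distribution has peaks at integer multiples of
the 20 ms stimulation period, and the cycle-skipping itself can be
long-range correlated, producing *fractal* rather than periodic firing.
Two classic indices quantify such long-range correlations:

- **Fano factor** `F(T) = var(Nᵢ(T)) / mean(Nᵢ(T))`, the variance-to-mean
  ratio of spike counts in non-overlapping windows of size `T`.
  `F(T) ≈ 1` for Poisson firing, `F(T) → 0` for periodic firing, and
  `F(T) ∝ T^α` over a scaling region for fractal firing. The scaling
  exponent `α` (double-log slope, fitted over `10^-0.5` – `10` s by default)
  has a theoretical ceiling of 1 for this estimator.
- **Hurst exponent** `H` by rescaled-range (R/S) analysis of the ISI
  sequence: segments of length `d` (from 4 to `N/3`) yield the mean ratio of
  the range of cumulative mean-deviations to the segment SD, `(R/S)_d`;
  `H` is the double-log slope of `(R/S)_d` versus `d`. `H = 0.5` means
  independent ISIs, `H > 0.5` persistent and `H < 0.5` antipersistent
  long-range correlations.

The package also computes the coefficient of variation (CV), approximate
entropy (ApEn, `m = 2`, `r = 0.15 × SD`) and ISI-range fractions (0–8 ms
burst fraction, 19–21 ms entrainment fraction), and includes generators
whose ground truth is known — homogeneous Poisson, periodic, fractional
Gaussian noise (fGn)–driven fractal ISI trains, and 50 Hz-entrained trains
with correlated cycle-skipping — so every estimator can be validated by
parameter recovery. It is aimed at electrophysiologists and computational
neuroscientists analyzing single-unit recordings under periodic stimulation.

## Worked example

Simulate one minute of 50 Hz-entrained firing (per-cycle response
probability 0.65, strongly persistent cycle-skipping) and analyze it:

```python
import spikefractal as sf

cfg = sf.EntrainmentConfig(per_cycle_probability=0.65, failure_H=0.8, seed=1)
train = sf.generate_entrained_train(cfg)
isis = sf.to_isi(train)

print(f"rate      = {sf.firing_rate(train):.2f} spikes/s")
print(f"CV        = {sf.cv(isis):.3f}")
print(f"ApEn      = {sf.apen(isis):.3f}")
print(f"frac 19-21 ms = {sf.isi_fraction(isis, 19, 21):.3f}")
print(f"ISI peak  = {sf.isi_histogram(isis).dominant_peak_ms:.0f} ms")

curve = sf.fano_curve(train)
print(f"Fano alpha = {sf.fano_alpha(curve):.3f}  (fit r2 = {curve.fit_r2:.3f})")
print(f"Hurst H    = {sf.hurst_of(isis):.3f}")

sur = sf.shuffle_surrogate(isis, seed=2)
print(f"surrogate H = {sf.hurst_of(sur):.3f}")
```

Output:

```
rate      = 33.85 spikes/s
CV        = 0.924
ApEn      = 0.776
frac 19-21 ms = 0.420
ISI peak  = 20 ms
Fano alpha = 0.321  (fit r2 = 0.757)
Hurst H    = 0.692
surrogate H = 0.591
```

The unit fires at about 34 spikes/s — a coupling ratio of ~0.68 relative to
the 50 Hz stimulus — with its dominant ISI at one stimulation period (20 ms)
and 42% of intervals inside the 19–21 ms band. The positive Fano slope and
`H ≈ 0.69 > 0.5` indicate persistent long-range correlations contributed by
the correlated cycle-skipping; shuffling the same intervals destroys the
temporal structure and pulls the estimate back to the estimator's
independent-ISI reference (≈0.58 at this length; raw R/S reads slightly
above 0.5 for finite series).

### Command line

```bash
spikefractal simulate --model entrained --seed 1 -o train.csv
spikefractal analyze train.csv -o metrics.json
spikefractal experiment --seed 0 -o results/   # full 25+14-unit cohort
```

`experiment` generates a cohort of pyramidal-like (bursty, ~2.4 spikes/s
baseline) and interneuron-like (scattered, ~9 spikes/s baseline) units,
their stimulated counterparts, and writes `per_unit.csv`, `summary.csv`
(mean ± SD per cell type × condition × metric) and `tests.json`
(Shapiro–Wilk and paired *t* per metric).

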