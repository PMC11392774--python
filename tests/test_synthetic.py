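"""Generators: determinism, distributional ground truth, fGn exactness."""

import numpy as np
import pytest
from scipy import stats

import spikefractal as sf
from oracles import fgn_autocov_closed_form


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "make",
    [
        lambda s: sf.generate_poisson(20, 60, s).timestamps,
        lambda s: sf.generate_periodic(0.02, 60, 0.001, s).timestamps,
        lambda s: sf.generate_fgn(512, 0.7, s),
        lambda s: sf.generate_fractal_isi_train(
            sf.FractalTrainConfig(target_H=0.7, n_spikes=256, seed=s)
        ).timestamps,
        lambda s: sf.generate_entrained_train(
            sf.EntrainmentConfig(seed=s)
        ).timestamps,
        lambda s: sf.generate_baseline_train(
            sf.BaselineConfig.pyramidal(seed=s)
        ).timestamps,
    ],
    ids=["poisson", "periodic", "fgn", "fractal", "entrained", "baseline"],
)
def test_generators_bit_identical_under_fixed_seed(make):
    np.testing.assert_array_equal(make(42), make(42))


# ---------------------------------------------------------------------------
# Poisson control
# ---------------------------------------------------------------------------

def test_poisson_count_within_99pct_interval(poisson_train):
    mean = 20 * 60
    lo, hi = stats.poisson.interval(0.99, mean)
    assert lo <= poisson_train.n_spikes <= hi


def test_poisson_isi_cv_is_one():
    """Exponential ISIs have CV = 1 analytically; check the seed average."""
    cvs = [
        sf.cv(sf.to_isi(sf.generate_poisson(20, 60, seed)))
        for seed in range(20)
    ]
    assert np.mean(cvs) == pytest.approx(1.0, abs=0.05)


def test_poisson_rejects_bad_parameters():
    with pytest.raises(sf.InvalidParameterError):
        sf.generate_poisson(-1.0, 60)
    with pytest.raises(sf.InvalidParameterError):
        sf.generate_poisson(10.0, 0.0)


# ---------------------------------------------------------------------------
# periodic control
# ---------------------------------------------------------------------------

def test_periodic_zero_jitter_construction(periodic_train):
    assert periodic_train.n_spikes == 3000
    isis = np.diff(periodic_train.timestamps)
    np.testing.assert_allclose(isis, 0.02, rtol=0, atol=1e-12)
    assert sf.cv(sf.to_isi(periodic_train)) == pytest.approx(0.0, abs=1e-9)


def test_periodic_jitter_coverage_matches_normal_model():
    """ISI = 20 ms + difference of two N(0, 1 ms) jitters, so SD sqrt(2) ms;
    the 19-21 ms band holds 2*Phi(1/sqrt(2)) - 1 of the intervals."""
    expected = 2 * stats.norm.cdf(1 / np.sqrt(2)) - 1
    fracs = [
        sf.isi_fraction(
            sf.to_isi(sf.generate_periodic(0.02, 60, jitter_sd=0.001, seed=s)),
            19.0, 21.0,
        )
        for s in range(10)
    ]
    assert np.mean(fracs) == pytest.approx(expected, abs=0.02)


def test_periodic_rejects_period_longer_than_record():
    with pytest.raises(sf.InvalidParameterError):
        sf.generate_periodic(period=60.0, duration=60.0)


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def test_fgn_closed_form_autocovariance_white_noise_case():
    g05 = sf.fgn_autocovariance(np.arange(1, 11), 0.5)
    np.testing.assert_allclose(g05, 0.0, atol=1e-12)
    n = 16384
    x = sf.generate_fgn(n, 0.5, seed=3)
    lag1 = np.mean(x[:-1] * x[1:])
    assert abs(lag1) < 3 / np.sqrt(n)


@pytest.mark.parametrize("H", [0.3, 0.5, 0.8])
def test_fgn_sample_autocovariance_matches_closed_form(H):
    """Sample autocovariance at lags 0-10 within 4 Bartlett standard errors
    of gamma(k) for n = 16384."""
    n = 16384
    x = sf.generate_fgn(n, H, seed=7)
    gamma = np.array([fgn_autocov_closed_form(k, H) for k in range(n)])
    # Bartlett-type large-sample SE for autocovariance estimates
    se = np.sqrt((gamma[0] ** 2 + 2 * np.sum(gamma[1:] ** 2)) / n)
    for k in range(11):
        est = np.mean(x[: n - k] * x[k:])
        assert abs(est - gamma[k]) < 4 * max(se, 1e-3), f"lag {k}"


def test_fgn_normalization():
    x = sf.generate_fgn(4096, 0.7, seed=5)
    assert np.mean(x) == pytest.approx(0.0, abs=4 / np.sqrt(4096) * 3)
    assert np.var(x) == pytest.approx(1.0, abs=0.15)


def test_fgn_rejects_bad_H():
    for H in (0.0, 1.0, -0.3, 1.7):
        with pytest.raises(sf.InvalidParameterError):
            sf.generate_fgn(128, H, seed=0)
    with pytest.raises(sf.InvalidParameterError):
        sf.generate_fgn(1, 0.5, seed=0)


# ---------------------------------------------------------------------------
# fractal ISI trains
# ---------------------------------------------------------------------------

def test_fractal_train_isis_positive_and_timed(fractal_train):
    isis = np.diff(fractal_train.timestamps)
    assert np.all(isis > 0)
    assert fractal_train.duration == pytest.approx(fractal_train.timestamps[-1])


def test_fractal_train_zero_dispersion_is_periodic():
    tr = sf.generate_fractal_isi_train(
        sf.FractalTrainConfig(target_H=0.7, mean_isi=0.05, isi_dispersion=0.0,
                              n_spikes=100, seed=0)
    )
    np.testing.assert_allclose(np.diff(tr.timestamps), 0.05, rtol=1e-12)


def test_fractal_train_independent_case_recovers_half():
    """target_H = 0.5 drives the ISIs with white noise; the estimated Hurst
    exponent stays near 0.5 (allowing the R/S small-sample bias)."""
    hs = [
        sf.hurst_of(
            sf.to_isi(
                sf.generate_fractal_isi_train(
                    sf.FractalTrainConfig(target_H=0.5, n_spikes=4096, seed=s)
                )
            )
        )
        for s in range(8)
    ]
    assert np.mean(hs) == pytest.approx(0.5, abs=0.08)


# ---------------------------------------------------------------------------
# entrainment
# ---------------------------------------------------------------------------

def test_entrained_full_coupling_is_periodic_at_20ms():
    tr = sf.generate_entrained_train(
        sf.EntrainmentConfig(per_cycle_probability=1.0, phase_jitter_sd=0.0, seed=0)
    )
    np.testing.assert_allclose(np.diff(tr.timestamps), 0.02, atol=1e-12)
    assert sf.firing_rate(tr) == pytest.approx(50.0, abs=1.0 / 60)


def test_entrained_marginal_rate_binomial_interval_when_independent():
    """With failure_H = 0.5 cycle successes are independent, so the spike
    count must sit inside the binomial 99% interval of p."""
    p, n_cycles = 0.65, 3000
    cfg = sf.EntrainmentConfig(per_cycle_probability=p, failure_H=0.5, seed=17)
    tr = sf.generate_entrained_train(cfg)
    lo, hi = stats.binom.interval(0.99, n_cycles, p)
    assert lo <= tr.n_spikes <= hi


def test_entrained_mean_rate_approximates_p_times_frequency():
    """Mean rate over seeds ~ p * f even with correlated skipping (the
    per-seed spread is wide at failure_H = 0.8, the mean is not)."""
    rates = [
        sf.firing_rate(sf.generate_entrained_train(sf.EntrainmentConfig(seed=s)))
        for s in range(10)
    ]
    assert np.mean(rates) == pytest.approx(0.65 * 50, rel=0.1)


def test_entrained_isi_peaks_at_stimulation_period_multiples(entrained_train):
    hist = sf.isi_histogram(sf.to_isi(entrained_train))
    assert hist.dominant_peak_ms == 20.0


def test_entrained_rejects_zero_probability():
    with pytest.raises(sf.InvalidParameterError):
        sf.generate_entrained_train(
            sf.EntrainmentConfig(per_cycle_probability=0.0, seed=0)
        )


# ---------------------------------------------------------------------------
# baseline firing
# ---------------------------------------------------------------------------

def test_baseline_pyramidal_is_bursty_at_target_rate():
    rates, fracs = [], []
    for s in range(6):
        tr = sf.generate_baseline_train(sf.BaselineConfig.pyramidal(seed=s))
        rates.append(sf.firing_rate(tr))
        fracs.append(sf.isi_fraction(sf.to_isi(tr), 0.0, 8.0))
    assert np.mean(rates) == pytest.approx(2.4, rel=0.25)
    assert 0.2 < np.mean(fracs) < 0.5  # ~burst_fraction of short ISIs


def test_baseline_interneuron_is_scattered_at_target_rate():
    rates, fracs = [], []
    for s in range(6):
        tr = sf.generate_baseline_train(sf.BaselineConfig.interneuron(seed=s))
        rates.append(sf.firing_rate(tr))
        fracs.append(sf.isi_fraction(sf.to_isi(tr), 0.0, 8.0))
    assert np.mean(rates) == pytest.approx(9.1, rel=0.2)
    assert np.mean(fracs) < 0.15


# ---------------------------------------------------------------------------
# shuffle surrogate
# ---------------------------------------------------------------------------

def test_shuffle_preserves_interval_multiset_and_moments(fractal_train):
    isis = sf.to_isi(fractal_train)
    sur = sf.shuffle_surrogate(isis, seed=9)
    np.testing.assert_allclose(
        np.sort(sur.intervals), np.sort(isis.intervals), rtol=0, atol=0
    )
    assert sur.mean_isi == pytest.approx(isis.mean_isi)
    assert sur.sd_isi == pytest.approx(isis.sd_isi)
    assert sur.cv == pytest.approx(isis.cv)
    assert not np.array_equal(sur.intervals, isis.intervals)


def test_shuffle_requires_two_intervals():
    with pytest.raises(sf.InsufficientDataError):
        sf.shuffle_surrogate(sf.ISISequence(intervals=np.array([0.1])), seed=0)
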