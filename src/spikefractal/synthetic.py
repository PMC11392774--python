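"""Seeded spike-train generators with controlled temporal structure.

The analysis pipeline (Fano-factor scaling, rescaled-range Hurst exponent)
is calibrated against trains whose ground truth is known:

* homogeneous Poisson trains (uncorrelated ISIs, Fano factor ~ 1, H ~ 0.5),
* periodic trains (Fano factor -> 0),
* fractal trains whose ISIs carry long-range correlations with a target
  Hurst exponent, built on exact fractional Gaussian noise (fGn),
* trains entrained to 50 Hz sinusoidal stimulation with stochastic
  cycle-skipping, so that ISIs fall at integer multiples of the 20 ms
  stimulation period and the skip process itself is long-range correlated,
* bursty / scattered baseline firing resembling hippocampal pyramidal
  cells and interneurons before stimulation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exceptions import (
    EmbeddingError,
    InsufficientDataError,
    InvalidParameterError,
)
from .trains import ISISequence, SpikeTrain

__all__ = [
    "fgn_autocovariance",
    "generate_fgn",
    "generate_poisson",
    "generate_periodic",
    "FractalTrainConfig",
    "generate_fractal_isi_train",
    "EntrainmentConfig",
    "generate_entrained_train",
    "BaselineConfig",
    "generate_baseline_train",
    "shuffle_surrogate",
]


# ---------------------------------------------------------------------------
# Fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(lags: np.ndarray | int, H: float) -> np.ndarray:
    """Autocovariance of unit-variance fGn with Hurst exponent ``H``.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    k = np.abs(np.atleast_1d(np.asarray(lags, dtype=float)))
    two_h = 2.0 * H
    return 0.5 * (
        np.abs(k + 1) ** two_h - 2 * k**two_h + np.abs(k - 1) ** two_h
    )


def generate_fgn(n: int, H: float, seed: int | np.random.Generator) -> np.ndarray:
    """Exact synthesis of fractional Gaussian noise by circulant embedding.

    Returns ``n`` samples of a zero-mean, unit-variance stationary Gaussian
    sequence whose autocovariance is exactly the fGn autocovariance for
    Hurst exponent ``H`` (Davies-Harte construction).  For H = 0.5 the
    output is white noise.

    Raises
    ------
    InvalidParameterError
        If ``H`` is outside (0, 1) or ``n < 2``.
    EmbeddingError
        If the circulant embedding has a negative eigenvalue for this
        ``(n, H)`` (the synthesis is never silently truncated).
    """
    if not 0.0 < H < 1.0:
        raise InvalidParameterError(f"H must be in (0, 1), got {H}")
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    gamma = fgn_autocovariance(np.arange(n + 1), H)
    # first row of the 2n x 2n circulant: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if np.min(lam) < -1e-10 * np.max(lam):
        raise EmbeddingError(
            f"circulant embedding not positive semi-definite for n={n}, H={H}"
        )
    lam = np.clip(lam, 0.0, None)

    m = 2 * n
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u + 1j * v)
    w[n + 1 :] = np.conj(w[n - 1 : 0 : -1])
    return np.fft.fft(w).real[:n]


# ---------------------------------------------------------------------------
# Control trains
# ---------------------------------------------------------------------------

def generate_poisson(
    rate: float,
    duration: float = 60.0,
    seed: int | np.random.Generator = 0,
    **train_kwargs,
) -> SpikeTrain:
    """Homogeneous Poisson spike train: i.i.d. exponential ISIs, mean 1/rate."""
    if rate <= 0:
        raise InvalidParameterError(f"rate must be > 0, got {rate}")
    if duration <= 0:
        raise InvalidParameterError(f"duration must be > 0, got {duration}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # draw with margin, extend in the rare case the record is not covered
    n_guess = max(16, int(rate * duration * 1.5) + 4 * int(np.sqrt(rate * duration) + 1))
    isis = rng.exponential(1.0 / rate, size=n_guess)
    t = np.cumsum(isis)
    while t[-1] < duration:
        extra = rng.exponential(1.0 / rate, size=n_guess)
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return SpikeTrain(timestamps=t[t <= duration], duration=duration, **train_kwargs)


def generate_periodic(
    period: float,
    duration: float = 60.0,
    jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    **train_kwargs,
) -> SpikeTrain:
    """Periodic spike train at k*period with optional Gaussian timing jitter.

    With ``jitter_sd = 0`` the train is strictly periodic and its Fano
    factor vanishes at counting windows that are multiples of the period.
    """
    if period <= 0:
        raise InvalidParameterError(f"period must be > 0, got {period}")
    if jitter_sd < 0:
        raise InvalidParameterError(f"jitter_sd must be >= 0, got {jitter_sd}")
    if period >= duration:
        raise InvalidParameterError(
            f"period {period} >= duration {duration}: fewer than 2 spikes"
        )
    # spikes at k*period for k*period < duration (e.g. 3000 spikes at 20 ms / 60 s)
    n = int(np.ceil(duration / period - 1e-9))
    t = np.arange(n) * period
    if jitter_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        t = np.sort(t + rng.normal(0.0, jitter_sd, size=t.size))
        t = t[(t >= 0) & (t <= duration)]
    return SpikeTrain(timestamps=t, duration=duration, **train_kwargs)


# ---------------------------------------------------------------------------
# Fractal ISI trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FractalTrainConfig:
    """Long-range-correlated ISI train driven by fGn through a lognormal link.

    ISI_i = mean_isi * exp(sigma * g_i - sigma^2 / 2) with g = fGn(target_H),
    so intervals are strictly positive with expectation ``mean_isi`` and the
    Hurst exponent of the ISI sequence is approximately ``target_H`` (the
    monotone log link preserves long-range dependence).
    """

    target_H: float = 0.7
    mean_isi: float = 0.05
    isi_dispersion: float = 0.5
    n_spikes: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_H < 1.0:
            raise InvalidParameterError("target_H must be in (0, 1)")
        if self.mean_isi <= 0:
            raise InvalidParameterError("mean_isi must be > 0")
        if self.isi_dispersion < 0:
            raise InvalidParameterError("isi_dispersion must be >= 0")
        if self.n_spikes < 2:
            raise InvalidParameterError("n_spikes must be >= 2")


def generate_fractal_isi_train(config: FractalTrainConfig, **train_kwargs) -> SpikeTrain:
    """Generate a spike train whose ISIs have tunable long-range correlations."""
    n_isi = config.n_spikes - 1
    sigma = config.isi_dispersion
    if sigma == 0.0:
        isis = np.full(n_isi, config.mean_isi)
    else:
        if n_isi < 2:
            g = np.zeros(n_isi)
        else:
            g = generate_fgn(n_isi, config.target_H, config.seed)
        isis = config.mean_isi * np.exp(sigma * g - 0.5 * sigma**2)
    t = np.concatenate([[0.0], np.cumsum(isis)])
    return SpikeTrain(timestamps=t, duration=float(t[-1]), **train_kwargs)


# ---------------------------------------------------------------------------
# Sinusoidal entrainment with fractal cycle-skipping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntrainmentConfig:
    """Spike train entrained to sinusoidal stimulation with cycle skipping.

    Each stimulation cycle (period ``1/stim_frequency``; 20 ms at the
    default 50 Hz) either elicits one spike or fails.  The success
    indicator of cycle k is ``fGn_k >= z_{1-p}``, which has exact marginal
    probability ``per_cycle_probability`` while successive successes carry
    long-range correlations controlled by ``failure_H`` — the stochastic
    analogue of intermittent axonal conduction block, which produces ISIs
    at n-fold multiples of the stimulation period.  Spikes are placed at a
    preferred phase within the cycle (default three-quarters of the cycle,
    the negative peak of a sine starting at phase 0) plus Gaussian jitter.
    """

    stim_frequency: float = 50.0
    per_cycle_probability: float = 0.65
    failure_H: float = 0.8
    phase_jitter_sd: float = 0.001
    preferred_phase_offset: float | None = None
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stim_frequency <= 0:
            raise InvalidParameterError("stim_frequency must be > 0")
        if not 0.0 <= self.per_cycle_probability <= 1.0:
            raise InvalidParameterError("per_cycle_probability must be in [0, 1]")
        if not 0.0 < self.failure_H < 1.0:
            raise InvalidParameterError("failure_H must be in (0, 1)")
        if self.phase_jitter_sd < 0:
            raise InvalidParameterError("phase_jitter_sd must be >= 0")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")

    @property
    def cycle_period(self) -> float:
        return 1.0 / self.stim_frequency

    @property
    def phase_offset(self) -> float:
        if self.preferred_phase_offset is not None:
            return self.preferred_phase_offset
        return 0.75 * self.cycle_period


def generate_entrained_train(config: EntrainmentConfig, **train_kwargs) -> SpikeTrain:
    """Simulate stimulation-entrained firing with correlated cycle-skipping."""
    p = config.per_cycle_probability
    if p == 0.0:
        raise InvalidParameterError("per_cycle_probability = 0 gives an empty train")
    period = config.cycle_period
    n_cycles = int(np.floor(config.duration / period))
    if n_cycles < 2:
        raise InsufficientDataError("duration too short for 2 stimulation cycles")
    rng = np.random.default_rng(config.seed)
    if p >= 1.0:
        success = np.ones(n_cycles, dtype=bool)
    else:
        g = generate_fgn(n_cycles, config.failure_H, rng)
        success = g >= stats.norm.ppf(1.0 - p)
    cycles = np.nonzero(success)[0]
    t = cycles * period + config.phase_offset
    if config.phase_jitter_sd > 0:
        t = np.sort(t + rng.normal(0.0, config.phase_jitter_sd, size=t.size))
    t = t[(t >= 0) & (t <= config.duration)]
    train_kwargs.setdefault("condition", "stimulation")
    return SpikeTrain(timestamps=t, duration=config.duration, **train_kwargs)


# ---------------------------------------------------------------------------
# Baseline (pre-stimulation) firing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineConfig:
    """Spontaneous baseline firing of hippocampal units.

    Pyramidal cells fire in bursts: a fraction ``burst_fraction`` of ISIs is
    drawn from a short lognormal component with mode near ``burst_isi``
    (~5 ms), the remainder from a long-range-correlated lognormal component
    whose mean is set so the overall rate matches ``rate``.  Interneurons
    fire in a scattered pattern: use ``burst_fraction = 0`` (or small) and a
    higher rate.  ``target_H`` sets the weak long-range correlation of the
    non-burst ISIs.
    """

    rate: float = 2.4
    burst_fraction: float = 0.35
    burst_isi: float = 0.005
    burst_isi_dispersion: float = 0.3
    target_H: float = 0.55
    isi_dispersion: float = 0.6
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidParameterError("rate must be > 0")
        if not 0.0 <= self.burst_fraction < 1.0:
            raise InvalidParameterError("burst_fraction must be in [0, 1)")
        if not 0.0 < self.target_H < 1.0:
            raise InvalidParameterError("target_H must be in (0, 1)")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")

    @classmethod
    def pyramidal(cls, seed: int = 0, **kw) -> "BaselineConfig":
        """Bursty pyramidal-cell baseline (~2.4 spikes/s, ISI mode ~5 ms)."""
        kw.setdefault("rate", 2.4)
        kw.setdefault("burst_fraction", 0.35)
        return cls(seed=seed, **kw)

    @classmethod
    def interneuron(cls, seed: int = 0, **kw) -> "BaselineConfig":
        """Scattered interneuron baseline (~9.1 spikes/s, few short ISIs)."""
        kw.setdefault("rate", 9.1)
        kw.setdefault("burst_fraction", 0.05)
        return cls(seed=seed, **kw)


def generate_baseline_train(config: BaselineConfig, **train_kwargs) -> SpikeTrain:
    """Generate spontaneous baseline firing (bursty or scattered)."""
    rng = np.random.default_rng(config.seed)
    q = config.burst_fraction
    mean_isi_total = 1.0 / config.rate
    # mean of the slow component so that the ISI mixture mean hits 1/rate
    mean_burst = config.burst_isi * np.exp(0.5 * config.burst_isi_dispersion**2)
    mean_slow = (mean_isi_total - q * mean_burst) / (1.0 - q)
    if mean_slow <= 0:
        raise InvalidParameterError(
            "rate too high for the requested burst fraction / burst ISI"
        )
    n_isi = max(16, int(np.ceil(config.rate * config.duration * 2)) + 32)
    g = generate_fgn(n_isi, config.target_H, rng)
    sigma = config.isi_dispersion
    slow = mean_slow * np.exp(sigma * g - 0.5 * sigma**2)
    isis = slow
    if q > 0:
        is_burst = rng.random(n_isi) < q
        burst = config.burst_isi * np.exp(
            config.burst_isi_dispersion * rng.standard_normal(n_isi)
        )
        isis = np.where(is_burst, burst, slow)
    t = np.concatenate([[0.0], np.cumsum(isis)])
    t = t[t <= config.duration]
    if t.size < 2:
        raise InsufficientDataError("baseline generator produced < 2 spikes")
    train_kwargs.setdefault("condition", "baseline")
    return SpikeTrain(timestamps=t, duration=config.duration, **train_kwargs)


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------

def shuffle_surrogate(isis: ISISequence, seed: int | np.random.Generator = 0) -> ISISequence:
    """Random permutation of the intervals.

    Destroys the temporal ordering (and with it any long-range correlation)
    while preserving the ISI distribution exactly; the standard surrogate
    control for the Hurst and Fano analyses.
    """
    if isis.n < 2:
        raise InsufficientDataError("need >= 2 intervals to shuffle")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return ISISequence(
        intervals=rng.permutation(isis.intervals),
        unit_id=isis.unit_id,
        condition=isis.condition,
    )
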