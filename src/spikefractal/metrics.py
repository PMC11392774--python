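"""First-order per-unit firing statistics.

ISI extraction, mean firing rate, coefficient of variation, ISI-range
fractions and probability histogram, and the Approximate Entropy (ApEn) of
the ISI sequence.  Conventions used throughout: sample standard deviation
with N-1 denominator; ISI bins are half-open ``[lo, hi)`` in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import InsufficientDataError, InvalidParameterError
from .trains import ISISequence, SpikeTrain

__all__ = [
    "to_isi",
    "firing_rate",
    "cv",
    "isi_fraction",
    "ISIHistogram",
    "isi_histogram",
    "ApEnConfig",
    "apen",
]


def to_isi(train: SpikeTrain) -> ISISequence:
    """Consecutive differences of the spike timestamps, order preserved."""
    if train.n_spikes < 2:
        raise InsufficientDataError(
            f"need >= 2 spikes for ISIs, got {train.n_spikes}"
        )
    return ISISequence(
        intervals=np.diff(train.timestamps),
        unit_id=train.unit_id,
        condition=train.condition,
    )


def firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate: spike count / record duration (spikes/s)."""
    return train.n_spikes / train.duration


def cv(isis: ISISequence) -> float:
    """Coefficient of variation of the ISIs: sample SD (N-1) / mean.

    0 for perfectly periodic firing, ~1 for Poisson firing.
    """
    if isis.n < 2:
        raise InsufficientDataError("CV needs >= 2 intervals")
    return isis.cv


def isi_fraction(isis: ISISequence, lo_ms: float, hi_ms: float) -> float:
    """Proportion of intervals with ``lo_ms <= ISI < hi_ms`` (half-open)."""
    if lo_ms >= hi_ms:
        raise InvalidParameterError(f"need lo < hi, got [{lo_ms}, {hi_ms})")
    iv_ms = isis.intervals * 1000.0
    return float(np.mean((iv_ms >= lo_ms) & (iv_ms < hi_ms)))


@dataclass(frozen=True)
class ISIHistogram:
    """Probability-normalized ISI histogram (bins in milliseconds)."""

    bin_edges: np.ndarray
    bin_probabilities: np.ndarray
    bin_width: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def dominant_peak_ms(self) -> float:
        """Bin center (ms) of the highest-probability bin."""
        return float(self.bin_centers[int(np.argmax(self.bin_probabilities))])


def isi_histogram(
    isis: ISISequence, bin_width_ms: float = 1.0, max_isi_ms: float = 200.0
) -> ISIHistogram:
    """Histogram of ISIs on half-open 1-ms bins, normalized to probabilities.

    Bins are centered on integer multiples of ``bin_width_ms`` (edges at
    half-widths, ``[k - w/2, k + w/2)``), so intervals concentrated at a
    stimulation period (e.g. 20, 40, 60 ms under 50 Hz entrainment) fall at
    a bin center instead of straddling an edge.  Intervals beyond
    ``max_isi_ms`` are collected in the final bin so the probabilities sum
    to 1 over all intervals counted.
    """
    if bin_width_ms <= 0:
        raise InvalidParameterError("bin_width_ms must be > 0")
    iv_ms = isis.intervals * 1000.0
    n_bins = int(np.ceil(max_isi_ms / bin_width_ms)) + 1
    edges = (np.arange(n_bins + 1) - 0.5) * bin_width_ms
    idx = np.floor(iv_ms / bin_width_ms + 0.5).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return ISIHistogram(
        bin_edges=edges,
        bin_probabilities=counts / counts.sum(),
        bin_width=bin_width_ms,
    )


@dataclass(frozen=True)
class ApEnConfig:
    """Approximate-entropy parameters.

    ``embedding_m`` is the template length (default 2) and ``r_factor`` the
    similarity tolerance expressed as a fraction of the sample SD of the
    analyzed sequence (default 0.15), the standard amplitude-invariant
    convention.
    """

    embedding_m: int = 2
    r_factor: float = 0.15

    def __post_init__(self) -> None:
        if self.embedding_m < 1:
            raise InvalidParameterError("embedding_m must be >= 1")
        if self.r_factor <= 0:
            raise InvalidParameterError("r_factor must be > 0")

    def r_absolute(self, x: np.ndarray) -> float:
        return self.r_factor * float(np.std(x, ddof=1))


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Phi^m(r): mean log of template match frequencies, self-matches included."""
    n = x.size
    n_templates = n - m + 1
    # (n_templates, m) embedding matrix
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    # Chebyshev distances between all template pairs
    dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
    c = np.count_nonzero(dist <= r, axis=1) / n_templates
    return float(np.mean(np.log(c)))


def apen(isis: ISISequence | np.ndarray, config: ApEnConfig | None = None) -> float:
    """Approximate Entropy of the ISI sequence.

    Classic ApEn(m, r): Phi^m(r) - Phi^{m+1}(r) with Chebyshev distance and
    self-matches included, ``r = r_factor * sample SD``.  Low values mean
    regular (predictable) firing, high values irregular firing.  A constant
    sequence has zero SD, hence ``r = 0`` and every template identical:
    the result is defined as 0.
    """
    config = config or ApEnConfig()
    x = isis.intervals if isinstance(isis, ISISequence) else np.asarray(isis, dtype=float)
    m = config.embedding_m
    if x.size < m + 2:
        raise InsufficientDataError(
            f"ApEn(m={m}) needs at least {m + 2} intervals, got {x.size}"
        )
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0
    r = config.r_factor * sd
    return _phi(x, m, r) - _phi(x, m + 1, r)
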