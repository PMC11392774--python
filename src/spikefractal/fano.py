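"""Fano-factor curve F(T) and its fractal scaling exponent alpha.

F(T) is the variance-to-mean ratio of spike counts in non-overlapping
windows of size T, anchored at t = 0; the remainder of the record beyond
the last complete window is discarded.  For a Poisson process F(T) ~ 1 at
every T; for periodic firing F(T) -> 0; for fractal firing F(T) grows as
T^alpha over a scaling region, with alpha the double-logarithmic slope
(theoretical ceiling 1 for this estimator).

The default counting-window grid spans 0.1-10 s (log-spaced, 10 points per
decade) and the default fit range is 10^-0.5 s (~0.32 s) to 10 s, the
region where spike trains of this kind show clean power-law scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import InsufficientDataError, InvalidParameterError
from .trains import SpikeTrain

__all__ = ["FanoCurve", "window_counts", "fano_curve", "fano_alpha"]

#: Default scaling-region fit bounds (seconds).
DEFAULT_FIT_LO = 10.0**-0.5
DEFAULT_FIT_HI = 10.0

#: Relative tolerance on window edges: a spike within EDGE_RTOL * T below an
#: edge is assigned to the upper window.  This is far below any physical
#: spike-timing resolution and makes counting robust to the floating-point
#: representation of times that lie exactly on a window boundary.
EDGE_RTOL = 1e-9

#: Minimum number of complete windows required for a window size to be kept.
MIN_WINDOWS = 4


@dataclass
class FanoCurve:
    """F(T) over a window-size grid, with the fitted scaling exponent."""

    T_grid: np.ndarray
    F_values: np.ndarray
    n_windows: np.ndarray
    dropped_T: np.ndarray = field(default_factory=lambda: np.array([]))
    alpha: float | None = None
    fit_range: tuple[float, float] | None = None
    fit_r2: float | None = None
    n_spikes: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"T_s": self.T_grid, "F": self.F_values, "n_windows": self.n_windows}
        )

    def save(self, csv_path: str | Path) -> None:
        """Write the curve as CSV plus a JSON sidecar with the fit results."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "alpha": self.alpha,
            "fit_lo": None if self.fit_range is None else self.fit_range[0],
            "fit_hi": None if self.fit_range is None else self.fit_range[1],
            "fit_r2": self.fit_r2,
            "n_spikes": self.n_spikes,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def window_counts(train: SpikeTrain, T: float) -> np.ndarray:
    """Spike counts in the floor(duration/T) complete windows of size T.

    Windows are contiguous, non-overlapping, anchored at t = 0, half-open
    ``[iT, (i+1)T)``; spikes beyond the last complete window are discarded.
    """
    if T <= 0 or T > train.duration:
        raise InvalidParameterError(f"window size T={T} outside (0, duration]")
    n = int(np.floor(train.duration / T))
    edges = np.arange(n + 1) * T - EDGE_RTOL * T
    idx = np.searchsorted(edges, train.timestamps, side="right") - 1
    idx = idx[(idx >= 0) & (idx < n)]
    return np.bincount(idx, minlength=n)


def log_grid(lo: float, hi: float, points_per_decade: int = 10) -> np.ndarray:
    if lo == hi:
        return np.array([lo])
    n_points = max(2, int(round(np.log10(hi / lo) * points_per_decade)) + 1)
    return np.logspace(np.log10(lo), np.log10(hi), n_points)


def fano_curve(
    train: SpikeTrain,
    T_min: float = 0.1,
    T_max: float = 10.0,
    points_per_decade: int = 10,
    min_windows: int = MIN_WINDOWS,
) -> FanoCurve:
    """Compute F(T) = var(N_i(T)) / mean(N_i(T)) over a log-spaced T grid.

    Sample variance uses the N-1 denominator.  Window sizes with zero mean
    count (no spikes in the counted windows) or fewer than ``min_windows``
    complete windows are excluded from the curve and reported in
    ``dropped_T``.
    """
    if train.n_spikes == 0:
        raise InsufficientDataError("empty spike train")
    if not 0 < T_min <= T_max <= train.duration:
        raise InvalidParameterError(
            f"need 0 < T_min <= T_max <= duration, got [{T_min}, {T_max}]"
        )
    kept_T, kept_F, kept_n, dropped = [], [], [], []
    for T in log_grid(T_min, T_max, points_per_decade):
        counts = window_counts(train, T)
        if counts.size < min_windows:
            dropped.append(T)
            continue
        mean = counts.mean()
        if mean == 0:
            warnings.warn(f"all-zero counts at T={T:.4g} s; window size excluded")
            dropped.append(T)
            continue
        kept_T.append(T)
        kept_F.append(counts.var(ddof=1) / mean)
        kept_n.append(counts.size)
    if not kept_T:
        raise InsufficientDataError("no usable window sizes on the grid")
    return FanoCurve(
        T_grid=np.array(kept_T),
        F_values=np.array(kept_F),
        n_windows=np.array(kept_n),
        dropped_T=np.array(dropped),
        n_spikes=train.n_spikes,
    )


def fano_alpha(
    curve: FanoCurve,
    fit_lo: float = DEFAULT_FIT_LO,
    fit_hi: float = DEFAULT_FIT_HI,
) -> float:
    """OLS slope of log10 F(T) vs log10 T restricted to the fit range.

    Stores ``alpha``, ``fit_range`` and ``fit_r2`` on the curve and returns
    alpha.  Points with non-positive F are unusable on log axes and are
    ignored; at least 4 usable grid points are required.
    """
    sel = (
        (curve.T_grid >= fit_lo * (1 - 1e-12))
        & (curve.T_grid <= fit_hi * (1 + 1e-12))
        & (curve.F_values > 0)
    )
    if np.count_nonzero(sel) < 4:
        raise InsufficientDataError(
            f"need >= 4 positive F(T) points in [{fit_lo:.3g}, {fit_hi:.3g}] s, "
            f"got {int(np.count_nonzero(sel))}"
        )
    x = np.log10(curve.T_grid[sel])
    y = np.log10(curve.F_values[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    curve.alpha = float(slope)
    curve.fit_range = (fit_lo, fit_hi)
    curve.fit_r2 = float(r2)
    return float(slope)
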