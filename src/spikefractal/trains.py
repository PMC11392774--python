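"""Core containers: spike trains and inter-spike-interval sequences.

A :class:`SpikeTrain` holds the sorted event times of one sorted unit within
a fixed-duration record (default 1 min, matching a one-minute baseline or
stimulation epoch).  An :class:`ISISequence` is the ordered sequence of
consecutive differences, the object every downstream statistic (CV, ApEn,
rescaled range) operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InsufficientDataError, InvalidParameterError

CONDITIONS = ("baseline", "stimulation")
CELL_TYPES = ("pyramidal", "interneuron", "unspecified")

#: Default record length in seconds (one-minute epochs).
DEFAULT_DURATION = 60.0


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamps of a single unit within a recording window.

    Parameters
    ----------
    timestamps
        Event times in seconds, strictly increasing, all within
        ``[0, duration]``.
    duration
        Record length in seconds (> 0).
    condition
        ``"baseline"`` or ``"stimulation"``.
    cell_type
        ``"pyramidal"``, ``"interneuron"`` or ``"unspecified"``.
    unit_id
        Identifier of the unit this train belongs to.
    """

    timestamps: np.ndarray
    duration: float = DEFAULT_DURATION
    condition: str = "baseline"
    cell_type: str = "unspecified"
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.condition not in CONDITIONS:
            raise InvalidParameterError(f"condition must be one of {CONDITIONS}")
        if self.cell_type not in CELL_TYPES:
            raise InvalidParameterError(f"cell_type must be one of {CELL_TYPES}")
        if ts.ndim != 1:
            raise InvalidParameterError("timestamps must be one-dimensional")
        if ts.size:
            if np.any(np.diff(ts) <= 0):
                raise InvalidParameterError("timestamps must be strictly increasing")
            if ts[0] < 0 or ts[-1] > self.duration:
                raise InvalidParameterError(
                    "timestamps must lie within [0, duration]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps.size)

    def shifted(self, offset: float) -> "SpikeTrain":
        """Return a copy with all timestamps shifted by ``offset`` (the
        duration is extended if needed so the invariant holds)."""
        ts = self.timestamps + offset
        dur = max(self.duration, float(ts[-1]) if ts.size else 0.0)
        return replace(self, timestamps=ts, duration=dur)


@dataclass(frozen=True)
class ISISequence:
    """Ordered inter-spike intervals of one unit (seconds, each > 0)."""

    intervals: np.ndarray
    unit_id: str = "unit0"
    condition: str = "baseline"

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.ndim != 1:
            raise InvalidParameterError("intervals must be one-dimensional")
        if iv.size and np.any(iv <= 0):
            raise InvalidParameterError("all intervals must be > 0")

    @property
    def n(self) -> int:
        return int(self.intervals.size)

    @property
    def mean_isi(self) -> float:
        return float(np.mean(self.intervals))

    @property
    def sd_isi(self) -> float:
        """Sample standard deviation (N-1 denominator)."""
        if self.n < 2:
            raise InsufficientDataError("need >= 2 intervals for a sample SD")
        return float(np.std(self.intervals, ddof=1))

    @property
    def cv(self) -> float:
        """Coefficient of variation, SD / mean."""
        return self.sd_isi / self.mean_isi


# ---------------------------------------------------------------------------
# Spike-times CSV (one row per spike: unit_id, condition, cell_type, time_s)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["unit_id", "condition", "cell_type", "time_s"]


def write_spike_csv(trains: Iterable[SpikeTrain] | SpikeTrain, path: str | Path) -> None:
    """Write one or more spike trains to a long-format CSV.

    Times are written with microsecond precision (6 decimal places) or
    better; the schema is ``unit_id,condition,cell_type,time_s``.
    """
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    frames = []
    for tr in trains:
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": tr.unit_id,
                    "condition": tr.condition,
                    "cell_type": tr.cell_type,
                    "time_s": tr.timestamps,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9f")


def read_spike_csv(
    path: str | Path, duration: float | None = None
) -> list[SpikeTrain]:
    """Read a spike-times CSV back into a list of trains.

    Rows are grouped by ``(unit_id, condition)``.  If ``duration`` is None
    the record length of each train is taken as the maximum of the default
    1-min window and its last spike time.
    """
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"spike CSV missing columns: {sorted(missing)}")
    trains = []
    for (unit, cond), grp in df.groupby(["unit_id", "condition"], sort=False):
        ts = np.sort(grp["time_s"].to_numpy(dtype=float))
        cell = str(grp["cell_type"].iloc[0])
        dur = duration if duration is not None else max(DEFAULT_DURATION, float(ts[-1]))
        trains.append(
            SpikeTrain(
                timestamps=ts,
                duration=dur,
                condition=str(cond),
                cell_type=cell,
                unit_id=str(unit),
            )
        )
    return trains
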