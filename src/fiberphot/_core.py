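"""Core data model for fiber-photometry sessions.

All times are seconds (float64). Intervals are half-open ``[start, end)``
throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

logger = logging.getLogger("fiberphot")

#: Relative tolerance on sample-interval jitter before a channel is
#: rejected as non-uniform.
UNIFORMITY_RTOL = 0.01


class FiberphotError(ValueError):
    """Raised for invalid inputs or degenerate analysis states."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled channel: timestamps (s), values, rate (Hz).

    Timestamps must be strictly increasing and evenly spaced within a
    1% jitter tolerance; values must be finite.
    """

    timestamps: np.ndarray
    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1:
            raise FiberphotError("timestamps and values must be 1-D")
        if len(t) != len(v):
            raise FiberphotError(
                f"length mismatch: {len(t)} timestamps vs {len(v)} values"
            )
        if len(t) < 2:
            raise FiberphotError(f"need >= 2 samples, got {len(t)}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise FiberphotError(
                f"timestamps not strictly increasing at index {bad}"
            )
        if not np.all(np.isfinite(v)):
            n_bad = int(np.sum(~np.isfinite(v)))
            raise FiberphotError(f"{n_bad} non-finite values in channel")
        nominal = 1.0 / self.sampling_rate
        if np.max(np.abs(dt - nominal)) >= UNIFORMITY_RTOL * nominal:
            raise FiberphotError(
                "sampling not uniform: max interval deviation "
                f"{np.max(np.abs(dt - nominal)):.3g} s exceeds 1% of "
                f"{nominal:.3g} s"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Span from first to one past the last sample, in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.sampling_rate

    @classmethod
    def from_timestamps(cls, timestamps, values) -> "TimeSeries":
        """Build a TimeSeries inferring the rate as 1/median(diff(t)).

        The median is robust to a single dropped frame.
        """
        t = np.asarray(timestamps, dtype=np.float64)
        if len(t) < 2:
            raise FiberphotError(f"need >= 2 samples, got {len(t)}")
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t, np.asarray(values, dtype=np.float64), rate)

    def with_values(self, values) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=np.float64))


@dataclass(frozen=True)
class EventStream:
    """Named behavioral event timestamps, sorted ascending, all >= 0."""

    name: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=np.float64)
        object.__setattr__(self, "timestamps", t)
        if t.ndim != 1:
            raise FiberphotError("event timestamps must be 1-D")
        if len(t) and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise FiberphotError(
                f"event stream {self.name!r}: timestamps must be sorted and >= 0"
            )

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class RecordingSession:
    """One recording: signal channel, optional isosbestic control, events."""

    signal: TimeSeries
    control: TimeSeries | None = None
    events: Mapping[str, EventStream] = field(default_factory=dict)
    session_id: str = "session"

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", dict(self.events))
        if self.control is not None:
            c, s = self.control, self.signal
            if c.timestamps[-1] <= s.timestamps[0] or s.timestamps[-1] <= c.timestamps[0]:
                raise FiberphotError(
                    "control and signal channels do not overlap in time"
                )


@dataclass(frozen=True)
class ChunkSelection:
    """Ordered, non-overlapping keep-intervals ``[start, end)`` in seconds.

    Samples and events outside every interval are excised as artifacts.
    """

    keep_intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b)) for a, b in self.keep_intervals)
        object.__setattr__(self, "keep_intervals", iv)
        if not iv:
            raise FiberphotError("keep_intervals must be non-empty")
        for a, b in iv:
            if not a < b:
                raise FiberphotError(f"interval [{a}, {b}) has start >= end")
        for (_, b0), (a1, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise FiberphotError("keep intervals overlap or are unsorted")


_ZSCORE_METHODS = ("standard", "baseline", "modified")


@dataclass(frozen=True)
class AnalysisParameters:
    """Every tunable knob of the pipeline, loadable from JSON/YAML.

    filter_window is the per-pass length (in samples) of the zero-phase
    moving-average filter; the conventional default is 100 points.
    """

    filter_window: int = 100
    trim_start: float = 0.0
    use_isosbestic: bool = True
    zscore_method: str = "standard"
    zscore_baseline_window: tuple[float, float] | None = None
    transient_window: float = 15.0
    psth_window: tuple[float, float] = (-5.0, 5.0)
    psth_baseline_window: tuple[float, float] | None = None
    measure_windows: tuple[tuple[float, float], ...] = ()
    chunks: ChunkSelection | None = None
    average_group: bool = False

    def __post_init__(self) -> None:
        if self.filter_window < 1:
            raise FiberphotError("filter_window must be >= 1")
        if self.trim_start < 0:
            raise FiberphotError("trim_start must be >= 0")
        if self.transient_window <= 0:
            raise FiberphotError("transient_window must be > 0")
        if self.zscore_method not in _ZSCORE_METHODS:
            raise FiberphotError(
                f"zscore_method must be one of {_ZSCORE_METHODS}, "
                f"got {self.zscore_method!r}"
            )
        if self.zscore_method == "baseline" and self.zscore_baseline_window is None:
            raise FiberphotError(
                "zscore_method='baseline' requires zscore_baseline_window"
            )
        a, b = self.psth_window
        if not a < b:
            raise FiberphotError(f"psth_window [A,B] needs A < B, got [{a}, {b}]")
        mw = tuple((float(s), float(e)) for s, e in self.measure_windows)
        object.__setattr__(self, "measure_windows", mw)
        if len(mw) > 5:
            raise FiberphotError(f"at most 5 measure windows, got {len(mw)}")
        for s, e in mw:
            if s < a or e > b or not s < e:
                raise FiberphotError(
                    f"measure window [{s}, {e}] not inside psth_window [{a}, {b}]"
                )
        if self.psth_baseline_window is not None:
            s, e = self.psth_baseline_window
            if s < a or e > b or not s < e:
                raise FiberphotError(
                    f"psth_baseline_window [{s}, {e}] not inside [{a}, {b}]"
                )


def interval_mask(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Boolean mask for the half-open interval [start, end)."""
    return (t >= start) & (t < end)
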