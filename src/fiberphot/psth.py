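"""Peri-event time histograms with baseline correction and window measures.

For each behavioral event e, the z trace is sampled on a uniform relative
grid t in [A, B) by nearest-sample lookup at e + t (events need not fall
on sample times; nearest lookup avoids interpolation smearing). With an
optional per-trial baseline window [a, b] in [A, B]:

    PSTH(i) = z(i) - mean(baseline samples of trial i)

Events whose window extends beyond the recording are dropped and
counted. AUC over a measurement window uses the trapezoidal rule; the
peak is the max of the mean PSTH in the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._core import EventStream, FiberphotError, TimeSeries, interval_mask

logger = logging.getLogger("fiberphot")

__all__ = [
    "PsthResult",
    "MeasureResult",
    "compute_psth",
    "measure_windows",
    "per_trial_measures",
]

MAX_MEASURE_WINDOWS = 5


@dataclass(frozen=True)
class PsthResult:
    """Trial matrix on a relative time grid, with mean and SEM.

    SEM uses the sample standard deviation (ddof=1) over sqrt(n); for a
    single trial it is reported as 0.
    """

    time: np.ndarray                 # length N, A <= t < B, uniform
    trials: np.ndarray               # n_events x N, z units
    mean: np.ndarray
    sem: np.ndarray
    event_name: str
    baseline_window: tuple[float, float] | None = None
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


@dataclass(frozen=True)
class MeasureResult:
    """Per-window AUC (z*s) and peak (z) of the mean PSTH."""

    windows: tuple[tuple[float, float], ...]
    auc: np.ndarray
    peak: np.ndarray
    event_name: str = ""


def _trial_stats(trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = trials.mean(axis=0)
    n = trials.shape[0]
    if n > 1:
        sem = trials.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros(trials.shape[1])
        logger.warning("single trial: SEM reported as 0")
    return mean, sem


def compute_psth(
    z: TimeSeries,
    events: EventStream,
    window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
) -> PsthResult:
    """Build the event-aligned trial matrix over [A, B).

    Raises if A >= B, if the baseline window is not inside [A, B], or if
    every event falls too close to a recording edge.
    """
    a_rel, b_rel = float(window[0]), float(window[1])
    if a_rel >= b_rel:
        raise FiberphotError(f"PSTH window needs A < B, got [{a_rel}, {b_rel}]")
    if baseline_window is not None:
        s, e = baseline_window
        if s < a_rel or e > b_rel or not s < e:
            raise FiberphotError(
                f"baseline window [{s}, {e}] not inside PSTH window "
                f"[{a_rel}, {b_rel}]"
            )

    dt = 1.0 / z.sampling_rate
    rel = np.arange(a_rel, b_rel - dt / 2, dt)
    t = z.timestamps
    rows = []
    n_dropped = 0
    for te in events.timestamps:
        lo, hi = te + rel[0], te + rel[-1]
        if lo < t[0] - dt / 2 or hi > t[-1] + dt / 2:
            n_dropped += 1
            continue
        idx = np.clip(np.searchsorted(t, te + rel), 1, len(t) - 1)
        # nearest-sample lookup
        left_closer = (te + rel - t[idx - 1]) < (t[idx] - (te + rel))
        idx = idx - left_closer.astype(np.intp)
        rows.append(z.values[idx])
    if not rows:
        raise FiberphotError(
            f"event {events.name!r}: all {len(events)} events fell outside "
            "the recording"
        )
    trials = np.vstack(rows)
    if baseline_window is not None:
        bmask = interval_mask(rel, baseline_window[0], baseline_window[1])
        if not bmask.any():
            raise FiberphotError("baseline window contains no grid samples")
        trials = trials - trials[:, bmask].mean(axis=1, keepdims=True)
    mean, sem = _trial_stats(trials)
    return PsthResult(
        time=rel,
        trials=trials,
        mean=mean,
        sem=sem,
        event_name=events.name,
        baseline_window=tuple(baseline_window) if baseline_window else None,
        n_dropped=n_dropped,
    )


def _check_windows(psth: PsthResult, windows) -> tuple[tuple[float, float], ...]:
    windows = tuple((float(s), float(e)) for s, e in windows)
    if not 1 <= len(windows) <= MAX_MEASURE_WINDOWS:
        raise FiberphotError(
            f"between 1 and {MAX_MEASURE_WINDOWS} measure windows, "
            f"got {len(windows)}"
        )
    lo, hi = psth.time[0], psth.time[-1]
    for s, e in windows:
        if not s < e:
            raise FiberphotError(f"measure window [{s}, {e}] has start >= end")
        if s < lo or e > hi + 1e-12:
            raise FiberphotError(
                f"measure window [{s}, {e}] outside PSTH range "
                f"[{lo:.6g}, {hi:.6g}]"
            )
    return windows


def _window_slice(time: np.ndarray, s: float, e: float) -> np.ndarray:
    idx = np.flatnonzero((time >= s - 1e-12) & (time <= e + 1e-12))
    if idx.size < 2:
        raise FiberphotError(f"measure window [{s}, {e}] holds < 2 samples")
    return idx


def measure_windows(psth: PsthResult, windows) -> MeasureResult:
    """Trapezoidal AUC and peak of the mean PSTH in up to 5 windows."""
    windows = _check_windows(psth, windows)
    auc = np.empty(len(windows))
    peak = np.empty(len(windows))
    for k, (s, e) in enumerate(windows):
        idx = _window_slice(psth.time, s, e)
        auc[k] = np.trapezoid(psth.mean[idx], psth.time[idx])
        peak[k] = np.max(psth.mean[idx])
    return MeasureResult(windows=windows, auc=auc, peak=peak, event_name=psth.event_name)


def per_trial_measures(psth: PsthResult, windows) -> tuple[np.ndarray, np.ndarray]:
    """AUC and peak per trial row: two (n_trials x n_windows) matrices.

    By linearity of the trapezoid, the column means of the AUC matrix
    equal the mean-PSTH AUCs; no such identity holds for peaks, whose
    argmax can differ between trials.
    """
    windows = _check_windows(psth, windows)
    n = psth.n_trials
    auc = np.empty((n, len(windows)))
    peak = np.empty((n, len(windows)))
    for k, (s, e) in enumerate(windows):
        idx = _window_slice(psth.time, s, e)
        auc[:, k] = np.trapezoid(psth.trials[:, idx], psth.time[idx], axis=1)
        peak[:, k] = psth.trials[:, idx].max(axis=1)
    return auc, peak
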