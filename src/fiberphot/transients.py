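"""Whole-session calcium-transient detection and summary statistics.

Two-stage robust thresholding on the z-score trace:

Stage 1 — the trace is partitioned into consecutive windows (default
15 s). Within each window, samples above ``median + 2*MAD`` of that
window are set aside as high-amplitude events; the survivors across the
whole session form the *resultant trace*, a transient-free estimate of
the noise floor.

Stage 2 — with m = median and d = MAD of the resultant trace, strict
local maxima of the full z trace exceeding ``m + 3*d`` are counted as
transients.

Samples removed in stage 1 leave the statistic pool only; peaks are
still found on the full trace (removing them outright would delete the
very transients being counted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._core import FiberphotError, TimeSeries
from .normalize import mad

logger = logging.getLogger("fiberphot")

__all__ = ["TransientResult", "detect_transients", "transient_summary"]

#: Default stage-1 thresholding window, seconds.
DEFAULT_WINDOW_S = 15.0


@dataclass(frozen=True)
class TransientResult:
    """Detected peaks plus session-level amplitude/frequency summaries."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    mean_amplitude: float
    frequency: float  # events per minute
    threshold_trace_median: float
    threshold_mad: float
    duration_min: float

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima: greater than both immediate neighbors.

    A flat plateau that rises then falls counts once, at its first
    sample. Endpoints are never maxima.
    """
    out = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=np.intp)


def detect_transients(
    z: TimeSeries,
    window_s: float = DEFAULT_WINDOW_S,
    stage1_mult: float = 2.0,
    stage2_mult: float = 3.0,
) -> TransientResult:
    """Run the two-stage MAD procedure on a z-score trace.

    Parameters
    ----------
    z
        The z-scored session trace.
    window_s
        Stage-1 window length in seconds (default 15 s). Implemented as
        consecutive non-overlapping windows; the last partial window is
        processed as-is.
    stage1_mult, stage2_mult
        MAD multipliers of the two stages (2 and 3 by convention).
    """
    x = z.values
    t = z.timestamps
    duration_s = z.duration
    if window_s > duration_s:
        raise FiberphotError(
            f"thresholding window {window_s} s exceeds trace duration "
            f"{duration_s:.6g} s"
        )

    # Stage 1: per-window removal of high-amplitude samples
    samples_per_window = max(1, int(round(window_s * z.sampling_rate)))
    keep_masks = []
    for start in range(0, len(x), samples_per_window):
        w = x[start : start + samples_per_window]
        thr = np.median(w) + stage1_mult * mad(w)
        keep_masks.append(w <= thr)
    keep = np.concatenate(keep_masks)
    resultant = x[keep]
    if resultant.size == 0:
        raise FiberphotError("thresholding removed all samples")

    # Stage 2: strict local maxima of the full trace above m + mult*d
    m = float(np.median(resultant))
    d = mad(resultant)
    threshold = m + stage2_mult * d
    peaks = _local_maxima(x)
    counted = peaks[x[peaks] > threshold]

    n = len(counted)
    duration_min = duration_s / 60.0
    mean_amp = float(np.mean(x[counted])) if n else float("nan")
    if n == 0:
        warnings.warn("no transients detected; mean amplitude is NaN")
    return TransientResult(
        peak_times=t[counted],
        peak_amplitudes=x[counted],
        mean_amplitude=mean_amp,
        frequency=n / duration_min,
        threshold_trace_median=m,
        threshold_mad=d,
        duration_min=duration_min,
    )


def transient_summary(result: TransientResult) -> tuple[float, float]:
    """(mean peak amplitude in z, frequency in events/min)."""
    return result.mean_amplitude, result.frequency
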