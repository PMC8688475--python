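"""Control fitting, dF/F, and z-scoring.

The normalization chain is the standard isosbestic correction: the
control channel (motion + bleaching artifacts, no indicator-dependent
activity) is fit to the signal channel by least-squares linear
regression, and

    dF/F = (signal - fitted_control) / fitted_control

The dF/F trace is then standardized to a z-score by one of three
conventions:

standard   (x - mean(x)) / sd(x)            over the whole trace
baseline   (x - mean(x[b])) / sd(x[b])      statistics from a baseline window
modified   0.6745 * (x - median(x)) / MAD   robust; 0.6745 = Phi^-1(0.75)
           makes 0.6745/MAD a consistent estimator of 1/sigma under
           Gaussian noise

Standard deviations use the population convention (ddof=0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._core import FiberphotError, TimeSeries, interval_mask
from .preprocess import ChunkedSession, _concatenate_chunks, fit_exponential_control

logger = logging.getLogger("fiberphot")

__all__ = [
    "FitResult",
    "DffTrace",
    "ZscoreTrace",
    "fit_control",
    "compute_dff",
    "compute_dff_chunked",
    "zscore",
    "mad",
]

#: Guard on the dF/F denominator: |fitted control| at or below this is fatal.
DENOM_EPS = 1e-9

#: Scaling constant of the modified z-score, the 0.75 normal quantile.
MODIFIED_Z_CONSTANT = 0.6745


@dataclass(frozen=True)
class FitResult:
    """Least-squares degree-1 fit of control onto signal."""

    slope: float
    intercept: float
    fitted_control: TimeSeries


@dataclass(frozen=True)
class DffTrace(TimeSeries):
    """dF/F (dimensionless) with the indices where chunks were joined."""

    chunk_boundaries: tuple[int, ...] = ()


@dataclass(frozen=True)
class ZscoreTrace(TimeSeries):
    """Standardized trace in z units."""

    method: str = "standard"
    baseline_window: tuple[float, float] | None = None


def fit_control(control: TimeSeries, signal: TimeSeries) -> FitResult:
    """Fit ``signal ~ slope*control + intercept`` by least squares.

    A constant control makes the fit degenerate; in that case use the
    pseudo-control path (exponential fit to the smoothed signal) instead.
    """
    if len(control) != len(signal):
        raise FiberphotError(
            f"length mismatch: control {len(control)} vs signal {len(signal)}"
        )
    c, s = control.values, signal.values
    if np.ptp(c) == 0:
        raise FiberphotError(
            "control channel is constant; the degree-1 fit is degenerate "
            "(consider the no-isosbestic exponential pseudo-control)"
        )
    slope, intercept = np.polyfit(c, s, 1)
    fitted = control.with_values(slope * c + intercept)
    return FitResult(float(slope), float(intercept), fitted)


def compute_dff(signal: TimeSeries, fitted_control: TimeSeries) -> DffTrace:
    """Elementwise (signal - fitted_control) / fitted_control."""
    if len(signal) != len(fitted_control):
        raise FiberphotError(
            f"length mismatch: signal {len(signal)} vs fitted control "
            f"{len(fitted_control)}"
        )
    f = fitted_control.values
    bad = np.flatnonzero(np.abs(f) <= DENOM_EPS)
    if bad.size:
        raise FiberphotError(
            f"fitted control ~ 0 (|v| <= {DENOM_EPS:g}) at indices "
            f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
        )
    return DffTrace(
        timestamps=signal.timestamps,
        values=(signal.values - f) / f,
        sampling_rate=signal.sampling_rate,
    )


def compute_dff_chunked(chunked: ChunkedSession, use_isosbestic: bool = True) -> DffTrace:
    """Per-chunk control fit + dF/F, concatenated in order.

    Each artifact-free chunk gets its own control fit (a single fit across
    an excised artifact would be skewed by the discontinuity); the chunk
    dF/F traces are then joined on the concatenated time axis and the
    join indices recorded.
    """
    pieces = []
    boundaries = []
    n_so_far = 0
    for i, (ctrl, sig) in enumerate(chunked.chunks):
        try:
            if use_isosbestic:
                if ctrl is None:
                    raise FiberphotError("no control channel present")
                fitted = fit_control(ctrl, sig).fitted_control
            else:
                fitted = fit_exponential_control(sig)
            pieces.append(compute_dff(sig, fitted))
        except FiberphotError as exc:
            raise FiberphotError(f"chunk {i}: {exc}") from exc
        if i > 0:
            boundaries.append(n_so_far)
        n_so_far += len(sig)
    rate = chunked.chunks[0][1].sampling_rate
    times, values = _concatenate_chunks(pieces, rate)
    return DffTrace(
        timestamps=times,
        values=values,
        sampling_rate=rate,
        chunk_boundaries=tuple(boundaries),
    )


def mad(x: np.ndarray) -> float:
    """Raw median absolute deviation, median(|x - median(x)|)."""
    x = np.asarray(x)
    return float(np.median(np.abs(x - np.median(x))))


def zscore(
    dff: TimeSeries,
    method: str = "standard",
    baseline_window: tuple[float, float] | None = None,
) -> ZscoreTrace:
    """Standardize a dF/F trace by one of the three conventions above.

    ``baseline_window`` is in absolute session seconds, half-open; it is
    required for (and only used by) the baseline method.
    """
    x = dff.values
    if method == "standard":
        mu, sd = float(np.mean(x)), float(np.std(x))
        if sd == 0:
            raise FiberphotError("constant trace: standard deviation is zero")
        z = (x - mu) / sd
    elif method == "baseline":
        if baseline_window is None:
            raise FiberphotError("baseline method requires baseline_window")
        a, b = baseline_window
        mask = interval_mask(dff.timestamps, a, b)
        if mask.sum() < 2:
            raise FiberphotError(
                f"baseline window [{a}, {b}) holds fewer than 2 samples"
            )
        mu, sd = float(np.mean(x[mask])), float(np.std(x[mask]))
        if sd == 0:
            raise FiberphotError("constant baseline segment: sd is zero")
        z = (x - mu) / sd
    elif method == "modified":
        med = float(np.median(x))
        d = mad(x)
        if d == 0:
            raise FiberphotError("constant trace: MAD is zero")
        z = MODIFIED_Z_CONSTANT * (x - med) / d
    else:
        raise FiberphotError(f"unknown z-score method {method!r}")
    return ZscoreTrace(
        timestamps=dff.timestamps,
        values=z,
        sampling_rate=dff.sampling_rate,
        method=method,
        baseline_window=baseline_window if method == "baseline" else None,
    )
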