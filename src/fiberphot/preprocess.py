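"""Denoising, start-trimming, artifact chunk excision, pseudo-control fitting.

The filter is the field's standard zero-phase moving average: a uniform
FIR kernel applied forward and then backward over the trace, which
squares the magnitude response and cancels the phase (no time shift of
transients). The per-pass window defaults to 100 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._core import (
    ChunkSelection,
    EventStream,
    FiberphotError,
    RecordingSession,
    TimeSeries,
    interval_mask,
)

logger = logging.getLogger("fiberphot")

__all__ = [
    "moving_average_zero_phase",
    "trim_start",
    "apply_chunks",
    "fit_exponential_control",
    "filter_session",
    "ChunkedSession",
]


def moving_average_zero_phase(ts: TimeSeries, window: int) -> TimeSeries:
    """Apply a length-``window`` uniform moving average forward then backward.

    Edges are reflect-padded by ``window`` samples before each pass and
    cropped after, so a light-on step at the very start does not smear a
    startup transient into the data. Output length equals input length and
    timestamps are unchanged.
    """
    n = len(ts)
    window = int(window)
    if window < 1:
        raise FiberphotError("filter window must be >= 1")
    if window > n:
        raise FiberphotError(f"filter window {window} exceeds trace length {n}")
    if window == 1:
        return ts
    kernel = np.ones(window) / window

    def one_pass(x: np.ndarray) -> np.ndarray:
        padded = np.pad(x, window, mode="reflect")
        # 'same' keeps the centered alignment of each pass
        smoothed = np.convolve(padded, kernel, mode="same")
        return smoothed[window:-window]

    forward = one_pass(ts.values)
    backward = one_pass(forward[::-1])[::-1]
    return ts.with_values(backward)


def trim_start(session: RecordingSession, seconds: float) -> RecordingSession:
    """Drop all samples and events before ``t0 + seconds``.

    Removes the light-on artifact at the beginning of a recording.
    Remaining timestamps are left unshifted.
    """
    if seconds < 0:
        raise FiberphotError("trim seconds must be >= 0")
    if seconds == 0:
        return session
    t0 = session.signal.timestamps[0]
    cut = t0 + seconds
    if cut >= session.signal.timestamps[-1]:
        raise FiberphotError(
            f"trim of {seconds} s >= recording duration "
            f"{session.signal.timestamps[-1] - t0:.6g} s"
        )

    def _trim(ts: TimeSeries) -> TimeSeries:
        keep = ts.timestamps >= cut
        return TimeSeries(ts.timestamps[keep], ts.values[keep], ts.sampling_rate)

    events = {
        name: EventStream(name, ev.timestamps[ev.timestamps >= cut])
        for name, ev in session.events.items()
    }
    return RecordingSession(
        signal=_trim(session.signal),
        control=_trim(session.control) if session.control is not None else None,
        events=events,
        session_id=session.session_id,
    )


@dataclass(frozen=True)
class ChunkedSession:
    """Keep-chunks of a session with events remapped to concatenated time.

    Each chunk is a (control-or-None, signal) pair cut at identical sample
    indices. An event retained inside keep-interval k is remapped to
    ``offset_k + (t - chunk_start_k)`` where offset_k is the concatenated
    time at which chunk k begins, so event-to-sample alignment survives
    the excision exactly.
    """

    chunks: tuple[tuple[TimeSeries | None, TimeSeries], ...]
    events: dict[str, EventStream]
    original_duration: float
    session_id: str = "session"

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    def concatenated_signal(self) -> TimeSeries:
        """Signal chunks joined on a continuous concatenated-time axis."""
        rate = self.chunks[0][1].sampling_rate
        times, values = _concatenate_chunks(
            [s for _, s in self.chunks], rate
        )
        return TimeSeries(times, values, rate)


def _concatenate_chunks(chunks: list[TimeSeries], rate: float):
    dt = 1.0 / rate
    times, values = [], []
    offset = 0.0
    for ts in chunks:
        local = ts.timestamps - ts.timestamps[0]
        times.append(local + offset)
        values.append(ts.values)
        offset += local[-1] + dt
    return np.concatenate(times), np.concatenate(values)


def apply_chunks(session: RecordingSession, chunks: ChunkSelection) -> ChunkedSession:
    """Excise everything outside the keep intervals.

    Both channels are cut at identical indices; events outside every keep
    interval are dropped and the rest remapped to concatenated time.
    """
    t = session.signal.timestamps
    t0, t1 = t[0], t[-1]
    dt = 1.0 / session.signal.sampling_rate
    for a, b in chunks.keep_intervals:
        if b <= t0 or a > t1 + dt:
            raise FiberphotError(
                f"keep interval [{a}, {b}) outside recording range "
                f"[{t0:.6g}, {t1:.6g}]"
            )

    out_chunks = []
    for a, b in chunks.keep_intervals:
        mask = interval_mask(t, a, b)
        if mask.sum() < 2:
            raise FiberphotError(
                f"keep interval [{a}, {b}) retains fewer than 2 samples"
            )
        sig = TimeSeries(t[mask], session.signal.values[mask], session.signal.sampling_rate)
        ctrl = None
        if session.control is not None:
            ctrl = TimeSeries(
                t[mask], session.control.values[mask], session.control.sampling_rate
            )
        out_chunks.append((ctrl, sig))

    # remap events: t' = chunk_offset + (t - chunk_first_sample_time)
    offsets = []
    offset = 0.0
    for _, sig in out_chunks:
        offsets.append(offset)
        offset += (sig.timestamps[-1] - sig.timestamps[0]) + dt
    events: dict[str, EventStream] = {}
    for name, ev in session.events.items():
        remapped = []
        for te in ev.timestamps:
            for (a, b), off, (_, sig) in zip(chunks.keep_intervals, offsets, out_chunks):
                if a <= te < b:
                    remapped.append(off + (te - sig.timestamps[0]))
                    break
        events[name] = EventStream(name, np.sort(np.asarray(remapped)))
        dropped = len(ev) - len(remapped)
        if dropped:
            logger.info("event %r: %d timestamps excised with artifacts", name, dropped)

    return ChunkedSession(
        chunks=tuple(out_chunks),
        events=events,
        original_duration=float(t1 - t0) + dt,
        session_id=session.session_id,
    )


def session_as_single_chunk(session: RecordingSession) -> ChunkedSession:
    """Wrap an un-excised session as a one-chunk ChunkedSession."""
    dt = 1.0 / session.signal.sampling_rate
    return ChunkedSession(
        chunks=((session.control, session.signal),),
        events=dict(session.events),
        original_duration=session.signal.duration,
        session_id=session.session_id,
    )


def fit_exponential_control(
    signal: TimeSeries, smooth_window: int = 100
) -> TimeSeries:
    """Construct a pseudo-control by fitting ``a*exp(-t/tau) + c`` to the signal.

    For recordings without an isosbestic channel: the signal is smoothed
    with the zero-phase moving average, then a single decaying exponential
    plus offset is fit by nonlinear least squares to approximate
    photobleaching. Falls back to a degree-1 polynomial trend (with a
    warning) if the fit does not converge. The pseudo-control corrects
    slow bleaching only, not fast shared artifacts.
    """
    if len(signal) < 10:
        raise FiberphotError("need >= 10 samples for an exponential fit")
    smooth_window = min(int(smooth_window), len(signal))
    smoothed = moving_average_zero_phase(signal, smooth_window)
    t = smoothed.timestamps - smoothed.timestamps[0]
    y = smoothed.values
    duration = t[-1]

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    a0 = y[0] - y[-1]
    c0 = y[-1]
    tau0 = duration / 3.0
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=(a0, tau0, c0),
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        fitted = model(t, *popt)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        logger.warning(
            "exponential fit did not converge (%s); falling back to linear trend",
            exc,
        )
        coef = np.polyfit(t, y, 1)
        fitted = np.polyval(coef, t)
    return signal.with_values(fitted)


def filter_session(session: RecordingSession, window: int) -> RecordingSession:
    """Zero-phase moving average applied to both channels."""
    return RecordingSession(
        signal=moving_average_zero_phase(session.signal, window),
        control=(
            moving_average_zero_phase(session.control, window)
            if session.control is not None
            else None
        ),
        events=dict(session.events),
        session_id=session.session_id,
    )
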