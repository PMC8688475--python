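"""Ground-truth synthetic photometry sessions.

Emulates the signal structure the isosbestic correction assumes: a slow
exponential photobleaching baseline in both channels, motion artifacts
injected identically (up to a scalar gain) into both channels, and
indicator transients — difference-of-exponentials kernels, the standard
calcium-indicator shape — present only in the signal channel. Gaussian
sensor noise is added independently per channel.

    control(t) = bleach_c(t) +     artifact(t) + noise
    signal(t)  = bleach_s(t) + k * artifact(t) + activity(t) + noise

What this generator does *not* emulate: hemodynamic contamination,
indicator saturation or other nonlinearities, pink/drift noise, and
frame drops. A pipeline test that passes here establishes correctness of
the arithmetic and alignment, not robustness to every pathology of real
recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._core import EventStream, FiberphotError, RecordingSession, TimeSeries

logger = logging.getLogger("fiberphot")

__all__ = ["SynthParams", "GroundTruth", "generate_session", "write_session"]


@dataclass(frozen=True)
class SynthParams:
    """The stated world of one synthetic session.

    Defaults describe a typical striatal GCaMP recording: 10 min at
    20 Hz, baseline fluorescence ~1 a.u. with a 30% exponential bleach
    over the session, 0.5% sensor noise, transients peaking at 5% dF/F
    with 0.1 s rise / 1 s decay kinetics.
    """

    duration: float = 600.0
    rate: float = 20.0
    bleach_signal: tuple[float, float, float] = (0.3, 600.0, 1.0)   # a, tau, c
    bleach_control: tuple[float, float, float] = (0.2, 400.0, 0.8)  # differs on purpose
    artifact_events: tuple[tuple[float, float, float], ...] = ()    # (time, amp, width)
    artifact_gain: float = 1.0       # scalar k applied to the artifact in the signal
    transient_times: tuple[float, ...] = ()
    transient_amplitude: float = 0.05
    transient_rise: float = 0.1
    transient_decay: float = 1.0
    noise_sd: float = 0.005
    behavioral_events: Mapping[str, Sequence[float]] = field(default_factory=dict)
    event_response_latency: float | None = None  # inject a kernel at event + latency
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise FiberphotError("rate and duration must be > 0")
        for name, (_, tau, _) in (
            ("bleach_signal", self.bleach_signal),
            ("bleach_control", self.bleach_control),
        ):
            if tau <= 0:
                raise FiberphotError(f"{name}: tau must be > 0")
        for t in self.transient_times:
            if not 0 <= t < self.duration:
                raise FiberphotError(f"transient time {t} outside [0, duration)")
        for t_, _, w in self.artifact_events:
            if not 0 <= t_ < self.duration or w <= 0:
                raise FiberphotError("artifact events need 0 <= t < duration, width > 0")
        object.__setattr__(
            self,
            "behavioral_events",
            {k: tuple(float(x) for x in v) for k, v in dict(self.behavioral_events).items()},
        )
        for name, times in self.behavioral_events.items():
            for t in times:
                if not 0 <= t < self.duration:
                    raise FiberphotError(
                        f"event {name!r} time {t} outside [0, duration)"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """What was injected, aligned to the generated timestamps."""

    timestamps: np.ndarray
    clean_activity_trace: np.ndarray
    artifact_trace: np.ndarray
    response_latency: float | None
    params: SynthParams


def _kernel(t_rel: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference of exponentials normalized to unit peak, 0 before onset."""
    k = np.where(
        t_rel >= 0,
        np.exp(-np.maximum(t_rel, 0) / decay) - np.exp(-np.maximum(t_rel, 0) / rise),
        0.0,
    )
    # analytic peak of exp(-t/d) - exp(-t/r) at t* = ln(d/r) * r*d/(d-r)
    t_star = np.log(decay / rise) * rise * decay / (decay - rise)
    peak = np.exp(-t_star / decay) - np.exp(-t_star / rise)
    return k / peak


def generate_session(params: SynthParams) -> tuple[RecordingSession, GroundTruth]:
    """Render the stated world into a RecordingSession plus its ground truth.

    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.rate))
    if n < 2:
        raise FiberphotError("duration * rate must give >= 2 samples")
    t = np.arange(n) / params.rate

    def bleach(coefs):
        a, tau, c = coefs
        return a * np.exp(-t / tau) + c

    artifact = np.zeros(n)
    for at, amp, width in params.artifact_events:
        artifact += amp * np.exp(-0.5 * ((t - at) / width) ** 2)

    activity = np.zeros(n)
    onsets = list(params.transient_times)
    if params.event_response_latency is not None:
        for times in params.behavioral_events.values():
            onsets.extend(te + params.event_response_latency for te in times)
    for onset in onsets:
        activity += params.transient_amplitude * _kernel(
            t - onset, params.transient_rise, params.transient_decay
        )

    control = bleach(params.bleach_control) + artifact
    sig = bleach(params.bleach_signal) + params.artifact_gain * artifact + activity
    if params.noise_sd > 0:
        control = control + rng.normal(0, params.noise_sd, n)
        sig = sig + rng.normal(0, params.noise_sd, n)

    events = {
        name: EventStream(name, np.sort(np.asarray(times, dtype=np.float64)))
        for name, times in params.behavioral_events.items()
    }
    session = RecordingSession(
        signal=TimeSeries(t, sig, params.rate),
        control=TimeSeries(t, control, params.rate),
        events=events,
        session_id=f"synth-{params.seed}",
    )
    truth = GroundTruth(
        timestamps=t,
        clean_activity_trace=activity,
        artifact_trace=artifact,
        response_latency=params.event_response_latency,
        params=params,
    )
    return session, truth


def write_session(
    session: RecordingSession,
    folder: Path,
    format: str = "generic_csv",
) -> list[Path]:
    """Write a session to disk in one of the supported input formats.

    ``generic_csv``: one ``timestamps,data`` CSV per channel plus one
    single-column CSV per event stream — reads back bit-identically.
    ``interleaved_csv``: a single camera-system CSV with alternating
    LED-state rows (control frames lead signal frames by half a sample
    period) — reads back after de-interleave + harmonize, with the
    control linearly re-interpolated.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format == "generic_csv":
        for role, ts in (("control", session.control), ("signal", session.signal)):
            if ts is None:
                continue
            path = folder / f"{role}.csv"
            pd.DataFrame({"timestamps": ts.timestamps, "data": ts.values}).to_csv(
                path, index=False, float_format="%.17g"
            )
            written.append(path)
    elif format == "interleaved_csv":
        if session.control is None:
            raise FiberphotError("interleaved format requires a control channel")
        dt = 1.0 / session.signal.sampling_rate
        t_sig = session.signal.timestamps
        t_ctrl = t_sig - dt / 2
        frames = pd.DataFrame(
            {
                "FrameCounter": np.arange(2 * len(t_sig)),
                "Timestamp": np.ravel(np.column_stack([t_ctrl, t_sig])),
                "LedState": np.tile([1, 2], len(t_sig)),
                "Region0G": np.ravel(
                    np.column_stack([session.control.values, session.signal.values])
                ),
            }
        )
        path = folder / "photometry.csv"
        frames.to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    else:
        raise FiberphotError(f"unknown format {format!r}")

    for name, ev in session.events.items():
        path = folder / f"{name}.csv"
        pd.DataFrame({"timestamps": ev.timestamps}).to_csv(
            path, index=False, float_format="%.17g"
        )
        written.append(path)
    return written
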