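"""End-to-end session analysis: the headless pipeline behind the CLI.

Order of operations per session: read -> zero-phase filter -> trim start
-> artifact chunk excision -> per-chunk control fit + dF/F -> z-score ->
whole-session transients -> per-event PSTHs -> window measures -> write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from ._core import AnalysisParameters, FiberphotError, RecordingSession
from . import io as fio
from .normalize import compute_dff_chunked, zscore
from .preprocess import apply_chunks, filter_session, session_as_single_chunk, trim_start
from .psth import compute_psth, measure_windows, per_trial_measures
from .transients import detect_transients

logger = logging.getLogger("fiberphot")

__all__ = ["SessionOutput", "analyze_session", "analyze_folder"]


@dataclass
class SessionOutput:
    """Everything the pipeline computed for one session."""

    session_id: str
    dff: object
    zscore: object
    transients: object
    psths: dict = field(default_factory=dict)
    measures: dict = field(default_factory=dict)
    per_trial: dict = field(default_factory=dict)
    written: list = field(default_factory=list)


def analyze_session(session: RecordingSession, params: AnalysisParameters) -> SessionOutput:
    """Run the full pipeline on an in-memory session."""
    n = len(session.signal)
    window = min(params.filter_window, n)
    if window < params.filter_window:
        logger.warning(
            "filter window %d capped to trace length %d", params.filter_window, n
        )
    session = filter_session(session, window)
    if params.trim_start > 0:
        session = trim_start(session, params.trim_start)
    if params.chunks is not None:
        chunked = apply_chunks(session, params.chunks)
    else:
        chunked = session_as_single_chunk(session)

    dff = compute_dff_chunked(chunked, use_isosbestic=params.use_isosbestic)
    z = zscore(dff, params.zscore_method, params.zscore_baseline_window)

    transients = None
    if params.transient_window <= z.duration:
        transients = detect_transients(z, params.transient_window)
    else:
        logger.warning(
            "trace shorter than transient window %.3g s; skipping transient detection",
            params.transient_window,
        )

    out = SessionOutput(
        session_id=session.session_id, dff=dff, zscore=z, transients=transients
    )
    for name, ev in chunked.events.items():
        if len(ev) == 0:
            logger.warning("event %r: no timestamps after excision; skipped", name)
            continue
        try:
            psth = compute_psth(z, ev, params.psth_window, params.psth_baseline_window)
        except FiberphotError as exc:
            logger.warning("event %r: PSTH skipped (%s)", name, exc)
            continue
        out.psths[name] = psth
        if params.measure_windows:
            out.measures[name] = measure_windows(psth, params.measure_windows)
            out.per_trial[name] = per_trial_measures(psth, params.measure_windows)
    return out


def analyze_folder(
    folder: Path,
    params: AnalysisParameters,
    out_dir: Path | None = None,
    formats: tuple[str, ...] = ("hdf5", "csv"),
    channel_map: dict | None = None,
) -> SessionOutput:
    """Read a generic-CSV session folder, analyze it, and write results."""
    folder = Path(folder)
    if not folder.is_dir():
        raise FiberphotError(f"session folder not found: {folder}")
    if channel_map is None:
        channel_map = {"signal": "signal.csv"}
        if (folder / "control.csv").exists():
            channel_map["control"] = "control.csv"
    session = fio.read_generic_session(folder, channel_map)
    result = analyze_session(session, params)

    out_dir = Path(out_dir) if out_dir else folder / "output"
    to_write = [result.dff, result.zscore]
    if result.transients is not None:
        to_write.append(result.transients)
    to_write.extend(result.psths.values())
    to_write.extend(result.measures.values())
    result.written = fio.write_results(
        to_write, out_dir, session_id=result.session_id, formats=formats
    )
    return result
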