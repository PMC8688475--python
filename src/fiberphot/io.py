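"""Session folder reading, parameter loading, and HDF5/CSV result output.

Supported inputs
----------------
* Generic per-channel CSVs: one file per channel with header
  ``timestamps,data``; any other CSV in the folder with a ``timestamps``
  header is auto-discovered as a behavioral event stream named by its
  filename stem.
* Interleaved camera-system CSVs: several excitation channels share one
  value column and are told apart by an LED-state flag column
  (default columns ``Timestamp``, ``LedState``, value columns matched by
  the prefix ``Region``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import fields as dataclass_fields
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

from ._core import (
    AnalysisParameters,
    ChunkSelection,
    EventStream,
    FiberphotError,
    RecordingSession,
    TimeSeries,
)

logger = logging.getLogger("fiberphot")

__all__ = [
    "read_generic_session",
    "read_interleaved_session",
    "harmonize",
    "read_events_csv",
    "load_parameters",
    "write_results",
    "read_hdf5_results",
]


def read_events_csv(path: Path, name: str | None = None) -> EventStream:
    """Read a single-column ``timestamps`` CSV into an EventStream."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "timestamps" not in df.columns:
        raise FiberphotError(f"{path.name}: event CSV needs a 'timestamps' column")
    return EventStream(name or path.stem, np.sort(df["timestamps"].to_numpy(float)))


def _read_channel_csv(path: Path) -> TimeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("timestamps", "data"):
        if col not in df.columns:
            raise FiberphotError(f"{path.name}: channel CSV needs a {col!r} column")
    t = df["timestamps"].to_numpy(float)
    if len(t) < 2:
        raise FiberphotError(f"{path.name}: fewer than 2 samples")
    if np.any(np.diff(t) <= 0):
        raise FiberphotError(f"{path.name}: timestamps not strictly increasing")
    return TimeSeries.from_timestamps(t, df["data"].to_numpy(float))


def read_generic_session(
    folder_path: Path,
    channel_map: Mapping[str, str],
    session_id: str | None = None,
) -> RecordingSession:
    """Read a session folder of per-channel CSVs.

    Parameters
    ----------
    folder_path
        Folder holding one CSV per channel plus optional event CSVs.
    channel_map
        Maps roles (``"signal"``, optionally ``"control"``) to filenames
        within the folder. Every CSV in the folder *not* named here is
        treated as an event stream.
    """
    folder = Path(folder_path)
    if "signal" not in channel_map:
        raise FiberphotError("channel_map must name a 'signal' file")
    channels: dict[str, TimeSeries] = {}
    for role, fname in channel_map.items():
        fpath = folder / fname
        if not fpath.exists():
            raise FiberphotError(f"missing channel file: {fname}")
        channels[role] = _read_channel_csv(fpath)

    named = {str(v) for v in channel_map.values()}
    events: dict[str, EventStream] = {}
    for fpath in sorted(folder.glob("*.csv")):
        if fpath.name in named:
            continue
        try:
            ev = read_events_csv(fpath)
        except FiberphotError:
            logger.warning("skipping %s: not an event CSV", fpath.name)
            continue
        events[ev.name] = ev

    control = channels.get("control")
    signal = channels["signal"]
    if control is not None:
        control, signal = harmonize(control, signal)
    return RecordingSession(
        signal=signal,
        control=control,
        events=events,
        session_id=session_id or folder.name,
    )


def read_interleaved_session(
    file_path: Path,
    state_map: Mapping[int, str],
    region_column: str | None = None,
    time_column: str = "Timestamp",
    state_column: str = "LedState",
    region_prefix: str = "Region",
    session_id: str | None = None,
    events_folder: Path | None = None,
) -> RecordingSession:
    """De-interleave a camera-system CSV into control/signal channels.

    Rows are partitioned by the state-flag column; each role keeps its own
    timestamps and the roles are then harmonized onto the signal grid.
    """
    file_path = Path(file_path)
    if not file_path.exists():
        raise FiberphotError(f"missing file: {file_path.name}")
    df = pd.read_csv(file_path, float_precision="round_trip")
    for col in (time_column, state_column):
        if col not in df.columns:
            raise FiberphotError(f"{file_path.name}: missing column {col!r}")
    if region_column is None:
        regions = [c for c in df.columns if c.startswith(region_prefix)]
        if not regions:
            raise FiberphotError(
                f"{file_path.name}: no column starts with {region_prefix!r}"
            )
        region_column = regions[0]
    elif region_column not in df.columns:
        raise FiberphotError(f"{file_path.name}: missing column {region_column!r}")

    channels: dict[str, TimeSeries] = {}
    for code, role in state_map.items():
        sub = df[df[state_column] == code]
        if len(sub) == 0:
            raise FiberphotError(
                f"state code {code} (role {role!r}) absent from {file_path.name}"
            )
        if len(sub) < 2:
            raise FiberphotError(f"role {role!r}: fewer than 2 frames")
        channels[role] = TimeSeries.from_timestamps(
            sub[time_column].to_numpy(float), sub[region_column].to_numpy(float)
        )
    if "signal" not in channels:
        raise FiberphotError("state_map must assign a 'signal' role")

    control = channels.get("control")
    signal = channels["signal"]
    if control is not None:
        control, signal = harmonize(control, signal)

    events: dict[str, EventStream] = {}
    folder = Path(events_folder) if events_folder else file_path.parent
    for fpath in sorted(folder.glob("*.csv")):
        if fpath.resolve() == file_path.resolve():
            continue
        try:
            ev = read_events_csv(fpath)
        except (FiberphotError, KeyError):
            continue
        events[ev.name] = ev
    return RecordingSession(
        signal=signal,
        control=control,
        events=events,
        session_id=session_id or file_path.stem,
    )


def harmonize(control: TimeSeries, signal: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    """Resample both channels onto the signal grid restricted to the overlap.

    The control is linearly interpolated onto the signal's timestamps; the
    signal's values are unchanged on the overlap. Needed because
    alternating-excitation systems record the two channels on offset
    grids, while the dF/F fit requires samplewise alignment.

    Signal samples up to half a sample period beyond the control's range
    are kept (alternating excitation offsets frames by half a period);
    there the control is linearly extrapolated from its edge segment.
    """
    half_dt = 0.5 / signal.sampling_rate
    t0 = max(control.timestamps[0], signal.timestamps[0]) - half_dt
    t1 = min(control.timestamps[-1], signal.timestamps[-1]) + half_dt
    if t0 >= t1:
        raise FiberphotError("control and signal have no temporal overlap")
    keep = (signal.timestamps >= t0) & (signal.timestamps <= t1)
    t = signal.timestamps[keep]
    if len(t) < 2:
        raise FiberphotError("fewer than 2 signal samples in the overlap")
    tc, vc = control.timestamps, control.values
    c_interp = np.interp(t, tc, vc)
    low = t < tc[0]
    if low.any():
        slope = (vc[1] - vc[0]) / (tc[1] - tc[0])
        c_interp[low] = vc[0] + slope * (t[low] - tc[0])
    high = t > tc[-1]
    if high.any():
        slope = (vc[-1] - vc[-2]) / (tc[-1] - tc[-2])
        c_interp[high] = vc[-1] + slope * (t[high] - tc[-1])
    sig = TimeSeries(t, signal.values[keep], signal.sampling_rate)
    ctrl = TimeSeries(t, c_interp, signal.sampling_rate)
    return ctrl, sig


# ---------------------------------------------------------------------------
# parameters

def _coerce_params(raw: Mapping) -> AnalysisParameters:
    known = {f.name for f in dataclass_fields(AnalysisParameters)}
    unknown = set(raw) - known
    if unknown:
        raise FiberphotError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if kwargs.get("chunks") is not None:
        kwargs["chunks"] = ChunkSelection(
            tuple((float(a), float(b)) for a, b in kwargs["chunks"])
        )
    for key in ("zscore_baseline_window", "psth_window", "psth_baseline_window"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    if kwargs.get("measure_windows"):
        kwargs["measure_windows"] = tuple(
            (float(s), float(e)) for s, e in kwargs["measure_windows"]
        )
    return AnalysisParameters(**kwargs)


def load_parameters(path: Path) -> AnalysisParameters:
    """Load and validate an analysis-parameters file (JSON or YAML)."""
    path = Path(path)
    if not path.exists():
        raise FiberphotError(f"parameter file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise FiberphotError(f"{path.name}: expected a key/value mapping")
    return _coerce_params(raw)


def save_parameters(params: AnalysisParameters, path: Path) -> Path:
    """Write parameters as JSON (the inverse of load_parameters)."""
    path = Path(path)
    d = {}
    for f in dataclass_fields(AnalysisParameters):
        v = getattr(params, f.name)
        if isinstance(v, ChunkSelection):
            v = [list(iv) for iv in v.keep_intervals]
        elif isinstance(v, tuple):
            v = [list(x) if isinstance(x, tuple) else x for x in v]
        d[f.name] = v
    path.write_text(json.dumps(d, indent=2))
    return path


# ---------------------------------------------------------------------------
# results output
#
# HDF5 layout: /session/<id>/dff, /zscore,
#   /transients/{peak_times,peak_amplitudes},
#   /psth/<event>/{trials,time,mean,sem}, /measures/<event>/{auc,peak}.
# CSV mirrors are named <id>_<key>.csv with '/' -> '_'.

def _result_arrays(result) -> dict[str, np.ndarray]:
    """Flatten any result object into {relative-key: array}."""
    from .normalize import DffTrace, ZscoreTrace
    from .psth import MeasureResult, PsthResult
    from .transients import TransientResult
    from .group import GroupResult

    if isinstance(result, DffTrace):
        return {"dff": result.values, "dff_time": result.timestamps,
                "dff_chunk_boundaries": np.asarray(result.chunk_boundaries, dtype=np.int64)}
    if isinstance(result, ZscoreTrace):
        return {"zscore": result.values, "zscore_time": result.timestamps}
    if isinstance(result, TransientResult):
        return {"transients/peak_times": result.peak_times,
                "transients/peak_amplitudes": result.peak_amplitudes}
    if isinstance(result, PsthResult):
        base = f"psth/{result.event_name}"
        return {f"{base}/trials": result.trials, f"{base}/time": result.time,
                f"{base}/mean": result.mean, f"{base}/sem": result.sem}
    if isinstance(result, MeasureResult):
        base = f"measures/{result.event_name}"
        return {f"{base}/auc": result.auc, f"{base}/peak": result.peak,
                f"{base}/windows": np.asarray(result.windows, dtype=np.float64)}
    if isinstance(result, GroupResult):
        base = f"group/{result.event_name}"
        out = {f"{base}/time": result.time,
               f"{base}/session_means": result.session_means,
               f"{base}/mean": result.group_mean, f"{base}/sem": result.group_sem}
        if result.measures is not None:
            out[f"{base}/measure_auc"] = result.measures["auc"]
            out[f"{base}/measure_peak"] = result.measures["peak"]
        return out
    if isinstance(result, dict):
        return {k: np.asarray(v) for k, v in result.items()}
    raise FiberphotError(f"cannot serialize result of type {type(result).__name__}")


def _result_attrs(result) -> dict:
    from .transients import TransientResult
    from .normalize import ZscoreTrace

    if isinstance(result, TransientResult):
        return {"mean_amplitude": result.mean_amplitude,
                "frequency_per_min": result.frequency,
                "threshold_trace_median": result.threshold_trace_median,
                "threshold_mad": result.threshold_mad}
    if isinstance(result, ZscoreTrace):
        attrs = {"method": result.method}
        if result.baseline_window is not None:
            attrs["baseline_window"] = list(result.baseline_window)
        return attrs
    return {}


def write_results(
    results,
    out_dir: Path,
    session_id: str = "session",
    formats: tuple[str, ...] = ("hdf5", "csv"),
) -> list[Path]:
    """Write one or more result objects under ``out_dir``.

    Returns the list of files written. Arrays round-trip exactly: HDF5
    stores float64 bit-identically and the CSV mirror uses ``repr``-exact
    float formatting.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise FiberphotError(f"output directory not writable: {out_dir}") from exc

    if not isinstance(results, (list, tuple)):
        results = [results]
    written: list[Path] = []
    flat: list[tuple[str, np.ndarray, dict]] = []
    for res in results:
        attrs = _result_attrs(res)
        for key, arr in _result_arrays(res).items():
            if arr.ndim >= 1 and arr.shape[0] == 0:
                logger.warning("result %s is empty (0 rows); writing anyway", key)
            flat.append((key, arr, attrs))

    if "hdf5" in formats:
        h5path = out_dir / f"{session_id}.h5"
        mode = "a" if h5path.exists() else "w"
        with h5py.File(h5path, mode) as h5:
            for key, arr, attrs in flat:
                full = f"/session/{session_id}/{key}"
                if full in h5:
                    del h5[full]
                ds = h5.create_dataset(full, data=arr)
                for ak, av in attrs.items():
                    ds.attrs[ak] = av
        written.append(h5path)
    if "csv" in formats:
        for key, arr, _ in flat:
            cpath = out_dir / f"{session_id}_{key.replace('/', '_')}.csv"
            a2 = np.atleast_2d(np.asarray(arr, dtype=np.float64))
            np.savetxt(cpath, a2, delimiter=",", fmt="%.17g")
            written.append(cpath)
    return written


def read_hdf5_results(path: Path, session_id: str | None = None) -> dict[str, np.ndarray]:
    """Read back every dataset written by write_results, keyed relatively."""
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as h5:
        sessions = list(h5["session"].keys())
        sid = session_id or sessions[0]
        grp = h5[f"session/{sid}"]

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]

        grp.visititems(visit)
    return out
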