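"""Cross-session (group) averaging of PSTHs and window measures.

Each session contributes exactly one trace — its mean PSTH — regardless
of how many trials it holds, so high-trial animals do not dominate the
group average. Sessions must share an identical event name and relative
time grid; a mismatch is an error, never a silent resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._core import FiberphotError
from .psth import MeasureResult, PsthResult

logger = logging.getLogger("fiberphot")

__all__ = ["GroupResult", "average_group"]


@dataclass(frozen=True)
class GroupResult:
    """Session-level mean PSTHs stacked with group mean and SEM."""

    time: np.ndarray
    session_means: np.ndarray        # n_sessions x N
    group_mean: np.ndarray
    group_sem: np.ndarray
    session_ids: tuple[str, ...]
    event_name: str
    measures: dict[str, np.ndarray] | None = None  # auc/peak: n_sessions x n_windows
    measure_mean: dict[str, np.ndarray] | None = None
    measure_sem: dict[str, np.ndarray] | None = None

    @property
    def n_sessions(self) -> int:
        return self.session_means.shape[0]


def _sem_rows(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    if n > 1:
        return mat.std(axis=0, ddof=1) / np.sqrt(n)
    logger.warning("group of one session: SEM reported as 0")
    return np.zeros(mat.shape[1])


def average_group(
    results: Sequence[PsthResult],
    measures: Sequence[MeasureResult] | None = None,
    session_ids: Sequence[str] | None = None,
) -> GroupResult:
    """Average PSTHs (and optionally window measures) across sessions."""
    if not results:
        raise FiberphotError("need at least one session to average")
    ref = results[0]
    bad = [i for i, r in enumerate(results) if r.event_name != ref.event_name]
    if bad:
        raise FiberphotError(
            f"event name mismatch in sessions {bad}: expected {ref.event_name!r}"
        )
    bad = [
        i
        for i, r in enumerate(results)
        if r.time.shape != ref.time.shape or not np.allclose(r.time, ref.time)
    ]
    if bad:
        raise FiberphotError(f"time-grid mismatch in sessions {bad}")

    session_means = np.vstack([r.mean for r in results])
    group_mean = session_means.mean(axis=0)
    group_sem = _sem_rows(session_means)
    ids = tuple(session_ids) if session_ids else tuple(
        f"session{i}" for i in range(len(results))
    )
    if len(ids) != len(results):
        raise FiberphotError("session_ids length does not match results")

    meas = mmean = msem = None
    if measures is not None:
        if len(measures) != len(results):
            raise FiberphotError("measures length does not match results")
        wref = measures[0].windows
        for i, m in enumerate(measures):
            if m.windows != wref:
                raise FiberphotError(f"measure windows mismatch in session {i}")
        auc = np.vstack([m.auc for m in measures])
        peak = np.vstack([m.peak for m in measures])
        meas = {"auc": auc, "peak": peak}
        mmean = {"auc": auc.mean(axis=0), "peak": peak.mean(axis=0)}
        msem = {"auc": _sem_rows(auc), "peak": _sem_rows(peak)}

    return GroupResult(
        time=ref.time.copy(),
        session_means=session_means,
        group_mean=group_mean,
        group_sem=group_sem,
        session_ids=ids,
        event_name=ref.event_name,
        measures=meas,
        measure_mean=mmean,
        measure_sem=msem,
    )
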