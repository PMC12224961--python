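"""Automatic capture of the swallowing window from the sEMG envelope.

A swallow starts when the aggregate envelope first reaches a data-driven
threshold: the mean of a 1500 ms reference span of the envelope plus three
times its standard deviation.  In healthy subjects the hyoid muscles are
quiet during oral preparation, so the reference span is a resting phase
(by default the first 1500 ms of the trial).  In dysphagia the hyoid
muscles assist bolus holding, so the reference is taken from that early
contraction phase instead; the threshold formula is the same.

The crossing time ``T_c`` anchors a fixed analysis window:
``T_s = T_c - 500 ms`` to ``T_e = T_c + 1500 ms`` (2000 ms total).
Intensity maps use 3000 ms from ``T_s``; the symmetry and barycenter
indicators use 1500 ms from ``T_c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SUBMENTAL, ElectrodeGrid
from .preprocess import compute_envelope
from .recording import Recording

REFERENCE_SPAN_MS = 1500.0
PRE_ONSET_MS = 500.0
POST_ONSET_MS = 1500.0

MODES = ("healthy", "dysphagia")


class NoSwallowDetectedError(RuntimeError):
    """The aggregate envelope never reaches the threshold."""


class WindowBoundaryError(ValueError):
    """The derived swallow window would extend outside the recording."""


@dataclass(frozen=True)
class SwallowEvent:
    """A detected swallow: crossing time and derived analysis window (ms)."""

    t_c_ms: float
    threshold_uv: float
    mode: str = "healthy"

    @property
    def t_s_ms(self) -> float:
        return self.t_c_ms - PRE_ONSET_MS

    @property
    def t_e_ms(self) -> float:
        return self.t_c_ms + POST_ONSET_MS


def estimate_threshold(envelope: np.ndarray, fs: float,
                       reference_start_ms: float = 0.0,
                       mode: str = "healthy") -> float:
    """Detection threshold: mean + 3 x SD of a 1500 ms envelope span.

    ``mode`` records whether the reference span is a resting phase
    (healthy) or the early contraction phase (dysphagia); the arithmetic is
    identical, the caller chooses the span.  Population SD (divide by N).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    envelope = np.asarray(envelope, dtype=float)
    i0 = int(round(reference_start_ms * fs / 1000.0))
    n_ref = int(round(REFERENCE_SPAN_MS * fs / 1000.0))
    if i0 < 0 or i0 + n_ref > envelope.shape[0]:
        raise ValueError(
            f"reference window of {REFERENCE_SPAN_MS:.0f} ms starting at "
            f"{reference_start_ms:.0f} ms does not fit in the envelope")
    ref = envelope[i0:i0 + n_ref]
    return float(np.mean(ref) + 3.0 * np.std(ref))


def aggregate_envelope(rec: Recording, grid: ElectrodeGrid,
                       window_ms: float = 100.0,
                       region: str = SUBMENTAL) -> np.ndarray:
    """Mean envelope across one region's channels (default submental,
    where swallow initiation is expressed first)."""
    idx = [c - 1 for c in grid.channels_in_region(region)]
    env = compute_envelope(rec.signal[:, idx], rec.fs, window_ms=window_ms)
    return env.mean(axis=1)


def detect_swallow(envelope: np.ndarray, fs: float, threshold: float,
                   mode: str = "healthy",
                   search_start_ms: float = 0.0,
                   min_dwell_ms: float = 0.0) -> SwallowEvent:
    """First threshold crossing of the aggregate envelope.

    ``T_c`` is the time of the first sample at or above *threshold* (from
    ``search_start_ms`` on).  With ``min_dwell_ms`` > 0 the envelope must
    stay above the threshold for at least that long before the crossing
    counts; a genuine burst exceeds the threshold for hundreds of
    milliseconds, while resting-noise grazes of a mean + 3 SD threshold
    last only a few tens.  Raises :class:`NoSwallowDetectedError` if no
    sample crosses, and :class:`WindowBoundaryError` if the derived window
    would leave the recording.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    envelope = np.asarray(envelope, dtype=float)
    i0 = int(round(search_start_ms * fs / 1000.0))
    mask = envelope[i0:] >= threshold
    dwell = max(1, int(round(min_dwell_ms * fs / 1000.0)))
    if dwell > 1 and mask.any():
        runs = np.convolve(mask.astype(int), np.ones(dwell, dtype=int),
                           mode="valid")
        starts = np.nonzero(runs == dwell)[0]
        above = starts if starts.size else np.array([], dtype=int)
    else:
        above = np.nonzero(mask)[0]
    if above.size == 0:
        raise NoSwallowDetectedError(
            f"envelope never reaches threshold {threshold:.3g} uV"
            + (f" for {min_dwell_ms:.0f} ms" if dwell > 1 else ""))
    t_c = (i0 + int(above[0])) / fs * 1000.0
    ev = SwallowEvent(t_c_ms=t_c, threshold_uv=float(threshold), mode=mode)
    duration_ms = envelope.shape[0] / fs * 1000.0
    if ev.t_s_ms < 0 or ev.t_e_ms > duration_ms:
        raise WindowBoundaryError(
            f"swallow window [{ev.t_s_ms:.0f}, {ev.t_e_ms:.0f}] ms outside "
            f"recording of {duration_ms:.0f} ms")
    return ev


def detect_swallows(envelope: np.ndarray, fs: float, threshold: float,
                    mode: str = "healthy",
                    search_start_ms: float = 0.0,
                    min_dwell_ms: float = 0.0,
                    max_events: int = 10) -> list[SwallowEvent]:
    """All swallows in a trial: detection re-arms after each ``T_e``.

    Repeat swallows (common in severe dysphagia) appear as additional
    events.  Events whose window would cross the recording end are dropped.
    """
    events: list[SwallowEvent] = []
    start = search_start_ms
    duration_ms = np.asarray(envelope).shape[0] / fs * 1000.0
    while len(events) < max_events:
        try:
            ev = detect_swallow(envelope, fs, threshold, mode=mode,
                                search_start_ms=start,
                                min_dwell_ms=min_dwell_ms)
        except (NoSwallowDetectedError, WindowBoundaryError):
            break
        events.append(ev)
        start = ev.t_e_ms
        if start + POST_ONSET_MS > duration_ms:
            break
    if not events:
        raise NoSwallowDetectedError("no complete swallow window in trial")
    return events


def extract_window(rec: Recording, start_ms: float,
                   duration_ms: float) -> Recording:
    """Slice all 64 channels over ``[start, start + duration)`` ms,
    propagating metadata."""
    return rec.slice_ms(start_ms, duration_ms)
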