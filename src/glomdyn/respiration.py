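"""Inhalation detection from airflow or thermistor respiration traces.

The flow convention is inhalation-downward: the inhalation peak is the
trough of the external flow signal, and inhalation onset is the point of
maximal (most negative) slope in the exhalation-to-inhalation transition.
Analyses restricted to resting-frequency breathing drop inhalations closer
than a minimum period (default 200 ms, i.e. a 5-Hz ceiling).
"""
from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .trace import InhalationEvents, InsufficientDataError, Trace

__all__ = ["detect_inhalations", "filter_min_period", "robust_sd"]


def robust_sd(values: np.ndarray) -> float:
    """MAD-based robust standard deviation."""
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_inhalations(flow: Trace, min_prominence: float | None = None,
                       invert: bool = False, source: str = "flow") -> InhalationEvents:
    """Detect inhalation troughs and onsets from a respiration trace.

    Parameters
    ----------
    flow : Trace
        Respiration signal, inhalation as a negative deflection.
    min_prominence : float, optional
        Trough prominence threshold in flow units; default 1× the robust
        (MAD-based) SD of the trace, so a pure oscillation (whose trough
        prominence is roughly twice its robust SD) is always detected.
    invert : bool
        Flip polarity first (for thermistor signals with inhalation upward).

    A constant trace yields an empty event list, not an error.  Detection is
    invariant to adding a constant to the flow.
    """
    if flow.duration_s < 2.0:
        raise InsufficientDataError("need at least 2 s of respiration data")
    x = -flow.values if invert else flow.values
    if min_prominence is None:
        sd = robust_sd(x)
        if sd == 0.0:
            return InhalationEvents(np.array([]), np.array([]), source)
        min_prominence = sd
    trough_idx, _ = find_peaks(-x, prominence=min_prominence)
    if trough_idx.size == 0:
        return InhalationEvents(np.array([]), np.array([]), source)

    # Maxima bound the search window for each trough's onset: the onset is
    # the most negative derivative between the preceding flow maximum
    # (exhalation peak) and the trough.
    peak_idx, _ = find_peaks(x, prominence=min_prominence)
    dx = np.gradient(x)
    onsets = np.empty(trough_idx.size)
    t = flow.time_s
    for k, ti in enumerate(trough_idx):
        prev_peaks = peak_idx[peak_idx < ti]
        lo = int(prev_peaks[-1]) if prev_peaks.size else max(int(trough_idx[k - 1]) if k else 0, 0)
        seg = dx[lo:ti + 1]
        onsets[k] = t[lo + int(np.argmin(seg))] if seg.size else t[ti]
    # Enforce strictly increasing onsets (flat segments can tie).
    keep = np.ones(trough_idx.size, dtype=bool)
    for k in range(1, trough_idx.size):
        if onsets[k] <= onsets[k - 1]:
            keep[k] = False
    return InhalationEvents(onsets[keep], t[trough_idx[keep]], source)


def filter_min_period(events: InhalationEvents,
                      min_period_s: float = 0.2) -> InhalationEvents:
    """Drop inhalations following the last retained one by less than
    ``min_period_s`` (greedy left-to-right scan; the earlier event of a close
    pair is kept)."""
    if len(events) == 0:
        return InhalationEvents(np.array([]), np.array([]), events.source)
    keep = [0]
    last = events.peak_s[0]
    for i in range(1, len(events)):
        if events.peak_s[i] - last >= min_period_s:
            keep.append(i)
            last = events.peak_s[i]
    keep = np.asarray(keep)
    return InhalationEvents(events.onset_s[keep], events.peak_s[keep], events.source)
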