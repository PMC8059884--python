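"""Multi-inhalation response-shape statistics.

Three complementary views of how a glomerular signal evolves over a
multi-sniff odorant presentation:

* **Adaptation index** (T2 − T1)/Tmax — the change in per-inhalation peak
  ΔF between the first (T1) and second-to-last (T2) inhalation of the
  presentation, normalized by the presentation maximum.  Negative values
  indicate adaptation, positive facilitation.
* **Sniff coherence** — magnitude-squared coherence (Welch estimate)
  between the fluorescence trace and an idealized inhalation pulse train,
  read out at the inhalation frequency; quantifies respiratory locking.
* **Pattern decorrelation** — Pearson correlation of the across-ROI
  response vector in successive 387-ms bins against the first bin,
  omitting the first 65 ms of the presentation to account for odorant
  arrival delays; computed on all ROIs without response thresholding.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .trace import (
    GlomdynError,
    InhalationEvents,
    InsufficientDataError,
    OdorEvent,
    Trace,
)

__all__ = [
    "AdaptationIndex",
    "DecorrelationSeries",
    "adaptation_index",
    "sniff_coherence",
    "pattern_decorrelation",
    "DECORR_BIN_S",
    "DECORR_SKIP_S",
]

DECORR_BIN_S = 0.387
DECORR_SKIP_S = 0.065
_N_BINS = 5


@dataclass
class AdaptationIndex:
    """Per-inhalation peak summary for one glomerulus-odor presentation."""

    T1: float
    T2: float
    Tmax: float
    index: float
    peaks: np.ndarray


def adaptation_index(trace: Trace, events: InhalationEvents,
                     odor: OdorEvent, reference: str = "onset",
                     tail_s: float = 0.5) -> AdaptationIndex:
    """(T2 − T1)/Tmax over the inhalations of one odorant presentation.

    Per-inhalation peaks are maxima over [event_i, event_{i+1}) windows;
    the final window closes at odor offset + ``tail_s``.  Tmax is the
    maximum ΔF over the whole presentation, so the index lies in [−1, 1]
    and is invariant to positive scaling of the trace.
    """
    during = events.during(odor.onset_s, odor.offset_s, reference)
    times = during.times(reference)
    if times.size < 3:
        raise InsufficientDataError(
            f"need >= 3 inhalations during odor, got {times.size}")
    bounds = np.append(times, odor.offset_s + tail_s)
    peaks = np.array([
        float(trace.slice_s(lo, hi).max()) for lo, hi in zip(bounds[:-1], bounds[1:])
    ])
    t1 = peaks[0]
    t2 = peaks[-2]
    tmax = float(trace.slice_s(odor.onset_s, odor.offset_s + tail_s).max())
    if tmax <= 0:
        raise GlomdynError("presentation maximum must be positive")
    return AdaptationIndex(t1, t2, tmax, (t2 - t1) / tmax, peaks)


def _pulse_train(n: int, rate_hz: float, freq_hz: float,
                 pulse_width_s: float = 0.050) -> np.ndarray:
    t = np.arange(n) / rate_hz
    return ((t % (1.0 / freq_hz)) < pulse_width_s).astype(float)


def sniff_coherence(trace: Trace, freq_hz: float = 2.0,
                    segment_s: float = 2.0, pulse_width_s: float = 0.050) -> float:
    """Magnitude-squared coherence between the trace and an idealized
    inhalation pulse train (rectangular pulses at ``freq_hz``), evaluated at
    the spectral bin nearest ``freq_hz``.

    Welch estimate: Hann window, ``segment_s``-long segments, 50% overlap.
    Needs at least two segments of data.
    """
    nperseg = int(round(segment_s * trace.rate_hz))
    if len(trace) < int(1.5 * nperseg) + 1:
        raise InsufficientDataError(
            f"trace too short for coherence: need >= {int(1.5 * nperseg) + 1} samples")
    pulses = _pulse_train(len(trace), trace.rate_hz, freq_hz, pulse_width_s)
    f, cxy = sps.coherence(trace.values, pulses, fs=trace.rate_hz,
                           window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
    return float(cxy[np.argmin(np.abs(f - freq_hz))])


@dataclass
class DecorrelationSeries:
    """Pearson r of the population vector in bins 1..5 against bin 1.
    Bins with a zero-variance vector carry ``nan`` and are flagged."""

    r_per_bin: np.ndarray
    bin_width_s: float = DECORR_BIN_S
    skip_s: float = DECORR_SKIP_S
    undefined_bins: tuple[int, ...] = ()


def pattern_decorrelation(traces_by_roi: dict[int, Trace],
                          odor: OdorEvent,
                          bin_width_s: float = DECORR_BIN_S,
                          skip_s: float = DECORR_SKIP_S) -> DecorrelationSeries:
    """Time-binned decorrelation of the across-ROI response pattern.

    Uses all provided ROIs without thresholding.  Five bins of
    ``bin_width_s`` starting ``skip_s`` after odorant onset must fit inside
    the presentation (plus the skip).
    """
    if len(traces_by_roi) < 3:
        raise InsufficientDataError("need >= 3 ROIs for a population vector")
    needed = skip_s + _N_BINS * bin_width_s
    if odor.duration_s + 1e-9 < needed:
        raise GlomdynError(
            f"odor presentation {odor.duration_s:.3f} s too short for "
            f"{_N_BINS} bins of {bin_width_s} s after a {skip_s} s skip")
    start = odor.onset_s + skip_s
    roi_ids = sorted(traces_by_roi)
    bins = np.empty((_N_BINS, len(roi_ids)))
    for k in range(_N_BINS):
        lo = start + k * bin_width_s
        hi = lo + bin_width_s
        for j, rid in enumerate(roi_ids):
            seg = traces_by_roi[rid].slice_s(lo, hi)
            if seg.size == 0:
                raise GlomdynError("empty time bin; trace does not cover window")
            bins[k, j] = seg.mean()
    r = np.empty(_N_BINS)
    undefined = []
    first = bins[0]
    for k in range(_N_BINS):
        if np.std(first) == 0.0 or np.std(bins[k]) == 0.0:
            r[k] = np.nan
            undefined.append(k)
        else:
            r[k] = stats.pearsonr(first, bins[k])[0]
    return DecorrelationSeries(r, bin_width_s, skip_s, tuple(undefined))
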