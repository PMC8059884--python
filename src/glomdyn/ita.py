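"""Inhalation-triggered averaging (ITA) and transient kinetics.

An ITA is the pointwise mean of unfiltered trace segments aligned to an
inhalation reference (onset or flow trough).  For low-frequency artificial
inhalation the default window is [0, 4) s after inhalation onset (17
inhalations over a 70-s presentation at 0.25 Hz); for awake recordings the
window is [−0.3, 0.4) s around the inhalation peak, which is the more robust
timing reference.

Kinetic metrics follow the transient-analysis conventions of event-triggered
fluorescence work: onset latency is the first sustained threshold crossing
(3× baseline SD held for ≥ 20 ms by default), time-to-peak is measured from
t = 0 to the global maximum (first sample on plateau ties), FWHM is the
width at half of (peak − baseline mean) with linear interpolation at the
crossings, and the decay time constant comes from a single-exponential fit
from the peak of the unfiltered ITA to the end of the window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .trace import GlomdynError, InhalationEvents, InsufficientDataError, Trace

__all__ = [
    "ITAResult",
    "ItaMetrics",
    "compute_ita",
    "ita_metrics",
    "fit_decay",
    "median_relative_latencies",
    "RelativeLatencies",
    "EmptyItaError",
    "FitFailureError",
    "analyze_ita",
]

ARTIFICIAL_WINDOW_S = (0.0, 4.0)
AWAKE_WINDOW_S = (-0.3, 0.4)
AWAKE_BASELINE_S = (-0.3, -0.1)


class EmptyItaError(GlomdynError):
    """No inhalation segment lies fully inside the trace."""


class FitFailureError(GlomdynError):
    """The exponential decay fit did not converge or is degenerate."""


@dataclass
class ItaMetrics:
    """Kinetics of one ITA waveform.  ``responded`` is False when no sample
    clears the onset threshold; the remaining fields are then undefined and
    set to ``nan`` (they never propagate silently)."""

    responded: bool
    onset_latency_s: float = np.nan
    time_to_peak_s: float = np.nan
    fwhm_s: float = np.nan
    peak_dff: float = np.nan


@dataclass
class ITAResult:
    """ITA waveform plus kinetics for one glomerulus-odor pair."""

    waveform: Trace
    n_inhalations: int
    metrics: ItaMetrics
    decay_tau_s: float = np.nan


def compute_ita(trace: Trace, events: InhalationEvents,
                window_s: tuple[float, float] = ARTIFICIAL_WINDOW_S,
                reference: str = "onset") -> Trace:
    """Pointwise mean of trace segments aligned to each inhalation.

    Only events whose full window lies inside the trace contribute.  The
    returned waveform has t = 0 at the inhalation reference.
    """
    lo, hi = window_s
    if hi <= lo:
        raise GlomdynError("ITA window must have positive length")
    n_win = int(round((hi - lo) * trace.rate_hz))
    t_ref = events.times(reference)
    t_end = trace.t0_s + trace.duration_s
    segments = []
    for t_e in t_ref:
        start = t_e + lo
        i0 = int(round((start - trace.t0_s) * trace.rate_hz))
        if i0 < 0 or i0 + n_win > len(trace):
            continue
        segments.append(trace.values[i0:i0 + n_win])
    if not segments:
        raise EmptyItaError(
            f"no inhalation window [{lo}, {hi}) s fits inside the trace "
            f"[{trace.t0_s}, {t_end}) s")
    waveform = np.mean(segments, axis=0)
    return Trace(waveform, trace.rate_hz, lo, units=trace.units)


def _half_crossings(t: np.ndarray, y: np.ndarray, half: float,
                    i_peak: int) -> tuple[float, float]:
    """Linear-interpolated times where y crosses ``half`` on either side of
    the peak; falls back to the window edges if a side never drops below."""
    t_left = t[0]
    for i in range(i_peak, 0, -1):
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            t_left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    t_right = t[-1]
    for i in range(i_peak, y.size - 1):
        if y[i] >= half > y[i + 1]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            t_right = t[i] + frac * (t[i + 1] - t[i])
            break
    return t_left, t_right


def ita_metrics(waveform: Trace, baseline_sd: float,
                *, threshold_sd: float = 3.0, hold_s: float = 0.020,
                baseline_mean: float | None = None,
                polarity: int = 1) -> ItaMetrics:
    """Onset latency, time-to-peak, FWHM and peak amplitude of an ITA.

    ``polarity=-1`` analyzes inhalation-linked decreases on the negated
    waveform (the returned peak is then the trough amplitude, negative).
    ``baseline_mean`` defaults to the mean of pre-zero samples when the
    window extends before t = 0, else 0 (ΔF/F convention).
    """
    t = waveform.time_s
    y = polarity * waveform.values.astype(float)
    if baseline_mean is None:
        pre = y[t < 0]
        baseline_mean = float(pre.mean()) if pre.size else 0.0
    y = y - baseline_mean

    post = t >= 0
    if not post.any():
        raise GlomdynError("ITA window contains no samples at t >= 0")
    y_post = y[post]
    t_post = t[post]

    threshold = max(threshold_sd * baseline_sd, 1e-12)
    hold_n = max(int(round(hold_s * waveform.rate_hz)), 1)
    above = y_post > threshold
    onset_idx = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= hold_n:
            onset_idx = i - hold_n + 1
            break
    if onset_idx is None:
        return ItaMetrics(responded=False)

    i_peak = int(np.argmax(y_post))  # first occurrence on plateau ties
    peak = float(y_post[i_peak])
    half = 0.5 * peak
    t_l, t_r = _half_crossings(t_post, y_post, half, i_peak)
    return ItaMetrics(
        responded=True,
        onset_latency_s=float(t_post[onset_idx]),
        time_to_peak_s=float(t_post[i_peak]),
        fwhm_s=float(t_r - t_l),
        peak_dff=float(polarity * peak + (baseline_mean if polarity == 1 else -baseline_mean)),
    )


def fit_decay(waveform: Trace, polarity: int = 1) -> float:
    """Decay time constant from a single-exponential least-squares fit
    ``A·exp(−(t−t_peak)/τ) + C`` over [t_peak, end] of the unfiltered ITA.

    Raises :class:`FitFailureError` when fewer than 5 samples follow the
    peak, the fit fails to converge, or the tail is too flat for τ to be
    identified (τ̂ exceeding 100× the fitted span is treated as a τ→∞
    guard).
    """
    t = waveform.time_s
    y = polarity * waveform.values.astype(float)
    post = t >= 0
    y_post, t_post = y[post], t[post]
    i_peak = int(np.argmax(y_post))
    tail_t = t_post[i_peak:] - t_post[i_peak]
    tail_y = y_post[i_peak:]
    if tail_y.size < 5:
        raise FitFailureError("need at least 5 samples after the peak")
    span = float(tail_t[-1])
    amp0 = float(tail_y[0] - tail_y[-1])
    if abs(amp0) < 1e-12 or np.ptp(tail_y) < 1e-12:
        raise FitFailureError("flat tail: decay constant unidentified")

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    # Initialize tau from the observed 1/e crossing of the tail.
    target = tail_y[-1] + amp0 / np.e
    below = np.flatnonzero(tail_y <= target) if amp0 > 0 else np.flatnonzero(tail_y >= target)
    tau0 = float(tail_t[below[0]]) if below.size and tail_t[below[0]] > 0 else span / 5.0
    try:
        popt, _ = curve_fit(
            model, tail_t, tail_y,
            p0=[amp0, max(tau0, 1e-3), float(tail_y[-1])],
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 1e4, np.inf]),
            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"decay fit did not converge: {exc}") from exc
    tau = float(popt[1])
    if tau > 100.0 * span:
        raise FitFailureError(f"fitted tau {tau:.3g} s exceeds 100x the fitted span")
    return tau


def analyze_ita(trace: Trace, events: InhalationEvents, baseline_sd: float,
                window_s: tuple[float, float] = ARTIFICIAL_WINDOW_S,
                reference: str = "onset", **metric_kwargs) -> ITAResult:
    """Convenience wrapper: average, extract kinetics, fit the decay."""
    lo, hi = window_s
    t_ref = events.times(reference)
    n_used = int(np.sum((t_ref + lo >= trace.t0_s - 1e-9)
                        & (t_ref + hi <= trace.t0_s + trace.duration_s + 1e-9)))
    waveform = compute_ita(trace, events, window_s, reference)
    metrics = ita_metrics(waveform, baseline_sd, **metric_kwargs)
    tau = np.nan
    if metrics.responded:
        try:
            tau = fit_decay(waveform, polarity=metric_kwargs.get("polarity", 1))
        except FitFailureError:
            tau = np.nan
    return ITAResult(waveform, n_used, metrics, tau)


@dataclass
class RelativeLatencies:
    """Latencies centered on the session median, with spread summaries."""

    centered_s: np.ndarray
    range_10_90_s: float
    sd_s: float


def median_relative_latencies(latencies_s: np.ndarray) -> RelativeLatencies:
    """Center a session's latency measurements on their median.

    Absolute latencies depend on the airflow waveform and sensor, so spread
    is reported relative to the per-session median: the 10th–90th percentile
    range and the SD of the centered values.
    """
    lat = np.asarray(latencies_s, dtype=float)
    if lat.size == 0:
        raise InsufficientDataError("need at least one latency")
    centered = lat - np.median(lat)
    p10, p90 = np.percentile(centered, [10, 90])
    return RelativeLatencies(centered, float(p90 - p10), float(centered.std(ddof=0)))
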