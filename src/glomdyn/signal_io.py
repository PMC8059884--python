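"""Trace I/O and preprocessing: ΔF/F, shape-preserving resampling, Gaussian
low-pass filtering, ROI extraction from image stacks, and ΔF response maps.

ΔF/F uses a pre-stimulus baseline mean (default: the 1–2 s window before
odorant onset).  Resampling to the 150-Hz analysis rate uses monotone
piecewise-cubic (PCHIP) interpolation, which passes through every original
sample without overshoot.  Low-pass filtering is zero-phase Gaussian
smoothing with the half-power point at the stated cutoff; display response
maps use ΔF (not ΔF/F) smoothed with a σ = 1 pixel Gaussian kernel to avoid
amplifying noise from non-fluorescent regions.
"""
from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .trace import (
    DegenerateBaselineError,
    GlomdynError,
    InvalidSpecError,
    Trace,
)

__all__ = [
    "RoiSet",
    "extract_roi_traces",
    "dff",
    "resample_shape_preserving",
    "gaussian_lowpass",
    "gaussian_sigma_for_cutoff",
    "response_map",
    "write_trace_csv",
    "read_trace_csv",
    "MissingRoiError",
    "WindowError",
]

ANALYSIS_RATE_HZ = 150.0


class MissingRoiError(GlomdynError):
    """Requested ROI id is absent from the label mask."""


class WindowError(GlomdynError):
    """A requested time window falls outside the available data."""


class RoiSet:
    """Integer label image defining regions of interest (0 = background)."""

    def __init__(self, labels: np.ndarray):
        labels = np.asarray(labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise InvalidSpecError("RoiSet labels must be a 2-D integer image")
        if labels.min() < 0:
            raise InvalidSpecError("ROI ids must be non-negative")
        self.labels = labels

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, roi_id: int) -> np.ndarray:
        m = self.labels == roi_id
        if not m.any():
            raise MissingRoiError(f"ROI id {roi_id} not present in mask")
        return m


def extract_roi_traces(stack: np.ndarray, rois: RoiSet, rate_hz: float,
                       roi_ids=None) -> dict[int, Trace]:
    """Unweighted per-frame mean over each ROI's pixels (units raw_F)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidSpecError("stack must be (frames, y, x)")
    if stack.shape[1:] != rois.labels.shape:
        raise InvalidSpecError("stack frames and ROI mask shapes differ")
    if roi_ids is None:
        roi_ids = rois.ids
    out: dict[int, Trace] = {}
    flat = stack.reshape(stack.shape[0], -1)
    for rid in roi_ids:
        idx = np.flatnonzero(rois.mask(int(rid)).ravel())
        out[int(rid)] = Trace(flat[:, idx].mean(axis=1), rate_hz, 0.0, units="raw_F")
    return out


def dff(trace: Trace, baseline_window_s: tuple[float, float]) -> Trace:
    """Fractional fluorescence change (F − F̄)/F̄ with F̄ the baseline mean.

    The unit tag forbids re-normalizing an already ΔF/F trace.
    """
    if trace.units == "dFF":
        raise InvalidSpecError("trace is already ΔF/F; refusing double normalization")
    lo, hi = baseline_window_s
    if hi <= lo:
        raise WindowError("baseline window must have positive length")
    t_end = trace.t0_s + trace.duration_s
    if lo < trace.t0_s - 1e-9 or hi > t_end + 1e-9:
        raise WindowError(f"baseline window [{lo}, {hi}) outside trace [{trace.t0_s}, {t_end})")
    base = trace.slice_s(lo, hi)
    if base.size == 0:
        raise WindowError("baseline window contains no samples")
    f0 = float(base.mean())
    if f0 <= 0:
        raise DegenerateBaselineError(f"baseline mean must be positive, got {f0}")
    return trace.with_values((trace.values - f0) / f0, units="dFF")


def resample_shape_preserving(trace: Trace, target_rate_hz: float = ANALYSIS_RATE_HZ) -> Trace:
    """Upsample with monotone piecewise-cubic interpolation.

    The interpolant passes through all original samples and cannot overshoot
    the local data range.  Downsampling is not supported.
    """
    if target_rate_hz < trace.rate_hz:
        raise InvalidSpecError(
            f"target rate {target_rate_hz} Hz below source rate {trace.rate_hz} Hz; "
            "downsampling is not supported")
    if target_rate_hz == trace.rate_hz:
        return replace(trace)
    t_src = trace.time_s
    interp = PchipInterpolator(t_src, trace.values)
    n_out = int(np.floor((t_src[-1] - trace.t0_s) * target_rate_hz)) + 1
    t_out = trace.t0_s + np.arange(n_out) / target_rate_hz
    return Trace(interp(t_out), target_rate_hz, trace.t0_s, units=trace.units)


def gaussian_sigma_for_cutoff(cutoff_hz: float) -> float:
    """Temporal σ (seconds) putting the Gaussian filter's half-power point
    (gain 1/√2) at the cutoff frequency: σ_t = √(ln 2)/(2π·f_c)."""
    return np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff_hz)


def gaussian_lowpass(trace: Trace, cutoff_hz: float) -> Trace:
    """Zero-phase Gaussian low-pass; reflection padding at the edges.

    DC gain is 1, so the trace mean is preserved and the filter commutes with
    additive constants.
    """
    nyquist = trace.rate_hz / 2.0
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise InvalidSpecError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff_hz}")
    sigma_samples = gaussian_sigma_for_cutoff(cutoff_hz) * trace.rate_hz
    smooth = gaussian_filter1d(trace.values, sigma_samples, mode="reflect")
    return trace.with_values(smooth)


def response_map(stack: np.ndarray, baseline_window: tuple[int, int],
                 odor_window: tuple[int, int], smoothing_sigma_px: float = 1.0) -> np.ndarray:
    """ΔF response map: pixelwise mean(odor frames) − mean(baseline frames),
    Gaussian-smoothed in space (σ in pixels; σ = 0 returns the raw map).
    Windows are half-open frame-index intervals."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise InvalidSpecError("stack must be (frames, y, x)")
    nf = stack.shape[0]
    for lo, hi in (baseline_window, odor_window):
        if not (0 <= lo < hi <= nf):
            raise WindowError(f"frame window [{lo}, {hi}) outside stack of {nf} frames")
    delta = stack[slice(*odor_window)].mean(axis=0) - stack[slice(*baseline_window)].mean(axis=0)
    if smoothing_sigma_px > 0:
        delta = gaussian_filter(delta, smoothing_sigma_px, mode="reflect")
    return delta


def write_trace_csv(path: str | Path, traces: dict[str, Trace]) -> None:
    """Write named traces sharing one clock to CSV + JSON sidecar (units, rate)."""
    items = list(traces.items())
    if not items:
        raise InvalidSpecError("no traces to write")
    first = items[0][1]
    for name, tr in items:
        if len(tr) != len(first) or tr.rate_hz != first.rate_hz:
            raise InvalidSpecError(f"trace {name!r} not aligned with the others")
    df = pd.DataFrame({"time_s": first.time_s, **{k: v.values for k, v in items}})
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.8g")
    sidecar = {"rate_hz": first.rate_hz, "t0_s": first.t0_s,
               "units": {k: v.units for k, v in items}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_trace_csv(path: str | Path) -> dict[str, Trace]:
    """Read traces written by :func:`write_trace_csv` (sidecar optional;
    rate inferred from the time column if absent)."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        rate, t0 = sidecar["rate_hz"], sidecar["t0_s"]
        units = sidecar.get("units", {})
    else:
        t = df["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t)))
        t0 = float(t[0])
        units = {}
    return {c: Trace(df[c].to_numpy(), rate, t0, units=units.get(c, "raw_F"))
            for c in df.columns if c != "time_s"}
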