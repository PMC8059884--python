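"""Response classification and odor-tuning sparseness.

A glomerulus-odor response is called significant when it deviates from
baseline by at least ±7 SD — a deliberately conservative criterion chosen to
keep false positives near 1%.  Excitation is scored on the 2-Hz low-passed
trace as 0.95 × the maximum z during the odor presentation; suppression on
the 0.5-Hz low-passed trace as the 15th percentile of z from odorant onset
to 500 ms after offset.  The z normalization pools baseline segments
([−2, −0.5] s before onset) across the whole odor panel for each ROI, so a
single noise estimate serves all of that ROI's odors.

Tuning breadth uses lifetime sparseness over the thresholded response
matrix:

    S = (1 − (Σ r_j / N)² / Σ (r_j² / N)) / (1 − 1/N)

with N the number of odors and r_j the thresholded |z| response to odor j
(sub-threshold entries set to 0); S = 1 for a one-hot tuning vector, 0 for
uniform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import gaussian_lowpass
from .trace import DegenerateBaselineError, GlomdynError, Trace

__all__ = [
    "ResponseClassification",
    "SparsenessResult",
    "zscore_responses",
    "classify_response",
    "classify_roi",
    "lifetime_sparseness",
    "DEFAULT_THRESHOLD_SD",
    "EXCITE_CUTOFF_HZ",
    "SUPPRESS_CUTOFF_HZ",
    "BASELINE_WINDOW_REL_S",
]

DEFAULT_THRESHOLD_SD = 7.0
EXCITE_CUTOFF_HZ = 2.0
SUPPRESS_CUTOFF_HZ = 0.5
#: Baseline window relative to odorant onset (0.5–2 s before onset).
BASELINE_WINDOW_REL_S = (-2.0, -0.5)


@dataclass
class ResponseClassification:
    """Scores and label for one ROI-odor pair."""

    z_excite: float
    z_suppress: float
    label: str  # excitatory | suppressive | biphasic | none
    threshold_sd: float = DEFAULT_THRESHOLD_SD


def zscore_responses(traces_by_odor: dict[str, Trace],
                     baseline_window_s: tuple[float, float]) -> dict[str, Trace]:
    """z-score one ROI's ΔF/F traces using a baseline pooled over all odors.

    ``baseline_window_s`` is an absolute time window shared by all traces
    (the protocol presents each odor at the same within-trial time).  The
    pooled mean and SD come from the concatenated baseline segments of every
    odor's trace for this ROI.
    """
    segments = [tr.slice_s(*baseline_window_s) for tr in traces_by_odor.values()]
    pooled = np.concatenate(segments)
    if pooled.size == 0:
        raise GlomdynError("baseline window contains no samples")
    mu = float(pooled.mean())
    sigma = float(pooled.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateBaselineError("pooled baseline SD is zero")
    return {odor: tr.with_values((tr.values - mu) / sigma, units="zscore")
            for odor, tr in traces_by_odor.items()}


def classify_response(z_2hz: Trace, z_05hz: Trace,
                      odor_window_s: tuple[float, float],
                      threshold: float = DEFAULT_THRESHOLD_SD,
                      excite_percentile: bool = False) -> ResponseClassification:
    """Label one ROI-odor pair from its two filtered z traces.

    ``excite_percentile=True`` switches the excitation score from the
    literal 0.95 × max reading to the 95th percentile of the odor-window
    signal (default is the literal reading).
    """
    on, off = odor_window_s
    exc_seg = z_2hz.slice_s(on, off)
    sup_seg = z_05hz.slice_s(on, off + 0.5)
    if exc_seg.size == 0 or sup_seg.size == 0:
        raise GlomdynError("odor window outside trace")
    if excite_percentile:
        z_exc = float(np.percentile(exc_seg, 95))
    else:
        z_exc = 0.95 * float(exc_seg.max())
    z_sup = float(np.percentile(sup_seg, 15))
    excited = z_exc >= threshold
    suppressed = z_sup <= -threshold
    if excited and suppressed:
        label = "biphasic"
    elif excited:
        label = "excitatory"
    elif suppressed:
        label = "suppressive"
    else:
        label = "none"
    return ResponseClassification(z_exc, z_sup, label, threshold)


def classify_roi(dff_by_odor: dict[str, Trace],
                 odor_window_s: tuple[float, float],
                 baseline_window_s: tuple[float, float] | None = None,
                 threshold: float = DEFAULT_THRESHOLD_SD,
                 excite_percentile: bool = False) -> dict[str, ResponseClassification]:
    """Full classification chain for one ROI across its odor panel.

    Filtering precedes z-scoring: each averaged ΔF/F trace is low-passed at
    2 Hz (excitation branch) and 0.5 Hz (suppression branch), then each
    branch is z-scored with its own pooled baseline.
    """
    on, _ = odor_window_s
    if baseline_window_s is None:
        baseline_window_s = (on + BASELINE_WINDOW_REL_S[0], on + BASELINE_WINDOW_REL_S[1])
    f2 = {o: gaussian_lowpass(tr, EXCITE_CUTOFF_HZ) for o, tr in dff_by_odor.items()}
    f05 = {o: gaussian_lowpass(tr, SUPPRESS_CUTOFF_HZ) for o, tr in dff_by_odor.items()}
    z2 = zscore_responses(f2, baseline_window_s)
    z05 = zscore_responses(f05, baseline_window_s)
    return {o: classify_response(z2[o], z05[o], odor_window_s, threshold,
                                 excite_percentile)
            for o in dff_by_odor}


@dataclass
class SparsenessResult:
    """Lifetime sparseness of one glomerulus over an odor panel."""

    S: float
    N: int
    r: np.ndarray
    defined: bool = True


def lifetime_sparseness(r, n_odors: int | None = None) -> SparsenessResult:
    """Lifetime sparseness S ∈ [0, 1] of a thresholded response vector.

    ``r`` holds non-negative thresholded |z| responses (one per odor;
    sub-threshold entries zero).  Excitatory and suppressive components are
    scored in separate calls.  An all-zero vector leaves S undefined
    (``defined=False``), not an error.
    """
    r = np.asarray(r, dtype=float)
    n = int(n_odors) if n_odors is not None else r.size
    if n < 2:
        raise GlomdynError("sparseness needs at least two odors")
    if r.size != n:
        raise GlomdynError(f"expected {n} responses, got {r.size}")
    if np.any(r < 0):
        raise GlomdynError("thresholded responses must be non-negative")
    sum_sq = float(np.sum(r**2)) / n
    if sum_sq == 0.0:
        return SparsenessResult(np.nan, n, r, defined=False)
    mean_sq = (float(np.sum(r)) / n) ** 2
    s = (1.0 - mean_sq / sum_sq) / (1.0 - 1.0 / n)
    return SparsenessResult(float(s), n, r, defined=True)
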