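"""Concordance between simultaneously imaged glutamate and calcium signals.

For paired recordings of the same glomerulus through a fast glutamate
reporter and a slower calcium reporter, this module quantifies agreement in:

* response classification — joint label table and directional percentages
  (e.g., the fraction of pairs with an excitatory glutamate response that
  also show a significant calcium response);
* prevalence — a one-degree-of-freedom goodness-of-fit χ² comparing two
  response counts against equal expected counts;
* kinetics — Spearman rank correlation of onset latencies and peak times,
  and quartiles of the per-pair latency difference (calcium minus
  glutamate, so positive = calcium delayed);
* multi-sniff shape — Pearson correlation of paired adaptation indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trace import GlomdynError, InsufficientDataError

__all__ = [
    "ConcordanceSummary",
    "concordance_table",
    "two_count_chi2",
    "latency_concordance",
    "adaptation_concordance",
    "LABELS",
]

LABELS = ("excitatory", "suppressive", "biphasic", "none")


@dataclass
class ConcordanceSummary:
    """Joint classification table plus directional percentages."""

    counts: pd.DataFrame  # glu labels (rows) x ca labels (columns)
    n_pairs: int
    pct_glu_with_ca: float  # of glu-excitatory pairs, % also ca-excitatory
    pct_ca_with_glu: float  # of ca-excitatory pairs, % also glu-excitatory
    extras: dict = field(default_factory=dict)


def _excited(label: str) -> bool:
    return label in ("excitatory", "biphasic")


def concordance_table(class_glu: dict, class_ca: dict) -> ConcordanceSummary:
    """Joint label table over identical (roi, odor) keys.

    Directional percentages count pairs with an excitatory component in one
    channel that also have an excitatory component in the other; they are
    ``nan`` when the denominator is empty.
    """
    if set(class_glu) != set(class_ca):
        raise GlomdynError("glutamate and calcium classifications index different pairs")
    keys = sorted(class_glu)
    counts = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS))

    def _label(c):
        return c.label if hasattr(c, "label") else str(c)

    n_glu_exc = n_ca_exc = n_both = 0
    for k in keys:
        lg, lc = _label(class_glu[k]), _label(class_ca[k])
        counts.loc[lg, lc] += 1
        g, c = _excited(lg), _excited(lc)
        n_glu_exc += g
        n_ca_exc += c
        n_both += g and c
    pct_g = 100.0 * n_both / n_glu_exc if n_glu_exc else np.nan
    pct_c = 100.0 * n_both / n_ca_exc if n_ca_exc else np.nan
    return ConcordanceSummary(counts, len(keys), pct_g, pct_c)


def two_count_chi2(n1: int, n2: int) -> tuple[float, float]:
    """One-degree-of-freedom goodness-of-fit χ² of two observed counts
    against equal expected counts (n1 + n2)/2, with the χ²₁ survival
    function p value.  Symmetric in its arguments."""
    if n1 < 0 or n2 < 0:
        raise GlomdynError("counts must be non-negative")
    total = n1 + n2
    if total == 0:
        raise GlomdynError("at least one count must be positive")
    expected = total / 2.0
    chi2 = (n1 - expected) ** 2 / expected + (n2 - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class LatencyConcordance:
    rho_latency: float
    rho_peak: float
    dlat_median_s: float
    dlat_q1_s: float
    dlat_q3_s: float
    dpeak_median_s: float
    n_pairs: int


def _spearman_or_nan(x, y) -> float:
    """Spearman rho, or NaN when either vector is constant (rank-undefined)."""
    if np.std(np.asarray(x, dtype=float)) == 0.0 or np.std(np.asarray(y, dtype=float)) == 0.0:
        return float("nan")
    return float(stats.spearmanr(x, y)[0])


def latency_concordance(metrics_glu: pd.DataFrame,
                        metrics_ca: pd.DataFrame) -> LatencyConcordance:
    """Rank agreement and per-pair differences of ITA timing metrics.

    Both frames must share an index of (glomerulus, odor) pairs and carry
    ``onset_latency_s`` and ``time_to_peak_s`` columns.  Differences are
    calcium minus glutamate.
    """
    common = metrics_glu.index.intersection(metrics_ca.index)
    if len(common) < 5:
        raise InsufficientDataError(f"need >= 5 paired metrics, got {len(common)}")
    g = metrics_glu.loc[common]
    c = metrics_ca.loc[common]
    rho_lat = _spearman_or_nan(g["onset_latency_s"], c["onset_latency_s"])
    rho_peak = _spearman_or_nan(g["time_to_peak_s"], c["time_to_peak_s"])
    dlat = (c["onset_latency_s"] - g["onset_latency_s"]).to_numpy()
    dpeak = (c["time_to_peak_s"] - g["time_to_peak_s"]).to_numpy()
    q1, med, q3 = np.percentile(dlat, [25, 50, 75])
    return LatencyConcordance(rho_lat, rho_peak, float(med), float(q1), float(q3),
                              float(np.median(dpeak)), len(common))


def adaptation_concordance(adapt_glu, adapt_ca) -> float:
    """Pearson r of paired adaptation indices from the two channels."""
    x = np.asarray(adapt_glu, dtype=float)
    y = np.asarray(adapt_ca, dtype=float)
    if x.size != y.size:
        raise GlomdynError("paired index vectors must have equal length")
    if x.size < 5:
        raise InsufficientDataError(f"need >= 5 pairs, got {x.size}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan  # undefined-r flag
    return float(stats.pearsonr(x, y)[0])
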