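"""End-to-end analysis of a synthetic (or loaded) multi-glomerulus dataset.

Stages: inhalation detection → ΔF/F → inhalation-triggered averaging and
kinetics → response classification and sparseness → multi-sniff dynamics →
dual-channel concordance (when a calcium channel is present).  Each stage
returns a tidy DataFrame so results serialize directly to CSV.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dualcolor, dynamics, ita, respclass, respiration, signal_io
from .synthgen import SyntheticDataset
from .trace import GlomdynError, InhalationEvents, Trace

__all__ = ["AnalysisResult", "analyze_dataset", "dff_dataset"]


@dataclass
class AnalysisResult:
    """Tidy result tables from one pipeline run."""

    inhalations: InhalationEvents
    ita_metrics: pd.DataFrame          # per (glomerulus, odor, channel)
    classification: pd.DataFrame       # per (glomerulus, odor, channel)
    sparseness: pd.DataFrame           # per (glomerulus, channel)
    adaptation: pd.DataFrame           # per (glomerulus, odor, channel)
    coherence: pd.DataFrame            # per (glomerulus, odor, channel)
    decorrelation: pd.DataFrame        # per (odor, channel, bin)
    concordance: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "ita_metrics": self.ita_metrics,
            "classification": self.classification,
            "sparseness": self.sparseness,
            "adaptation": self.adaptation,
            "coherence": self.coherence,
            "decorrelation": self.decorrelation,
        }


def dff_dataset(ds: SyntheticDataset) -> dict:
    """ΔF/F every raw trace against the 1–2 s pre-onset baseline."""
    onset = ds.config.odor_onset_s
    window = (onset - 2.0, onset - 1.0)
    return {key: signal_io.dff(tr, window) for key, tr in ds.traces.items()}


def _baseline_sd(tr: Trace, onset_s: float) -> float:
    return float(tr.slice_s(onset_s - 2.0, onset_s - 0.5).std(ddof=0))


def analyze_dataset(ds: SyntheticDataset,
                    ita_window_s: tuple[float, float] | None = None,
                    threshold_sd: float = respclass.DEFAULT_THRESHOLD_SD) -> AnalysisResult:
    """Run the full pipeline on a dataset with known protocol."""
    cfg = ds.config
    events = respiration.filter_min_period(
        respiration.detect_inhalations(ds.respiration))
    dffs = dff_dataset(ds)
    onset = cfg.odor_onset_s
    offset = onset + cfg.odor_duration_s
    odor_window = (onset, offset)
    if ita_window_s is None:
        period = 1.0 / cfg.respiration.rate_hz
        ita_window_s = (0.0, min(4.0, period))

    gloms = sorted({g for g, _, _ in ds.traces})
    channels = list(cfg.channels)

    ita_rows, adapt_rows, coh_rows = [], [], []
    class_rows, sparse_rows, decor_rows = [], [], []

    for ch in channels:
        for g in gloms:
            by_odor = {o: dffs[(g, o, ch)] for o in cfg.odors}

            # --- ITA kinetics ------------------------------------------------
            for o, tr in by_odor.items():
                during = events.during(onset, offset, "onset")
                base_sd = _baseline_sd(tr, onset)
                row = {"glomerulus": g, "odor": o, "channel": ch,
                       "n_inhalations": len(during)}
                try:
                    res = ita.analyze_ita(tr, during, base_sd, ita_window_s, "onset")
                    m = res.metrics
                    row.update(responded=m.responded,
                               onset_latency_s=m.onset_latency_s,
                               time_to_peak_s=m.time_to_peak_s,
                               fwhm_s=m.fwhm_s, peak_dff=m.peak_dff,
                               decay_tau_s=res.decay_tau_s)
                except GlomdynError:
                    row.update(responded=False, onset_latency_s=np.nan,
                               time_to_peak_s=np.nan, fwhm_s=np.nan,
                               peak_dff=np.nan, decay_tau_s=np.nan)
                ita_rows.append(row)

            # --- classification + sparseness --------------------------------
            cls = respclass.classify_roi(by_odor, odor_window, threshold=threshold_sd)
            for o, c in cls.items():
                class_rows.append({"glomerulus": g, "odor": o, "channel": ch,
                                   "z_excite": c.z_excite, "z_suppress": c.z_suppress,
                                   "label": c.label, "threshold_sd": c.threshold_sd})
            r_exc = np.array([
                cls[o].z_excite if cls[o].label in ("excitatory", "biphasic") else 0.0
                for o in cfg.odors])
            r_sup = np.array([
                abs(cls[o].z_suppress) if cls[o].label in ("suppressive", "biphasic") else 0.0
                for o in cfg.odors])
            if len(cfg.odors) >= 2:
                s_exc = respclass.lifetime_sparseness(r_exc)
                s_sup = respclass.lifetime_sparseness(r_sup)
                sparse_rows.append({"glomerulus": g, "channel": ch,
                                    "S_excitatory": s_exc.S, "S_suppressive": s_sup.S})

            # --- adaptation + coherence --------------------------------------
            for o, tr in by_odor.items():
                row = {"glomerulus": g, "odor": o, "channel": ch}
                try:
                    ai = dynamics.adaptation_index(tr, events, ds.protocol.for_odor(o))
                    row.update(T1=ai.T1, T2=ai.T2, Tmax=ai.Tmax, index=ai.index)
                except GlomdynError:
                    row.update(T1=np.nan, T2=np.nan, Tmax=np.nan, index=np.nan)
                adapt_rows.append(row)
                seg = Trace(tr.slice_s(onset, offset), tr.rate_hz, onset, units=tr.units)
                try:
                    coh = dynamics.sniff_coherence(seg, cfg.respiration.rate_hz)
                except GlomdynError:
                    coh = np.nan
                coh_rows.append({"glomerulus": g, "odor": o, "channel": ch,
                                 "coherence": coh})

        # --- population decorrelation per odor -------------------------------
        for o in cfg.odors:
            by_roi = {g: dffs[(g, o, ch)] for g in gloms}
            try:
                series = dynamics.pattern_decorrelation(by_roi, ds.protocol.for_odor(o))
                for k, r in enumerate(series.r_per_bin):
                    decor_rows.append({"odor": o, "channel": ch, "bin": k + 1, "r": r})
            except GlomdynError as exc:
                warnings.warn(f"decorrelation skipped for odor {o!r}: {exc}", stacklevel=2)

    ita_df = pd.DataFrame(ita_rows)
    class_df = pd.DataFrame(class_rows)
    result = AnalysisResult(
        inhalations=events,
        ita_metrics=ita_df,
        classification=class_df,
        sparseness=pd.DataFrame(sparse_rows),
        adaptation=pd.DataFrame(adapt_rows),
        coherence=pd.DataFrame(coh_rows),
        decorrelation=pd.DataFrame(decor_rows),
    )

    if "glu" in channels and "ca" in channels:
        result.concordance = _concordance(result)
    return result


def _concordance(result: AnalysisResult) -> dict:
    """Dual-channel agreement from the per-channel tables."""
    cls = result.classification.set_index(["glomerulus", "odor"])
    glu = cls[cls["channel"] == "glu"]["label"].to_dict()
    ca = cls[cls["channel"] == "ca"]["label"].to_dict()
    summary = dualcolor.concordance_table(glu, ca)

    n_sup_glu = sum(1 for v in glu.values() if v in ("suppressive", "biphasic"))
    n_sup_ca = sum(1 for v in ca.values() if v in ("suppressive", "biphasic"))
    out = {
        "counts": summary.counts,
        "n_pairs": summary.n_pairs,
        "pct_glu_with_ca": summary.pct_glu_with_ca,
        "pct_ca_with_glu": summary.pct_ca_with_glu,
    }
    if n_sup_glu + n_sup_ca > 0:
        chi2, p = dualcolor.two_count_chi2(n_sup_ca, n_sup_glu)
        out["suppressive_chi2"] = chi2
        out["suppressive_chi2_p"] = p

    met = result.ita_metrics
    responded = met[met["responded"].astype(bool)].set_index(["glomerulus", "odor"])
    mg = responded[responded["channel"] == "glu"]
    mc = responded[responded["channel"] == "ca"]
    try:
        lat = dualcolor.latency_concordance(mg, mc)
        out.update(rho_latency=lat.rho_latency, rho_peak=lat.rho_peak,
                   dlat_median_s=lat.dlat_median_s, dlat_q1_s=lat.dlat_q1_s,
                   dlat_q3_s=lat.dlat_q3_s, n_latency_pairs=lat.n_pairs)
    except GlomdynError:
        pass

    ad = result.adaptation.dropna(subset=["index"]).set_index(["glomerulus", "odor"])
    ag = ad[ad["channel"] == "glu"]["index"]
    ac = ad[ad["channel"] == "ca"]["index"]
    common = ag.index.intersection(ac.index)
    if len(common) >= 5:
        out["r_adapt"] = dualcolor.adaptation_concordance(
            ag.loc[common].to_numpy(), ac.loc[common].to_numpy())
    return out
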