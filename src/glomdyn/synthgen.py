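"""Synthetic respiration, stimulus and glomerular-fluorescence generator.

The generator is phenomenological: it emulates the statistical structure the
downstream analysis assumes — inhalation-locked transients with glomerulus-
and odor-specific onset latency, rise/decay kinetics, per-inhalation gain
sequences (sustained / adapting / facilitating / suppressive / biphasic /
tonic), sensor kernels for a fast glutamate reporter versus a slower calcium
reporter, respiration at 0.25–2 Hz (artificial) or 3–6 Hz (awake), and
additive Gaussian noise — with full ground truth retained for validation.

Forward model for one glomerulus-odor trace (ΔF/F units)::

    x(t) = coupling * Σ_i gain_i * h(t - t_i - L)          (phasic part)
         + tonic_amp * (b * k)(t - L)                      (tonic part)
         + suppression_amp * (b * k)(t - L)                (suppression)
         + ε(t),   ε ~ N(0, noise_sd²)

where ``h`` is a difference-of-exponentials transient normalized to unit
peak, ``t_i`` the inhalation onsets during odor, ``L`` the total onset
latency (glomerulus latency + sensor latency offset), ``b`` the odor boxcar
and ``k`` a normalized exponential smoothing kernel.  Sensor kinetics enter
as additive contributions to the rise and decay time constants, so the
effective transient stays a difference of exponentials with an analytic
peak time t* = (τr·τd/(τd−τr))·ln(τd/τr).
"""
from __future__ import annotations

import io
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import (
    InhalationEvents,
    InvalidSpecError,
    OdorEvent,
    StimulusProtocol,
    Trace,
)

__all__ = [
    "RespirationSpec",
    "GlomerulusSpec",
    "SensorKernel",
    "FAST_GLU",
    "SLOW_CA",
    "DatasetConfig",
    "SyntheticDataset",
    "simulate_respiration",
    "true_inhalation_events",
    "simulate_glomerulus",
    "simulate_dual_channel",
    "generate_dataset",
    "double_exp_transient",
    "transient_peak_time",
    "RESPONSE_CLASSES",
]

#: Recognized ground-truth response classes.
RESPONSE_CLASSES = (
    "sustained", "adapting", "facilitating", "suppressive", "biphasic", "tonic", "none",
)

# Fraction of the breath period occupied by the (sharper) inhalation limb.
_INHALE_FRACTION = 0.35
# Exhalation bump amplitude relative to inhalation trough depth.
_EXHALE_REL_AMP = 0.6


@dataclass
class RespirationSpec:
    """Parameters for a simulated respiration (nasal airflow) trace.

    ``artificial`` mode produces strictly periodic breaths (0.25–2 Hz typical
    of artificial inhalation); ``awake`` mode draws i.i.d. lognormal breath
    periods truncated to [150 ms, 1 s], matching the 3–6 Hz awake range with
    occasional pauses (session mean ≈ 4.4 breaths/s).
    """

    mode: str = "artificial"  # artificial | awake
    rate_hz: float = 2.0
    amplitude: float = 1.0
    noise_sd: float = 0.0
    duration_s: float = 10.0
    rate_jitter_log_sd: float = 0.2  # lognormal sigma of awake breath periods
    sample_rate_hz: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("artificial", "awake"):
            raise InvalidSpecError(f"unknown respiration mode {self.mode!r}")
        if self.rate_hz <= 0:
            raise InvalidSpecError("rate_hz must be positive")
        if self.duration_s <= 0:
            raise InvalidSpecError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise InvalidSpecError("sample_rate_hz must be positive")


def _breath_starts(spec: RespirationSpec) -> np.ndarray:
    """Breath onset times; deterministic given the spec (incl. its seed)."""
    if spec.mode == "artificial":
        period = 1.0 / spec.rate_hz
        return np.arange(0.0, spec.duration_s, period)
    rng = np.random.default_rng([spec.seed, 0xB2EA7])
    mean_period = 1.0 / spec.rate_hz
    sigma = spec.rate_jitter_log_sd
    mu = np.log(mean_period) - 0.5 * sigma**2
    starts = []
    t = 0.0
    while t < spec.duration_s:
        starts.append(t)
        period = float(np.exp(rng.normal(mu, sigma)))
        period = min(max(period, 0.150), 1.0)
        t += period
    return np.asarray(starts)


def _breath_waveform(t_rel: np.ndarray, period: float, amplitude: float) -> np.ndarray:
    """Asymmetric per-breath flow: sharp negative inhalation limb, slower
    positive exhalation bump.  ``t_rel`` is time since breath start."""
    d_in = _INHALE_FRACTION * period
    d_ex = period - d_in
    out = np.zeros_like(t_rel)
    inhale = (t_rel >= 0) & (t_rel < d_in)
    out[inhale] = -amplitude * np.sin(np.pi * t_rel[inhale] / d_in)
    exhale = (t_rel >= d_in) & (t_rel < period)
    out[exhale] = _EXHALE_REL_AMP * amplitude * np.sin(np.pi * (t_rel[exhale] - d_in) / d_ex)
    return out


def simulate_respiration(spec: RespirationSpec) -> Trace:
    """Simulate a nasal airflow trace; inhalation is the negative deflection,
    so the flow trough marks the inhalation peak.  Deterministic per seed."""
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    flow = np.zeros(n)
    starts = _breath_starts(spec)
    bounds = np.append(starts, spec.duration_s)
    for s, e in zip(bounds[:-1], bounds[1:]):
        period = e - s
        seg = (t >= s) & (t < e)
        flow[seg] = _breath_waveform(t[seg] - s, period, spec.amplitude)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 0xF10])
        flow = flow + rng.normal(0.0, spec.noise_sd, n)
    return Trace(flow, spec.sample_rate_hz, 0.0, units="flow")


def true_inhalation_events(spec: RespirationSpec) -> InhalationEvents:
    """Ground-truth inhalation events for a respiration spec.

    Onset = breath start (steepest descent of the inhalation limb);
    peak = flow trough at the middle of the inhalation limb.
    """
    starts = _breath_starts(spec)
    bounds = np.append(starts, spec.duration_s)
    periods = np.diff(bounds)
    # Drop a trailing partial breath whose trough lies outside the trace.
    troughs = starts + 0.5 * _INHALE_FRACTION * periods
    keep = troughs < spec.duration_s
    return InhalationEvents(starts[keep], troughs[keep], source="artificial")


@dataclass
class SensorKernel:
    """Kinetic signature of a fluorescent reporter.

    Rise/decay taus add to the underlying glomerular taus; ``latency_offset_s``
    shifts the whole response (the slow calcium reporter lags the fast
    glutamate reporter by ≈113 ms by default).
    """

    name: str
    rise_tau_s: float
    decay_tau_s: float
    latency_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise InvalidSpecError("kernel taus must be positive")


FAST_GLU = SensorKernel("fast_glu", rise_tau_s=0.010, decay_tau_s=0.020, latency_offset_s=0.0)
SLOW_CA = SensorKernel("slow_ca", rise_tau_s=0.020, decay_tau_s=0.200, latency_offset_s=0.113)


@dataclass
class GlomerulusSpec:
    """Ground-truth response parameters for one glomerulus-odor pair."""

    onset_latency_s: float = 0.15
    rise_tau_s: float = 0.04
    decay_tau_s: float = 0.15
    gain_seq: np.ndarray = field(default_factory=lambda: np.ones(8))
    tonic_amp: float = 0.0
    suppression_amp: float = 0.0
    coupling: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.gain_seq = np.asarray(self.gain_seq, dtype=float)
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise InvalidSpecError("taus must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise InvalidSpecError("coupling must lie in [0, 1]")
        if np.any(self.gain_seq < 0):
            raise InvalidSpecError("gain_seq entries must be non-negative")
        if self.suppression_amp > 0:
            raise InvalidSpecError("suppression_amp must be <= 0")


def transient_peak_time(rise_tau_s: float, decay_tau_s: float) -> float:
    """Analytic peak time of the difference-of-exponentials transient."""
    tr, td = rise_tau_s, decay_tau_s
    if td <= tr:
        raise InvalidSpecError("decay tau must exceed rise tau")
    return tr * td / (td - tr) * np.log(td / tr)


def double_exp_transient(t: np.ndarray, rise_tau_s: float, decay_tau_s: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials, zero for t < 0."""
    t_star = transient_peak_time(rise_tau_s, decay_tau_s)
    peak = np.exp(-t_star / decay_tau_s) - np.exp(-t_star / rise_tau_s)
    out = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / decay_tau_s)
                   - np.exp(-np.clip(t, 0, None) / rise_tau_s), 0.0)
    return out / peak


def _smoothed_boxcar(t: np.ndarray, on_s: float, off_s: float,
                     tau_s: float, rate_hz: float) -> np.ndarray:
    """Odor boxcar convolved with a unit-area exponential decay kernel."""
    box = ((t >= on_s) & (t < off_s)).astype(float)
    n_k = max(int(round(6 * tau_s * rate_hz)), 1)
    k = np.exp(-np.arange(n_k) / (tau_s * rate_hz))
    k /= k.sum()
    return np.convolve(box, k)[: t.size]


def simulate_glomerulus(
    spec: GlomerulusSpec,
    kernel: SensorKernel,
    inhalations: InhalationEvents,
    protocol: StimulusProtocol,
    seed: int = 0,
    *,
    rate_hz: float = 150.0,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Render one glomerulus-odor ΔF/F trace through a sensor kernel.

    Only inhalations whose onset falls inside an odor presentation drive
    phasic transients; gains index those inhalations in order (the last gain
    is reused if the sequence is shorter than the inhalation count).
    """
    if duration_s is None:
        last = max([ev.offset_s for ev in protocol] or [0.0])
        duration_s = last + 4.0
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = np.zeros(n)

    tau_r = spec.rise_tau_s + kernel.rise_tau_s
    tau_d = spec.decay_tau_s + kernel.decay_tau_s
    latency = spec.onset_latency_s + kernel.latency_offset_s

    for ev in protocol:
        during = inhalations.during(ev.onset_s, ev.offset_s, reference="onset")
        if len(during) == 0 and spec.coupling > 0 and spec.tonic_amp == 0:
            warnings.warn(
                f"no inhalations during odor {ev.odor!r}; returning baseline-only trace",
                stacklevel=2,
            )
        for i, t_inh in enumerate(during.onset_s):
            gain = spec.gain_seq[min(i, spec.gain_seq.size - 1)] if spec.gain_seq.size else 0.0
            if gain == 0.0 or spec.coupling == 0.0:
                continue
            x += spec.coupling * gain * double_exp_transient(t - t_inh - latency, tau_r, tau_d)
        slow = spec.tonic_amp + spec.suppression_amp
        if slow != 0.0:
            x += slow * _smoothed_boxcar(t, ev.onset_s + latency, ev.offset_s + latency,
                                         tau_d, rate_hz)

    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng([seed, 0x901])
        x = x + rng.normal(0.0, spec.noise_sd, n)
    return Trace(x, rate_hz, 0.0, units="dFF")


def simulate_dual_channel(
    spec: GlomerulusSpec,
    inhalations: InhalationEvents,
    protocol: StimulusProtocol,
    seed: int = 0,
    *,
    glu_kernel: SensorKernel = FAST_GLU,
    ca_kernel: SensorKernel = SLOW_CA,
    rate_hz: float = 150.0,
    duration_s: float | None = None,
) -> tuple[Trace, Trace]:
    """Same latent drive viewed through the fast glutamate and slow calcium
    kernels; noise is independent between channels."""
    glu = simulate_glomerulus(spec, glu_kernel, inhalations, protocol,
                              rate_hz=rate_hz, duration_s=duration_s,
                              rng=np.random.default_rng([seed, 0x61]))
    ca = simulate_glomerulus(spec, ca_kernel, inhalations, protocol,
                             rate_hz=rate_hz, duration_s=duration_s,
                             rng=np.random.default_rng([seed, 0xCA]))
    return glu, ca


# ---------------------------------------------------------------------------
# Full dataset generation
# ---------------------------------------------------------------------------

@dataclass
class DatasetConfig:
    """Study conditions for a complete synthetic dataset.

    Defaults follow the artificial-inhalation concentration-series protocol:
    2-Hz inhalation, 4-s odorant presentation, 150-Hz analysis rate.  Kinetic
    parameters are drawn per glomerulus-odor pair from the reported ranges
    (onset latency 113–253 ms).
    """

    n_glomeruli: int = 10
    odors: tuple[str, ...] = ("odorA", "odorB", "odorC", "odorD")
    class_proportions: dict = field(default_factory=lambda: {
        "sustained": 0.30, "adapting": 0.20, "facilitating": 0.10,
        "suppressive": 0.05, "biphasic": 0.05, "tonic": 0.10, "none": 0.20,
    })
    channels: tuple[str, ...] = ("glu",)
    respiration: RespirationSpec = field(default_factory=lambda: RespirationSpec(
        mode="artificial", rate_hz=2.0, duration_s=16.0))
    odor_onset_s: float = 6.0
    odor_duration_s: float = 4.0
    rate_hz: float = 150.0
    noise_sd: float = 0.02
    amp_range: tuple[float, float] = (0.3, 1.0)       # peak ΔF/F
    latency_range_s: tuple[float, float] = (0.113, 0.253)
    rise_range_s: tuple[float, float] = (0.03, 0.06)
    decay_range_s: tuple[float, float] = (0.10, 0.20)
    baseline_f: float = 100.0  # raw-F offset so traces exercise the ΔF/F step

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(f"class proportions must sum to 1, got {total}")
        for label in self.class_proportions:
            if label not in RESPONSE_CLASSES:
                raise InvalidSpecError(f"unknown response class {label!r}")


def _substream(seed: int, *parts: str) -> np.random.Generator:
    """Stable per-item RNG substream from the root seed and string parts."""
    tag = zlib.crc32("|".join(parts).encode())
    return np.random.default_rng([int(seed), int(tag)])


def _gain_sequence(label: str, n_inh: int, rng: np.random.Generator) -> np.ndarray:
    if label == "sustained":
        return np.ones(n_inh)
    if label == "adapting":
        return 0.55 ** np.arange(n_inh)
    if label == "facilitating":
        return np.linspace(0.2, 1.0, max(n_inh, 2))
    if label == "biphasic":
        return 0.55 ** np.arange(n_inh)
    return np.zeros(max(n_inh, 1))  # suppressive, tonic, none


def _spec_for(label: str, n_inh: int, cfg: DatasetConfig,
              rng: np.random.Generator) -> GlomerulusSpec:
    amp = rng.uniform(*cfg.amp_range)
    base = dict(
        onset_latency_s=rng.uniform(*cfg.latency_range_s),
        rise_tau_s=rng.uniform(*cfg.rise_range_s),
        decay_tau_s=rng.uniform(*cfg.decay_range_s),
        noise_sd=cfg.noise_sd,
    )
    gains = amp * _gain_sequence(label, n_inh, rng)
    if label == "none":
        return GlomerulusSpec(**base, gain_seq=np.zeros(1), coupling=0.0)
    if label == "tonic":
        return GlomerulusSpec(**base, gain_seq=np.zeros(1), coupling=0.0, tonic_amp=amp)
    if label == "suppressive":
        return GlomerulusSpec(**base, gain_seq=np.zeros(1), coupling=0.0,
                              suppression_amp=-0.6 * amp)
    if label == "biphasic":
        return GlomerulusSpec(**base, gain_seq=gains, coupling=1.0,
                              suppression_amp=-0.5 * amp)
    return GlomerulusSpec(**base, gain_seq=gains, coupling=1.0)


@dataclass
class SyntheticDataset:
    """Complete synthetic recording with ground truth."""

    traces: dict  # (glomerulus:int, odor:str, channel:str) -> Trace
    respiration: Trace
    inhalations: InhalationEvents
    protocol: StimulusProtocol
    truth: pd.DataFrame
    specs: dict  # (glomerulus, odor) -> GlomerulusSpec
    seed: int
    config: DatasetConfig

    def channel_frame(self, channel: str) -> pd.DataFrame:
        """Wide table: time_s plus one column per (glomerulus, odor)."""
        cols: dict[str, np.ndarray] = {}
        time = None
        for (g, o, ch), tr in sorted(self.traces.items()):
            if ch != channel:
                continue
            if time is None:
                time = tr.time_s
            cols[f"g{g:03d}__{o}"] = tr.values
        if time is None:
            raise KeyError(f"no traces for channel {channel!r}")
        return pd.DataFrame({"time_s": time, **cols})

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ch in self.config.channels:
            self.channel_frame(ch).to_csv(out / f"traces_{ch}.csv", index=False,
                                          float_format="%.8g")
        pd.DataFrame({"time_s": self.respiration.time_s,
                      "flow": self.respiration.values}).to_csv(
            out / "respiration.csv", index=False, float_format="%.8g")
        self.inhalations.to_csv(out / "inhalations.csv")
        self.protocol.to_json(out / "protocol.json")
        self.truth.to_csv(out / "truth.csv", index=False)
        meta = {"seed": self.seed, "rate_hz": self.config.rate_hz,
                "channels": list(self.config.channels), "units": "raw_F"}
        (out / "meta.json").write_text(json.dumps(meta, indent=2))

    def digest(self) -> str:
        """CRC of the serialized channel tables (for determinism checks)."""
        buf = io.StringIO()
        for ch in self.config.channels:
            self.channel_frame(ch).to_csv(buf, index=False, float_format="%.8g")
        self.truth.to_csv(buf, index=False)
        return f"{zlib.crc32(buf.getvalue().encode()):08x}"


def generate_dataset(config: DatasetConfig, seed: int = 0) -> SyntheticDataset:
    """Generate the full dataset plus truth table, deterministically per seed.

    Every trace shares the respiration trace's duration and the stimulus
    protocol; response class labels are drawn i.i.d. from the configured
    proportions per (glomerulus, odor) pair.
    """
    resp_spec = RespirationSpec(**{**config.respiration.__dict__, "seed": seed})
    respiration = simulate_respiration(resp_spec)
    inhalations = true_inhalation_events(resp_spec)
    odor_off = config.odor_onset_s + config.odor_duration_s
    protocol = StimulusProtocol([
        OdorEvent(o, config.odor_onset_s, odor_off) for o in config.odors
    ])
    n_inh = len(inhalations.during(config.odor_onset_s, odor_off))

    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[k] for k in labels])
    traces: dict = {}
    specs: dict = {}
    rows = []
    for g in range(config.n_glomeruli):
        for o in config.odors:
            prng = _substream(seed, "params", str(g), o)
            label = labels[int(prng.choice(len(labels), p=probs))]
            gspec = _spec_for(label, n_inh, config, prng)
            specs[(g, o)] = gspec
            single = StimulusProtocol([protocol.for_odor(o)])
            for ch in config.channels:
                kernel = FAST_GLU if ch == "glu" else SLOW_CA
                trng = _substream(seed, "trace", str(g), o, ch)
                dff = simulate_glomerulus(
                    gspec, kernel, inhalations, single,
                    rate_hz=config.rate_hz, duration_s=resp_spec.duration_s, rng=trng)
                raw = config.baseline_f * (1.0 + dff.values)
                traces[(g, o, ch)] = Trace(raw, config.rate_hz, 0.0, units="raw_F")
            amp = float(np.max(gspec.gain_seq)) if gspec.gain_seq.size else 0.0
            rows.append({
                "glomerulus": g, "odor": o, "label": label,
                "onset_latency_s": gspec.onset_latency_s,
                "rise_tau_s": gspec.rise_tau_s, "decay_tau_s": gspec.decay_tau_s,
                "amplitude": amp if label not in ("tonic", "suppressive")
                else abs(gspec.tonic_amp or gspec.suppression_amp),
            })
    truth = pd.DataFrame(rows)
    return SyntheticDataset(traces, respiration, inhalations, protocol, truth,
                            specs, seed, config)
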