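"""Inhalation-triggered averaging, kinetic metrics, decay fits and
median-relative latency summaries."""
import numpy as np
import pytest

from glomdyn import ita
from glomdyn.synthgen import (
    FAST_GLU,
    GlomerulusSpec,
    simulate_glomerulus,
    transient_peak_time,
)
from glomdyn.trace import OdorEvent, StimulusProtocol, as_events

from conftest import make_trace

RATE = 150.0


class TestComputeIta:
    def test_periodic_response_average_equals_single_cycle(self):
        # 17 identical 4-s cycles: the ITA must equal one cycle exactly.
        cycle = np.sin(np.linspace(0, np.pi, int(4 * RATE))) ** 2
        trace = make_trace(np.tile(cycle, 17))
        events = as_events(np.arange(17) * 4.0)
        out = ita.compute_ita(trace, events, (0.0, 4.0), "onset")
        assert np.allclose(out.values, cycle, atol=1e-12)

    def test_single_event_returns_that_segment(self):
        rng = np.random.default_rng(2)
        trace = make_trace(rng.normal(size=int(10 * RATE)))
        events = as_events([3.0])
        out = ita.compute_ita(trace, events, (0.0, 2.0), "onset")
        i0 = int(3.0 * RATE)
        assert np.array_equal(out.values, trace.values[i0:i0 + int(2 * RATE)])

    def test_noise_averages_down_as_sqrt_n(self):
        rng = np.random.default_rng(3)
        sigma, n_events = 1.0, 25
        trace = make_trace(rng.normal(0, sigma, int(30 * RATE)))
        events = as_events(np.arange(n_events) * 1.0)
        out = ita.compute_ita(trace, events, (0.0, 1.0), "onset")
        assert out.values.std() == pytest.approx(sigma / np.sqrt(n_events), rel=0.2)

    def test_linearity(self):
        rng = np.random.default_rng(4)
        x = make_trace(rng.normal(size=int(8 * RATE)))
        y = make_trace(rng.normal(size=int(8 * RATE)))
        events = as_events([1.0, 3.0, 5.0])
        combo = make_trace(2.0 * x.values + 3.0 * y.values)
        lhs = ita.compute_ita(combo, events, (0.0, 1.5)).values
        rhs = (2.0 * ita.compute_ita(x, events, (0.0, 1.5)).values
               + 3.0 * ita.compute_ita(y, events, (0.0, 1.5)).values)
        assert np.allclose(lhs, rhs)

    def test_no_valid_events_raises(self):
        trace = make_trace(np.zeros(int(2 * RATE)))
        with pytest.raises(ita.EmptyItaError):
            ita.compute_ita(trace, as_events([10.0]), (0.0, 4.0))


class TestItaMetrics:
    def test_triangular_pulse_geometry(self):
        # Triangle: support [0.1, 0.5] s, peak 1 at 0.3 s -> FWHM 0.2 s.
        t = np.arange(0, 1, 1 / RATE)
        y = np.interp(t, [0.0, 0.1, 0.3, 0.5, 1.0], [0, 0, 1, 0, 0])
        m = ita.ita_metrics(make_trace(y), baseline_sd=0.0)
        assert m.responded
        assert m.time_to_peak_s == pytest.approx(0.3, abs=1 / RATE)
        assert m.fwhm_s == pytest.approx(0.2, abs=2 / RATE)
        assert m.peak_dff == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_waveform_flags_no_response(self):
        m = ita.ita_metrics(make_trace(np.zeros(300)), baseline_sd=0.0)
        assert not m.responded
        assert np.isnan(m.onset_latency_s)

    def test_noiseless_transient_onset_within_one_sample(self, single_inhalation):
        events, protocol = single_inhalation
        for latency in (0.113, 0.150, 0.253):
            spec = GlomerulusSpec(onset_latency_s=latency, rise_tau_s=0.005,
                                  decay_tau_s=0.15, gain_seq=np.array([1.0]),
                                  noise_sd=0.0)
            trace = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=8.0)
            out = ita.compute_ita(trace, events, (0.0, 4.0))
            m = ita.ita_metrics(out, baseline_sd=0.0)
            assert abs(m.onset_latency_s - latency) <= 1 / RATE + 1e-9

    def test_negative_polarity_transient(self):
        t = np.arange(0, 2, 1 / RATE)
        y = -np.interp(t, [0.0, 0.2, 0.4, 0.6, 2.0], [0, 0, 1, 0, 0])
        m = ita.ita_metrics(make_trace(y), baseline_sd=0.01, polarity=-1)
        assert m.responded
        assert m.peak_dff == pytest.approx(-1.0, abs=1e-9)

    def test_time_to_peak_not_before_onset(self, single_inhalation):
        events, protocol = single_inhalation
        spec = GlomerulusSpec(gain_seq=np.array([1.0]), noise_sd=0.0)
        trace = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=8.0)
        m = ita.ita_metrics(ita.compute_ita(trace, events, (0.0, 4.0)), 0.0)
        assert m.time_to_peak_s >= m.onset_latency_s


class TestFitDecay:
    def test_exact_exponential_self_consistency(self):
        t = np.arange(0, 3, 1 / RATE)
        w = make_trace(np.exp(-t / 0.3))
        assert ita.fit_decay(w) == pytest.approx(0.3, abs=0.001)

    def test_noisy_exponential_within_five_percent(self):
        t = np.arange(0, 4, 1 / RATE)
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.exp(-t / 0.25) + rng.normal(0, 0.05, t.size)
            errs.append(abs(ita.fit_decay(make_trace(y)) - 0.25) / 0.25)
        assert np.median(errs) < 0.05

    def test_flat_tail_fails(self):
        w = make_trace(np.ones(300))
        with pytest.raises(ita.FitFailureError):
            ita.fit_decay(w)

    def test_too_few_samples_fails(self):
        w = make_trace(np.exp(-np.arange(4) / 3.0))
        with pytest.raises(ita.FitFailureError):
            ita.fit_decay(w)

    def test_noiseless_transient_tau_within_five_percent(self, single_inhalation):
        # Fast-rise regime: the single-exponential-from-peak fit recovers the
        # effective decay constant to within 5%.
        events, protocol = single_inhalation
        spec = GlomerulusSpec(onset_latency_s=0.15, rise_tau_s=0.005,
                              decay_tau_s=0.16, gain_seq=np.array([1.0]),
                              noise_sd=0.0)
        trace = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=8.0)
        tau_true = 0.16 + FAST_GLU.decay_tau_s
        tau_hat = ita.fit_decay(ita.compute_ita(trace, events, (0.0, 4.0)))
        assert abs(tau_hat - tau_true) / tau_true < 0.05


class TestMedianRelativeLatencies:
    def test_centering(self):
        out = ita.median_relative_latencies(np.array([0.1, 0.2, 0.3]))
        assert np.allclose(out.centered_s, [-0.1, 0.0, 0.1])

    def test_all_equal_gives_zero_spread(self):
        out = ita.median_relative_latencies(np.full(5, 0.2))
        assert np.all(out.centered_s == 0.0)
        assert out.range_10_90_s == 0.0

    def test_uniform_latencies_ten_ninety_range(self):
        # U(113, 253) ms: the centered 10th-90th percentile range is
        # 0.8 * 140 = 112 ms in expectation.
        rng = np.random.default_rng(12)
        lat = rng.uniform(0.113, 0.253, 400)
        out = ita.median_relative_latencies(lat)
        assert out.range_10_90_s * 1000 == pytest.approx(112, abs=10)


def test_latency_rank_order_preserved(single_inhalation):
    """Across glomeruli with different true latencies, ITA latency ordering
    matches ground truth exactly at zero noise."""
    from scipy import stats

    events, protocol = single_inhalation
    true_lat = np.linspace(0.113, 0.253, 8)
    measured = []
    for lat in true_lat:
        spec = GlomerulusSpec(onset_latency_s=lat, gain_seq=np.array([1.0]),
                              noise_sd=0.0)
        tr = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=8.0)
        m = ita.ita_metrics(ita.compute_ita(tr, events, (0.0, 4.0)), 0.0)
        measured.append(m.onset_latency_s)
    rho = stats.spearmanr(true_lat, measured)[0]
    assert rho == pytest.approx(1.0)
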