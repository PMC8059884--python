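"""Generator contracts: respiration statistics, forward-model identities,
dataset bookkeeping and determinism."""
import numpy as np
import pytest

from glomdyn.respiration import detect_inhalations
from glomdyn.synthgen import (
    FAST_GLU,
    SLOW_CA,
    DatasetConfig,
    GlomerulusSpec,
    RespirationSpec,
    SensorKernel,
    generate_dataset,
    simulate_dual_channel,
    simulate_glomerulus,
    simulate_respiration,
    transient_peak_time,
    true_inhalation_events,
)
from glomdyn.trace import InvalidSpecError, OdorEvent, StimulusProtocol, as_events


class TestRespiration:
    def test_artificial_periodicity(self):
        spec = RespirationSpec(mode="artificial", rate_hz=2.0, duration_s=10.0)
        truth = true_inhalation_events(spec)
        assert len(truth) == 20
        assert np.allclose(np.diff(truth.peak_s), 0.5)

    def test_requested_sample_count(self):
        spec = RespirationSpec(duration_s=7.0, sample_rate_hz=150.0)
        assert len(simulate_respiration(spec)) == 1050

    def test_awake_breath_count_near_mean_rate(self):
        # 4.4 breaths/s for 60 s: empirical count within 3 SD of 264.
        spec = RespirationSpec(mode="awake", rate_hz=4.4, duration_s=60.0, seed=7)
        n = len(true_inhalation_events(spec))
        expected = 4.4 * 60
        # breath-count SD for a renewal process ~ sqrt(n) * cv of the period
        assert abs(n - expected) < 3 * np.sqrt(expected)

    def test_awake_periods_truncated(self):
        spec = RespirationSpec(mode="awake", rate_hz=4.4, duration_s=120.0, seed=1)
        periods = np.diff(true_inhalation_events(spec).onset_s)
        assert periods.min() >= 0.150 - 1e-9
        assert periods.max() <= 1.0 + 1e-9

    def test_same_seed_identical(self):
        spec = RespirationSpec(mode="awake", rate_hz=4.4, duration_s=10.0,
                               noise_sd=0.1, seed=11)
        a, b = simulate_respiration(spec), simulate_respiration(spec)
        assert np.array_equal(a.values, b.values)

    def test_inhalation_is_negative_deflection(self):
        spec = RespirationSpec(mode="artificial", rate_hz=1.0, duration_s=5.0)
        flow = simulate_respiration(spec)
        truth = true_inhalation_events(spec)
        for tp in truth.peak_s:
            assert flow.values[flow.index_at(tp)] < 0

    def test_detected_troughs_match_ground_truth(self):
        spec = RespirationSpec(mode="artificial", rate_hz=1.0, duration_s=10.0)
        detected = detect_inhalations(simulate_respiration(spec))
        truth = true_inhalation_events(spec)
        assert len(detected) == len(truth)
        assert np.all(np.abs(detected.peak_s - truth.peak_s) <= 1.0 / 150 + 1e-9)

    @pytest.mark.parametrize("bad", [dict(rate_hz=0.0), dict(duration_s=-1.0),
                                     dict(mode="rem")])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(InvalidSpecError):
            RespirationSpec(**bad)


class TestGlomerulusForwardModel:
    def test_zero_gains_zero_tonic_gives_zero(self, single_inhalation):
        events, protocol = single_inhalation
        spec = GlomerulusSpec(gain_seq=np.zeros(1), noise_sd=0.0)
        tr = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=8.0)
        assert np.all(tr.values == 0.0)

    def test_single_inhalation_peak_at_analytic_time(self, single_inhalation):
        events, protocol = single_inhalation
        spec = GlomerulusSpec(onset_latency_s=0.15, rise_tau_s=0.04,
                              decay_tau_s=0.15, gain_seq=np.array([1.0]),
                              noise_sd=0.0)
        tr = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=8.0)
        tau_r = 0.04 + FAST_GLU.rise_tau_s
        tau_d = 0.15 + FAST_GLU.decay_tau_s
        t_star = transient_peak_time(tau_r, tau_d)
        expected = 2.0 + 0.15 + t_star
        t_peak = tr.time_s[np.argmax(tr.values)]
        assert abs(t_peak - expected) <= 0.5 / tr.rate_hz + 1e-9
        assert np.max(tr.values) == pytest.approx(1.0, abs=1e-3)

    def test_gain_sequence_sets_per_inhalation_peak_ratio(self):
        events = as_events([2.0, 6.0, 10.0, 14.0])
        protocol = StimulusProtocol([OdorEvent("x", 1.0, 17.0)])
        gains = np.array([1.0, 0.5, 0.25, 0.125])
        spec = GlomerulusSpec(gain_seq=gains, noise_sd=0.0)
        tr = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=20.0)
        peaks = [tr.slice_s(t, t + 4.0).max() for t in events.onset_s]
        assert np.allclose(np.asarray(peaks) / peaks[0], gains / gains[0], rtol=1e-3)

    def test_linearity_in_gains(self, single_inhalation):
        events, protocol = single_inhalation
        g1 = GlomerulusSpec(gain_seq=np.array([0.7]), noise_sd=0.0)
        g2 = GlomerulusSpec(gain_seq=np.array([1.4]), noise_sd=0.0)
        t1 = simulate_glomerulus(g1, FAST_GLU, events, protocol, duration_s=8.0)
        t2 = simulate_glomerulus(g2, FAST_GLU, events, protocol, duration_s=8.0)
        assert np.allclose(t2.values, 2.0 * t1.values)

    def test_no_inhalations_warns_and_returns_baseline(self):
        events = as_events([20.0])  # outside the odor window
        protocol = StimulusProtocol([OdorEvent("x", 2.0, 6.0)])
        spec = GlomerulusSpec(gain_seq=np.array([1.0]), noise_sd=0.0)
        with pytest.warns(UserWarning, match="baseline-only"):
            tr = simulate_glomerulus(spec, FAST_GLU, events, protocol, duration_s=25.0)
        assert np.all(tr.values == 0.0)


class TestDualChannel:
    def test_identical_kernels_identical_traces(self, single_inhalation):
        events, protocol = single_inhalation
        spec = GlomerulusSpec(gain_seq=np.array([1.0]), noise_sd=0.0)
        k = SensorKernel("fast_glu", 0.01, 0.02, latency_offset_s=0.0)
        glu, ca = simulate_dual_channel(spec, events, protocol, glu_kernel=k,
                                        ca_kernel=k, duration_s=8.0)
        assert np.array_equal(glu.values, ca.values)

    def test_calcium_lags_by_kernel_offset(self, single_inhalation):
        events, protocol = single_inhalation
        spec = GlomerulusSpec(gain_seq=np.array([1.0]), noise_sd=0.0)
        glu, ca = simulate_dual_channel(spec, events, protocol, duration_s=8.0)
        t_first_glu = glu.time_s[np.flatnonzero(glu.values > 1e-9)[0]]
        t_first_ca = ca.time_s[np.flatnonzero(ca.values > 1e-9)[0]]
        assert t_first_ca - t_first_glu == pytest.approx(
            SLOW_CA.latency_offset_s, abs=1.0 / glu.rate_hz)

    def test_slower_calcium_decay_broadens_fwhm(self, single_inhalation):
        events, protocol = single_inhalation
        spec = GlomerulusSpec(gain_seq=np.array([1.0]), noise_sd=0.0)
        slow = SensorKernel("slow_ca", 0.02, 5 * FAST_GLU.decay_tau_s, 0.0)
        glu, ca = simulate_dual_channel(spec, events, protocol,
                                        ca_kernel=slow, duration_s=8.0)

        def fwhm(tr):
            y = tr.values / tr.values.max()
            above = np.flatnonzero(y >= 0.5)
            return (above[-1] - above[0]) / tr.rate_hz

        assert fwhm(ca) > fwhm(glu)


class TestDataset:
    def test_bookkeeping_counts(self):
        cfg = DatasetConfig(n_glomeruli=10, odors=("a", "b", "c", "d"))
        ds = generate_dataset(cfg, seed=1)
        assert len(ds.truth) == 40
        assert sum(1 for k in ds.traces if k[2] == "glu") == 40
        assert set(ds.truth.label).issubset(set(cfg.class_proportions))

    def test_every_trace_shares_respiration_duration(self):
        ds = generate_dataset(DatasetConfig(n_glomeruli=3, odors=("a",)), seed=2)
        for tr in ds.traces.values():
            assert len(tr) == len(ds.respiration)

    def test_fixed_seed_identical_serialization(self):
        cfg = DatasetConfig(n_glomeruli=4, odors=("a", "b"))
        assert generate_dataset(cfg, seed=9).digest() == generate_dataset(cfg, seed=9).digest()

    def test_different_seed_differs(self):
        cfg = DatasetConfig(n_glomeruli=4, odors=("a", "b"))
        assert generate_dataset(cfg, seed=1).digest() != generate_dataset(cfg, seed=2).digest()

    def test_bad_proportions_rejected(self):
        with pytest.raises(InvalidSpecError):
            DatasetConfig(class_proportions={"none": 0.5})

    def test_roundtrip_serialization(self, tmp_path):
        import pandas as pd

        cfg = DatasetConfig(n_glomeruli=2, odors=("a",), channels=("glu", "ca"))
        ds = generate_dataset(cfg, seed=3)
        ds.save(tmp_path)
        wide = pd.read_csv(tmp_path / "traces_glu.csv")
        assert wide.shape[1] == 3  # time + 2 glomeruli
        truth = pd.read_csv(tmp_path / "truth.csv")
        assert len(truth) == 2
        assert (tmp_path / "protocol.json").exists()
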