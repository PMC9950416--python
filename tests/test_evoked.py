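import numpy as np
import pytest

from rungwalk import evoked
from rungwalk.synth.ecog import (EcogSimSpec, EpTemplate, StepFieldEvent,
                                 default_templates, synthesize_ecog)


def square_strobe(rate=1000.0, strobe_rate=120.0, duration=1.0):
    t = np.arange(int(duration * rate)) / rate
    phase = np.floor(t * strobe_rate * 2.0).astype(int)
    return (phase % 2 == 0).astype(float)


class TestSynchronization:
    def test_120_hz_strobe_yields_120_edges_with_8_to_9_sample_spacing(self):
        strobe = square_strobe()
        counters = np.arange(120)
        fmap = evoked.build_frame_sample_map(strobe, counters, 1000.0)
        assert len(fmap) == 120
        spacing = np.diff(fmap.samples)
        assert set(spacing.tolist()) <= {8, 9}

    def test_dropped_frame_leaves_a_hole(self):
        strobe = square_strobe(strobe_rate=100.0, duration=0.05)
        edges = evoked.detect_falling_edges(strobe)
        counters = np.array([0, 1, 3, 4, 5])[:len(edges)]
        fmap = evoked.build_frame_sample_map(strobe, counters, 1000.0)
        assert 2 not in fmap
        assert 1 in fmap and 3 in fmap

    def test_counter_wraparound_unwrapped_monotonically(self):
        strobe = square_strobe(strobe_rate=100.0, duration=0.05)
        edges = evoked.detect_falling_edges(strobe)
        counters = (np.arange(len(edges)) + 2 ** 16 - 2) % 2 ** 16
        fmap = evoked.build_frame_sample_map(strobe, counters, 1000.0)
        assert np.all(np.diff(fmap.frames) > 0)

    def test_more_counters_than_edges_errors_with_counts(self):
        strobe = square_strobe(strobe_rate=100.0, duration=0.05)
        n_edges = len(evoked.detect_falling_edges(strobe))
        with pytest.raises(ValueError, match=f"{n_edges}"):
            evoked.build_frame_sample_map(strobe,
                                          np.arange(n_edges + 3), 1000.0)

    def test_map_inverse_is_identity_on_mapped_frames(self):
        strobe = square_strobe()
        fmap = evoked.build_frame_sample_map(strobe, np.arange(120), 1000.0)
        for frame in [0, 17, 119]:
            assert fmap.frame_of(fmap[frame]) == frame

    def test_generator_event_alignment_error_at_most_one_sample(self):
        spec = EcogSimSpec(noise_white_sd=0.0)
        events = [StepFieldEvent(1.0, "contra", "unstable")]
        sim = synthesize_ecog(events, spec, seed=0, duration_s=3.0)
        fmap = evoked.build_frame_sample_map(sim.strobe, sim.frame_counters,
                                             spec.sample_rate)
        frame, _ = sim.events[0]
        mapped = fmap[frame]
        # injected template starts at the frame's falling edge
        onset = np.flatnonzero(np.abs(sim.samples[0]) > 1e-9)[0]
        assert abs(int(mapped) - int(onset)) <= 1


class TestEpochs:
    def _recording_and_map(self, spec, events, duration):
        sim = synthesize_ecog(events, spec, seed=1, duration_s=duration)
        rec = evoked.EcogRecording(sim.samples, spec.sample_rate)
        fmap = evoked.build_frame_sample_map(sim.strobe, sim.frame_counters,
                                             spec.sample_rate)
        return sim, rec, fmap

    def test_epochs_are_exactly_750_ms(self):
        spec = EcogSimSpec(noise_white_sd=0.0)
        events = [StepFieldEvent(1.0 + i, "contra", "stable")
                  for i in range(10)]
        sim, rec, fmap = self._recording_and_map(spec, events, 12.0)
        epochs = evoked.extract_epochs(rec, list(sim.events), fmap)
        assert len(epochs) == 10
        assert all(e.data.shape[1] == 750 for e in epochs)

    def test_event_at_recording_start_skipped_with_warning(self):
        spec = EcogSimSpec(noise_white_sd=0.0)
        events = [StepFieldEvent(0.05, "contra", "stable"),
                  StepFieldEvent(1.0, "contra", "stable")]
        sim, rec, fmap = self._recording_and_map(spec, events, 3.0)
        with pytest.warns(UserWarning, match="skipped 1"):
            epochs = evoked.extract_epochs(rec, list(sim.events), fmap)
        assert len(epochs) == 1

    def test_noise_free_epoch_peaks_at_template(self):
        spec = EcogSimSpec(noise_white_sd=0.0)
        events = [StepFieldEvent(1.0, "contra", "unstable")]
        sim, rec, fmap = self._recording_and_map(spec, events, 3.0)
        epochs = evoked.extract_epochs(rec, list(sim.events), fmap)
        peak = evoked.measure_peak(epochs[0].data[0], "negative",
                                   window_ms=(0, 200),
                                   sample_rate=1000.0, pre_ms=250.0)
        assert peak.amplitude_uv == pytest.approx(-300.0, abs=0.5)
        assert peak.latency_ms == pytest.approx(70.0, abs=1.0)


class TestFiltering:
    def _epoch(self, trace):
        return evoked.Epoch(np.asarray(trace)[None], 1000.0, 250.0)

    def test_dc_passes_with_unit_gain(self):
        epoch = self._epoch(np.full(750, 42.0))
        out = evoked.filter_epoch(epoch)
        assert np.allclose(out.data, 42.0, atol=1e-6)

    @pytest.mark.parametrize("freq,max_attenuation", [(10.0, 0.01)])
    def test_passband_sinusoid_attenuation_below_1_percent(
            self, freq, max_attenuation):
        t = np.arange(2000) / 1000.0
        epoch = evoked.Epoch(np.sin(2 * np.pi * freq * t)[None], 1000.0,
                             250.0)
        out = evoked.filter_epoch(epoch)
        amp = np.ptp(out.data[0, 500:1500]) / 2
        # two-pass 4th-order Butterworth: |H|^2 = 1/(1+(f/fc)^8)
        expected = 1.0 / (1.0 + (freq / 50.0) ** 8)
        assert amp == pytest.approx(expected, abs=max_attenuation)

    def test_stopband_sinusoid_attenuated_over_99_percent(self):
        t = np.arange(2000) / 1000.0
        epoch = evoked.Epoch(np.sin(2 * np.pi * 200.0 * t)[None], 1000.0,
                             250.0)
        out = evoked.filter_epoch(epoch)
        assert np.abs(out.data[0, 500:1500]).max() < 0.01

    def test_zero_phase_keeps_symmetric_pulse_latency(self):
        x = np.zeros(750)
        x[370:381] = 1.0  # symmetric pulse centered at 375
        out = evoked.filter_epoch(self._epoch(x))
        assert int(np.argmax(out.data[0])) == 375

    def test_time_reversal_commutes_with_filtering(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=750)
        fwd = evoked.filter_epoch(self._epoch(x)).data[0]
        rev = evoked.filter_epoch(self._epoch(x[::-1])).data[0]
        # exact away from the padded edges
        assert np.allclose(fwd[100:-100], rev[::-1][100:-100], atol=1e-6)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            evoked.filter_epoch(self._epoch(np.zeros(750)), cutoff_hz=600.0)


class TestBaseline:
    def test_constant_offset_removed(self):
        epoch = evoked.Epoch(np.full((3, 750), 7.0), 1000.0, 250.0)
        out = evoked.baseline_epoch(epoch)
        assert np.allclose(out.data, 0.0)

    def test_per_channel_independence(self):
        data = np.vstack([np.full(750, 5.0), np.full(750, -3.0)])
        out = evoked.baseline_epoch(evoked.Epoch(data, 1000.0, 250.0))
        assert np.allclose(out.data[:, :250], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        epoch = evoked.Epoch(rng.normal(size=(2, 750)), 1000.0, 250.0)
        once = evoked.baseline_epoch(epoch)
        twice = evoked.baseline_epoch(once)
        assert np.allclose(once.data, twice.data)

    def test_baseline_longer_than_pre_span_rejected(self):
        epoch = evoked.Epoch(np.zeros((1, 750)), 1000.0, 250.0)
        with pytest.raises(ValueError):
            evoked.baseline_epoch(epoch, baseline_ms=300.0)

    def test_pipeline_linearity(self):
        rng = np.random.default_rng(2)
        a = evoked.Epoch(rng.normal(size=(2, 750)), 1000.0, 250.0)
        b = evoked.Epoch(rng.normal(size=(2, 750)), 1000.0, 250.0)
        def process(e):
            return evoked.baseline_epoch(evoked.filter_epoch(e)).data
        combined = evoked.Epoch(a.data + b.data, 1000.0, 250.0)
        assert np.allclose(process(combined), process(a) + process(b),
                           atol=1e-8)


class TestBadChannels:
    def test_homogeneous_channels_all_kept(self, rng):
        samples = rng.normal(0, 50, (8, 2000))
        keep, _ = evoked.exclude_bad_channels(samples)
        assert keep.all()

    def test_high_variance_channel_excluded(self, rng):
        samples = rng.normal(0, 50, (8, 2000))
        samples[3] *= 100
        keep, reasons = evoked.exclude_bad_channels(samples)
        assert not keep[3] and reasons[3] == "variance"
        assert keep.sum() == 7

    def test_corrupted_fixture_channels_identified_exactly(self, rng):
        samples = rng.normal(0, 50, (12, 3000))
        bad = [1, 5, 9]
        for ch in bad:
            samples[ch] = rng.normal(0, 2000, 3000)
        keep, _ = evoked.exclude_bad_channels(samples)
        assert sorted(np.flatnonzero(~keep).tolist()) == bad

    def test_impedance_limit(self, rng):
        samples = rng.normal(0, 50, (4, 1000))
        imp = np.array([10.0, 10.0, 900.0, 10.0])
        keep, reasons = evoked.exclude_bad_channels(
            samples, impedances=imp, impedance_limit=500.0)
        assert not keep[2] and reasons[2] == "impedance"

    def test_all_excluded_raises(self, rng):
        samples = rng.normal(0, 50, (2, 100))
        with pytest.raises(ValueError):
            evoked.exclude_bad_channels(samples, variance_factor=0.0)


class TestAveragingAndPeaks:
    def test_identical_epochs_average_to_themselves(self):
        data = np.arange(750, dtype=float)[None]
        epochs = [evoked.Epoch(data, 1000.0, 250.0, {"side": "contra",
                                                     "state": "stable"})
                  for _ in range(5)]
        erps = evoked.average_evoked(epochs)
        erp = erps[("contra", "stable")]
        assert np.allclose(erp.mean, data)
        assert erp.n == 5

    def test_noise_average_shrinks_as_sqrt_n(self, rng):
        def mean_amplitude(n):
            epochs = [evoked.Epoch(rng.normal(0, 50, (1, 750)), 1000.0,
                                   250.0, {"side": "x", "state": "y"})
                      for _ in range(n)]
            erp = evoked.average_evoked(epochs)[("x", "y")]
            return np.abs(erp.mean).max()
        small, large = mean_amplitude(8), mean_amplitude(128)
        assert large < small  # 1/sqrt(n) shrinkage (factor 4 expected)

    def test_positive_polarity_on_negative_trace_flagged(self):
        trace = -np.abs(np.sin(np.linspace(0, 3, 750))) - 1.0
        peak = evoked.measure_peak(trace, "positive", window_ms=(0, 200),
                                   sample_rate=1000.0, pre_ms=250.0)
        assert not peak.polarity_matched

    def test_noise_free_condition_split_recovers_templates(self):
        spec = EcogSimSpec(noise_white_sd=0.0)
        events = []
        for i in range(4):
            events.append(StepFieldEvent(1.0 + 3 * i, "contra", "unstable"))
            events.append(StepFieldEvent(2.5 + 3 * i, "ipsi", "unstable"))
        sim = synthesize_ecog(events, spec, seed=0, duration_s=15.0)
        rec = evoked.EcogRecording(sim.samples, spec.sample_rate)
        fmap = evoked.build_frame_sample_map(sim.strobe, sim.frame_counters,
                                             spec.sample_rate)
        epochs = [evoked.baseline_epoch(e)
                  for e in evoked.extract_epochs(rec, list(sim.events), fmap)]
        erps = evoked.average_evoked(epochs)
        contra = erps[("contra", "unstable")].mean[0]
        ipsi = erps[("ipsi", "unstable")].mean[0]
        assert contra.min() == pytest.approx(-300.0, abs=1.0)
        assert np.abs(ipsi).max() < 5.0


class TestEpRecoveryMonotonicity:
    def test_recovery_error_decreases_with_trial_count(self):
        """Peak-amplitude error shrinks (within Monte-Carlo noise) as the
        number of averaged trials grows."""
        from rungwalk.pipeline import run_ep_recovery
        few = np.mean([run_ep_recovery(seed=s, n_trials=5,
                                       include_ipsi=False)
                       ["amplitude_rel_error"] for s in range(3)])
        many = np.mean([run_ep_recovery(seed=s, n_trials=60,
                                        include_ipsi=False)
                        ["amplitude_rel_error"] for s in range(3)])
        assert many <= few + 0.02
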