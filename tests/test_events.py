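"""Idealization, open-probability and action-current detection, checked
against the generators' internal ground truth."""

import numpy as np
import pytest

from kmburst.events import (
    EventTrain,
    amplitude_histogram_fit,
    detect_action_currents,
    estimate_npo,
    firing_frequency,
    idealize_trace,
)
from kmburst.synth import (
    ChannelSimSpec,
    NoiseSpec,
    Trace,
    gen_action_current_train,
    gen_single_channel_trace,
)


def _trace(spec_kw, seed=0, sd=None, dt=0.1):
    spec = ChannelSimSpec(**spec_kw)
    return gen_single_channel_trace(spec, NoiseSpec(trace_noise_sd=sd, seed=seed),
                                    sample_interval_ms=dt)


class TestAmplitudeHistogram:
    def test_two_level_telegraph_levels_recovered(self):
        tr = _trace(dict(open_probability=0.4, unitary_amplitude_pA=10.8,
                         mean_open_time_ms=5.0, duration_ms=20000.0), sd=0.5)
        lf = amplitude_histogram_fit(tr, n_levels=2)
        assert lf.converged
        assert lf.means_pA[0] == pytest.approx(0.0, abs=0.15)
        assert lf.means_pA[1] == pytest.approx(10.8, abs=0.15)
        assert lf.unitary_amplitude_pA == pytest.approx(10.8, abs=0.2)
        assert lf.weights.sum() == pytest.approx(1.0)

    def test_pure_baseline_raises_mode_flag(self):
        tr = _trace(dict(open_probability=0.0, duration_ms=5000.0), sd=0.5)
        lf = amplitude_histogram_fit(tr, n_levels=2)
        assert lf.flags  # fewer apparent modes than requested levels

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            amplitude_histogram_fit(np.zeros(500), n_levels=2)


class TestIdealization:
    def test_constant_baseline_single_closed_segment(self):
        ideal = idealize_trace(np.zeros(5000), 0.0, 10.8, sample_interval_ms=0.1)
        assert ideal.segments.shape[0] == 1
        assert ideal.segments[0, 2] == 0

    def test_noiseless_alternation_recovers_dwell_sequence_exactly(self):
        # deterministic square wave with every dwell above the dead time
        rng = np.random.default_rng(0)
        levels = []
        state = 0
        while len(levels) < 50000:
            levels.extend([state] * int(rng.integers(5, 80)))
            state = 1 - state
        truth = np.array(levels[:50000])
        ideal = idealize_trace(truth * 10.8, 0.0, 10.8, sample_interval_ms=0.1)
        np.testing.assert_array_equal(ideal.levels_per_sample(), truth)

    def test_generator_trace_recovered_up_to_dead_time(self):
        tr = _trace(dict(open_probability=0.3, unitary_amplitude_pA=10.8,
                         mean_open_time_ms=5.0, duration_ms=20000.0), sd=0.0)
        ideal = idealize_trace(tr, 0.0, 10.8)
        agree = np.mean(ideal.levels_per_sample() == tr.meta["occupancy"])
        assert agree > 0.999  # only sub-dead-time dwells may be censored

    def test_noisy_trace_recovers_sequence_nearly_everywhere(self):
        tr = _trace(dict(open_probability=0.3, unitary_amplitude_pA=10.8,
                         mean_open_time_ms=5.0, duration_ms=20000.0), seed=2)
        ideal = idealize_trace(tr, 0.0, 10.8)
        agree = np.mean(ideal.levels_per_sample() == tr.meta["occupancy"])
        assert agree > 0.99

    def test_downward_deflections_with_negative_unitary(self):
        tr = _trace(dict(open_probability=0.3, unitary_amplitude_pA=-1.8,
                         mean_open_time_ms=5.0, duration_ms=20000.0), seed=3)
        ideal = idealize_trace(tr, 0.0, -1.8)
        assert estimate_npo(ideal) == pytest.approx(tr.meta["occupancy"].mean(),
                                                    abs=0.02)

    def test_wrong_sign_unitary_rejected(self):
        tr = _trace(dict(open_probability=0.4, unitary_amplitude_pA=10.8,
                         mean_open_time_ms=5.0, duration_ms=10000.0), seed=1)
        with pytest.raises(ValueError, match="sign"):
            idealize_trace(tr, 0.0, -10.8)

    def test_offset_invariance_with_reestimated_baseline(self):
        tr = _trace(dict(open_probability=0.3, unitary_amplitude_pA=10.8,
                         mean_open_time_ms=5.0, duration_ms=20000.0), seed=4)
        a = idealize_trace(tr, 0.0, 10.8)
        shifted = Trace(tr.values_pA + 7.5, tr.sample_interval_ms, tr.meta)
        b = idealize_trace(shifted, 7.5, 10.8)
        np.testing.assert_array_equal(a.segments, b.segments)

    def test_zero_unitary_rejected(self):
        with pytest.raises(ValueError):
            idealize_trace(np.zeros(2000), 0.0, 0.0, sample_interval_ms=0.1)


class TestNPo:
    def test_always_closed_gives_zero(self):
        ideal = idealize_trace(np.zeros(5000), 0.0, 1.0, sample_interval_ms=0.1)
        assert estimate_npo(ideal) == 0.0

    def test_single_channel_po_near_generator_value(self):
        tr = _trace(dict(n_channels=1, open_probability=0.211,
                         unitary_amplitude_pA=10.8, mean_open_time_ms=2.0,
                         duration_ms=60000.0), seed=7)
        po = estimate_npo(idealize_trace(tr, 0.0, 10.8))
        assert po == pytest.approx(0.211, abs=0.03)

    def test_three_channels_npo_matches_n_times_po(self):
        tr = _trace(dict(n_channels=3, open_probability=1.45 / 3,
                         unitary_amplitude_pA=1.8, mean_open_time_ms=5.0,
                         duration_ms=60000.0), seed=11)
        npo = estimate_npo(idealize_trace(tr, 0.0, 1.8))
        assert npo == pytest.approx(1.45, rel=0.15)


class TestActionCurrentDetection:
    def test_flat_noise_yields_no_events(self):
        tr = gen_action_current_train(0.0, 20.0, noise=NoiseSpec(seed=0))
        train = detect_action_currents(tr, k_sd=6.0)
        assert train.n_events == 0

    def test_high_snr_detection_is_near_perfect(self):
        tr = gen_action_current_train(1.5, 60.0, noise=NoiseSpec(seed=6), snr=10.0)
        truth = tr.meta["event_times_s"]
        # the detector enforces a 20 ms lockout; collapse truth likewise
        kept = [truth[0]] if truth.size else []
        for t in truth[1:]:
            if t - kept[-1] >= 0.02:
                kept.append(t)
        det = detect_action_currents(tr, k_sd=6.0).event_times_s
        tp = sum(1 for t in kept if det.size and np.min(np.abs(det - t)) < 0.005)
        precision = tp / max(det.size, 1)
        recall = tp / max(len(kept), 1)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.99

    def test_recovered_frequency_near_generator_rate(self):
        tr = gen_action_current_train(1.21, 100.0, noise=NoiseSpec(seed=3))
        freq = firing_frequency(detect_action_currents(tr))
        assert abs(freq - 1.21) < 3 * np.sqrt(121) / 100.0

    def test_short_trace_rejected(self):
        tr = gen_action_current_train(1.0, 5.0, noise=NoiseSpec(seed=0))
        with pytest.raises(ValueError):
            detect_action_currents(tr)

    def test_nonpositive_threshold_rejected(self):
        tr = gen_action_current_train(1.0, 20.0, noise=NoiseSpec(seed=0))
        with pytest.raises(ValueError):
            detect_action_currents(tr, k_sd=0.0)


class TestFiringFrequency:
    @pytest.mark.parametrize("n,dur,expected", [(0, 10.0, 0.0),
                                                (121, 100.0, 1.21),
                                                (54, 100.0, 0.54)])
    def test_count_over_duration(self, n, dur, expected):
        times = np.linspace(0.5, dur - 0.5, n) if n else np.array([])
        train = EventTrain(times, dur)
        assert firing_frequency(train) == pytest.approx(expected)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            firing_frequency(EventTrain(np.array([]), 0.0))

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            EventTrain(np.array([2.0, 1.0]), 10.0)
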