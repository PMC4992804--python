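import numpy as np
import pytest

import p300bci as p
from helpers import make_session
from p300bci.errors import InvalidParameterError


class TestP300Waveform:
    def test_peak_placement_and_amplitude(self):
        w = p.p300_waveform(peak_latency=300, amplitude=1.0, duration=400)
        assert int(np.argmax(w)) == 75
        assert w.max() == pytest.approx(1.0)

    def test_edges_below_one_percent(self):
        w = p.p300_waveform(300, 2.5, 400)
        assert w[0] < 0.01 * 2.5 and w[-1] < 0.01 * 2.5

    def test_zero_amplitude_is_flat(self):
        assert not np.any(p.p300_waveform(300, 0.0, 400))

    def test_latency_shift_moves_argmax_exactly(self):
        early = p.p300_waveform(250, 1.0, 600)
        late = p.p300_waveform(350, 1.0, 600)
        # brute-force argmax of the two sampled waveforms, 100 ms = 25 samples
        assert int(np.argmax(late)) - int(np.argmax(early)) == 25

    def test_unimodal(self):
        w = p.p300_waveform(300, 1.0, 400)
        peak = int(np.argmax(w))
        assert np.all(np.diff(w[: peak + 1]) >= 0)
        assert np.all(np.diff(w[peak:]) <= 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"peak_latency": 300, "amplitude": -1.0, "duration": 400},
            {"peak_latency": 300, "amplitude": 1.0, "duration": -5},
            {"peak_latency": 500, "amplitude": 1.0, "duration": 400},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            p.p300_waveform(**kwargs)


class TestSimulateSession:
    def test_noise_free_epoch_matches_template(self):
        session = make_session(
            12, seed=5, noise_sd=0.0, latency_jitter=0.0, amplitude_variability=0.0
        )
        trials = p.session_epochs(session)
        template = p.template_from_session(session, 10, trials=trials)
        for i, trial in enumerate(trials):
            r = p.ppmcc(trial[session.truth[i]].samples, template.samples)
            assert r > 0.99

    def test_noise_free_pre_target_intervals_are_flat(self):
        # intervals before the attended one see no signal; the window of the
        # interval after it overlaps the P300 tail by paradigm construction
        cfg = p.SimulationConfig(target_sequence=(2,), noise_sd=0.0,
                                 latency_jitter=0.0, amplitude_variability=0.0)
        session = p.simulate_session(cfg)
        trial = p.session_epochs(session)[0]
        assert trial[0].context.var() == 0.0
        # the k=1 window closes 136 ms before the peak: residual < 1% amplitude
        raw_window = trial[1].context[15:85]
        assert np.abs(raw_window).max() < 0.01 * session.config.p300_amplitude

    def test_same_seed_bit_identical(self):
        a = make_session(5, seed=11)
        b = make_session(5, seed=11)
        np.testing.assert_array_equal(a.recording.data, b.recording.data)
        assert a.injected_latencies == b.injected_latencies

    def test_jitter_recorded_and_bounded(self):
        session = make_session(50, seed=7, latency_jitter=20.0)
        lat = np.asarray(session.injected_latencies)
        assert lat.shape == (50,)
        assert np.all(np.abs(lat) <= 20.0)
        assert lat.std() > 0

    def test_fatigue_shrinks_amplitude(self):
        quiet = dict(noise_sd=0.0, latency_jitter=0.0, amplitude_variability=0.0)
        fresh = p.simulate_session(
            p.SimulationConfig(target_sequence=(1,) * 20, fatigue_rate=0.0, **quiet)
        )
        tired = p.simulate_session(
            p.SimulationConfig(target_sequence=(1,) * 20, fatigue_rate=0.03, **quiet)
        )
        # the last trial's P300 is visibly smaller under fatigue
        last = slice(-300, None)
        assert tired.recording.data[last].max() < 0.6 * fresh.recording.data[last].max()

    def test_truth_validated(self):
        with pytest.raises(InvalidParameterError):
            p.SimulationConfig(target_sequence=(0, 4))

    def test_schedule_trial_duration(self):
        session = make_session(3, seed=1)
        assert session.schedule.trial_length_ms == 1050.0
        np.testing.assert_allclose(session.schedule.trial_onsets, [0.0, 1050.0, 2100.0])


class TestShiftRecovery:
    """An injected latency offset moves the feature argmax by exactly its
    sample equivalent (noise-free, single on-grid trial)."""

    @pytest.mark.parametrize("delta", [-60, -28, 0, 12, 60])
    def test_feature_argmax_tracks_injected_latency(self, delta):
        def single(latency):
            cfg = p.SimulationConfig(
                target_sequence=(1,), noise_sd=0.0, latency_jitter=0.0,
                amplitude_variability=0.0, p300_peak_latency=300.0 + latency,
            )
            return p.simulate_session(cfg)

        template = p.template_from_session(single(0), 1)
        trial = p.session_epochs(single(delta))[0]
        fv = p.timeshift_features(trial[1], template)
        assert int(np.argmax(fv.r)) - 15 == delta // 4


class TestNoiseMonotonicity:
    def test_more_noise_never_helps(self):
        """Expected single-epoch accuracy is non-increasing in the noise level."""
        accs = []
        for noise in (5.0, 10.0, 20.0):
            train_s = make_session(120, seed=900, noise_sd=noise)
            model, _ = p.train_pipeline(train_s, p.TrainingConfig(seed=901))
            test_s = make_session(100, seed=950, noise_sd=noise)
            accs.append(
                p.single_epoch_accuracy(p.session_epochs(test_s), test_s.truth, model)
            )
        assert accs[0] >= accs[1] >= accs[2]


class TestBlockedTargets:
    def test_blocks_constant_and_switching(self):
        seq = p.blocked_targets(23, block_length=5, seed=3)
        assert len(seq) == 23
        assert all(0 <= k <= 3 for k in seq)
        for start in range(0, 20, 5):
            block = seq[start : start + 5]
            assert len(set(block)) == 1
        # consecutive blocks differ
        assert seq[0] != seq[5] and seq[5] != seq[10]
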