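"""Signal conditioning chain: reference, filter, resample, epoch, reject."""

import numpy as np
import pandas as pd
import pytest

from planact import preprocess as pp
from planact.simulate import MASTOIDS, Montage, SimulationConfig, simulate_continuous


def _recording(data, rate=1000.0):
    mont = Montage()
    full = np.zeros((len(mont.channels), data.shape[-1]))
    full[: data.shape[0]] = data
    return pp.Recording(data=full, montage=mont, sampling_rate_hz=rate)


@pytest.fixture()
def sine_recording():
    t = np.arange(4000) / 1000.0
    mont = Montage()
    data = np.tile(np.sin(2 * np.pi * 10 * t), (len(mont.channels), 1))
    return pp.Recording(data=data, montage=mont, sampling_rate_hz=1000.0)


class TestRereference:
    def test_identical_mastoids_shift_every_channel(self):
        mont = Montage()
        t = np.arange(100)
        data = np.ones((len(mont.channels), 100)) * 5.0
        m = np.sin(t / 10)
        for ch in MASTOIDS:
            data[mont.channels.index(ch)] = m
        rec = pp.rereference(pp.Recording(data, mont, 1000.0))
        fz = rec.data[mont.channels.index("Fz")]
        assert np.allclose(fz, 5.0 - m)

    def test_idempotent_once_mastoids_zeroed(self, sine_recording):
        once = pp.rereference(sine_recording)
        twice = pp.rereference(once)
        assert np.allclose(once.data, twice.data)

    def test_bipolar_differences_unchanged(self, rng):
        mont = Montage()
        data = rng.standard_normal((len(mont.channels), 500))
        rec = pp.rereference(pp.Recording(data, mont, 1000.0))
        i, j = mont.index(["Fz", "Cz"])
        assert np.allclose(data[i] - data[j], rec.data[i] - rec.data[j])


class TestFilter:
    CFG = pp.PreprocessConfig()

    def test_passband_within_1db(self):
        gain = pp.bandpass_frequency_response(self.CFG, np.array([10.0]), 1000.0)[0]
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)
        t = np.arange(20000) / 1000.0
        rec = _recording(np.sin(2 * np.pi * 10 * t)[None, :])
        out = pp.bandpass_zero_phase(rec, self.CFG).data[0]
        middle = slice(5000, 15000)
        assert out[middle].std() / rec.data[0][middle].std() == pytest.approx(
            1.0, abs=0.1
        )

    def test_stopband_attenuated_40db(self):
        # designed transfer function: forward-backward squares the response
        gain = pp.bandpass_frequency_response(self.CFG, np.array([60.0]), 1000.0)[0]
        assert gain < 10 ** (-40 / 20)

    def test_dc_offset_removed(self):
        rec = _recording(np.full((1, 30000), 100.0))
        out = pp.bandpass_zero_phase(rec, self.CFG).data[0]
        assert abs(out[10000:20000].mean()) < 1.0

    def test_zero_phase_preserves_peak_latency(self):
        # long record: the 0.05 Hz high-pass has multi-second transients
        t = np.arange(60000) / 1000.0
        burst = np.exp(-((t - 30.0) ** 2) / 0.05) * np.sin(2 * np.pi * 10 * t)
        rec = _recording(burst[None, :])
        out = pp.bandpass_zero_phase(rec, self.CFG).data[0]
        assert abs(np.argmax(np.abs(out)) - np.argmax(np.abs(burst))) <= 1

    def test_lowpass_above_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 100)), rate=50.0)
        with pytest.raises(ValueError):
            pp.bandpass_zero_phase(rec, self.CFG)


class TestResample:
    def test_sample_count(self):
        rec = _recording(np.zeros((1, 2000)))
        out = pp.resample(rec, 200.0)
        assert out.data.shape[-1] == 400
        assert out.sampling_rate_hz == 200.0

    def test_constant_preserved(self):
        rec = _recording(np.full((1, 1000), 3.3))
        out = pp.resample(rec, 200.0)
        assert np.allclose(out.data[0], 3.3)

    def test_tone_rms_preserved_within_1pct(self):
        t = np.arange(10000) / 1000.0
        rec = _recording(np.sin(2 * np.pi * 10 * t)[None, :])
        out = pp.resample(rec, 200.0).data[0][100:-100]
        assert out.std() == pytest.approx(np.sqrt(0.5), rel=0.01)

    def test_upsampling_rejected(self):
        rec = _recording(np.zeros((1, 100)), rate=100.0)
        with pytest.raises(ValueError):
            pp.resample(rec, 200.0)


class TestEpoching:
    def test_window_gives_301_samples_at_200hz(self):
        rec = _recording(np.zeros((1, 2000)), rate=200.0)
        events = pd.DataFrame(
            {
                "event_sample": [500, 1000],
                "participant_id": 1,
                "condition": "self",
                "sequence_length": 2,
                "move_position": 1,
                "rt_s": 1.0,
            }
        )
        epochs, dropped = pp.extract_epochs(rec, events, (-1.0, 0.5))
        assert epochs.data.shape == (2, len(rec.montage.channels), 301)
        assert dropped == 0

    def test_edge_event_dropped_and_counted(self):
        rec = _recording(np.zeros((1, 500)), rate=200.0)
        events = pd.DataFrame(
            {
                "event_sample": [10, 300],
                "participant_id": 1,
                "condition": "stim",
                "sequence_length": 2,
                "move_position": 2,
                "rt_s": 1.0,
            }
        )
        epochs, dropped = pp.extract_epochs(rec, events, (-1.0, 0.5))
        assert dropped == 1
        assert len(epochs.trials) == 1

    def test_epoch_content_matches_continuous_slice(self, rng):
        mont = Montage()
        data = rng.standard_normal((len(mont.channels), 1000))
        rec = pp.Recording(data, mont, 200.0)
        events = pd.DataFrame(
            {
                "event_sample": [400],
                "participant_id": 1,
                "condition": "self",
                "sequence_length": 4,
                "move_position": 3,
                "rt_s": 0.9,
            }
        )
        epochs, _ = pp.extract_epochs(rec, events, (-1.0, 0.5))
        assert np.array_equal(epochs.data[0], data[:, 200:501])
        assert epochs.times_s[200] == pytest.approx(0.0)


class TestRejection:
    def _epochs(self, spike_channel=None, amp=121.0):
        rec = _recording(np.zeros((1, 2000)), rate=200.0)
        events = pd.DataFrame(
            {
                "event_sample": [500, 1000, 1500],
                "participant_id": 1,
                "condition": "self",
                "sequence_length": 2,
                "move_position": 1,
                "rt_s": 1.0,
            }
        )
        epochs, _ = pp.extract_epochs(rec, events, (-1.0, 0.5))
        if spike_channel is not None:
            idx = epochs.montage.index([spike_channel])[0]
            epochs.data[1, idx, 150] = amp
        return epochs

    def test_roi_spike_rejected(self):
        kept, mask = pp.reject_artifacts(self._epochs("Fz"))
        assert mask.tolist() == [False, True, False]
        assert len(kept.trials) == 2

    def test_non_roi_spike_retained(self):
        kept, mask = pp.reject_artifacts(self._epochs("O1"))
        assert not mask.any()

    def test_at_threshold_retained(self):
        kept, mask = pp.reject_artifacts(self._epochs("Fz", amp=120.0))
        assert not mask.any()

    def test_all_zero_epochs_retained(self):
        kept, mask = pp.reject_artifacts(self._epochs())
        assert len(kept.trials) == 3


class TestFullChain:
    def test_deterministic_and_ordered(self):
        cfg = SimulationConfig(seed=4)
        data, events, rate = simulate_continuous(
            cfg, participant_id=1, n_trials_per_cell=2, rng=1
        )
        rec = pp.Recording(data, Montage(), rate)
        out1, log1 = pp.preprocess_recording(rec, events)
        out2, log2 = pp.preprocess_recording(rec, events)
        assert np.array_equal(out1.data, out2.data)
        assert log1["stage_order"] == [
            "rereference", "bandpass", "resample", "epoch", "reject",
        ]
        assert log1["baseline"] == "none"
        assert out1.sampling_rate_hz == 200.0
        assert out1.data.shape[-1] == 301

    def test_baseline_cannot_be_enabled(self):
        with pytest.raises(ValueError):
            pp.PreprocessConfig(baseline="prestim")
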