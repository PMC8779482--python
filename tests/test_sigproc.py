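"""Preprocessing chain: filters, ICA, re-referencing, resampling, epoching."""

import numpy as np
import pytest

from tacitload import (
    Event,
    GeneratorConfig,
    InputError,
    ParameterError,
    RawRecording,
    bandpass,
    downsample,
    epoch,
    generate_recording,
    inject_artifacts,
    notch,
    preprocess,
    remove_artifacts,
    rereference_average,
)
from tacitload.sigproc import (
    PREPROCESS_ORDER,
    load_epochs,
    load_recording,
    save_epochs,
)
from tacitload.synthgen import save_recording

from conftest import central_rms, tone_recording


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = tone_recording(6.0)
        out = bandpass(rec, 1.0, 32.0)
        ratio = central_rms(out) / central_rms(rec)
        assert np.all(np.abs(ratio - 1.0) < 0.01)

    def test_drift_attenuated_20db(self):
        rec = tone_recording(0.1, duration=30.0)
        out = bandpass(rec, 1.0, 32.0)
        ratio = central_rms(out) / central_rms(rec)
        assert np.all(ratio <= 0.1)  # >= 20 dB down

    @pytest.mark.parametrize("low,high", [(32.0, 1.0), (5.0, 5.0), (1.0, 300.0), (0.0, 32.0)])
    def test_bad_edges_raise(self, low, high):
        with pytest.raises(ParameterError):
            bandpass(tone_recording(6.0), low, high)


class TestNotch:
    def test_line_frequency_suppressed(self):
        rec = tone_recording(50.0, duration=8.0)
        out = notch(rec, 50.0)
        assert np.all(central_rms(out) <= 0.1 * central_rms(rec))

    def test_neighbouring_band_untouched(self):
        for freq in (10.0, 45.0, 55.0):
            rec = tone_recording(freq, duration=8.0)
            out = notch(rec, 50.0)
            ratio = central_rms(out) / central_rms(rec)
            assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_nyquist_error(self):
        with pytest.raises(ParameterError):
            notch(tone_recording(6.0, rate=64.0), 50.0)


class TestRereference:
    def test_column_means_zero(self):
        rng = np.random.default_rng(0)
        rec = RawRecording(["a", "b", "c"], 64.0, rng.standard_normal((3, 256)))
        out = rereference_average(rec)
        assert np.allclose(out.signal.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(["a", "b"], 64.0, rng.standard_normal((2, 128)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.signal, twice.signal)

    def test_antisymmetric_pair_unchanged(self):
        x = np.sin(np.linspace(0, 10, 200))
        rec = RawRecording(["a", "b"], 64.0, np.vstack([x, -x]))
        out = rereference_average(rec)
        assert np.allclose(out.signal, rec.signal)

    def test_single_channel_error(self):
        with pytest.raises(ParameterError):
            rereference_average(RawRecording(["a"], 64.0, np.zeros((1, 64))))


class TestDownsample:
    def test_eight_to_one_decimation_count(self):
        rec = RawRecording(["a"], 512.0, np.zeros((1, 4096)))
        out = downsample(rec, 64.0)
        assert out.rate == 64.0
        assert abs(out.n_samples - 512) <= 1

    def test_low_tone_amplitude_preserved(self):
        rec = tone_recording(6.0, duration=8.0)
        out = downsample(rec, 64.0)
        ratio = central_rms(out) / central_rms(rec)
        assert np.all(np.abs(ratio - 1.0) < 0.02)

    def test_above_new_nyquist_attenuated(self):
        rec = tone_recording(40.0, duration=8.0)
        out = downsample(rec, 64.0)
        assert np.all(central_rms(out) < 0.3 * central_rms(rec))

    def test_event_onsets_rescaled(self):
        ev = Event(onset=1024, condition="rest")
        rec = RawRecording(["a"], 512.0, np.zeros((1, 4096)), [ev])
        out = downsample(rec, 64.0)
        assert out.events[0].onset == 128

    def test_target_above_rate_error(self):
        rec = tone_recording(6.0)
        with pytest.raises(ParameterError):
            downsample(rec, 1024.0)


class TestEpoch:
    def test_epoch_counts_from_default_session(self):
        cfg = GeneratorConfig(n_subjects=1, seed=0)
        rec = generate_recording(cfg, 0)
        epochs, _ = preprocess(rec, run_ica=False)
        assert epochs.data.shape == (84, 16, 64)  # 60 rest + 12 + 12 events
        counts = epochs.meta["condition"].value_counts()
        assert counts["rest"] == 60 and counts["picking"] == 12

    def test_constant_channel_zeroed_by_baseline(self):
        sig = np.vstack([np.full(128, 7.5), np.zeros(128)])
        rec = RawRecording(["a", "b"], 64.0, sig, [Event(0, "rest"), Event(64, "rest")])
        epochs = epoch(rec, 1.0)
        assert np.allclose(epochs.data, 0.0, atol=1e-12)

    def test_per_epoch_mean_is_zero(self):
        rng = np.random.default_rng(5)
        rec = RawRecording(
            ["a", "b"], 64.0, rng.standard_normal((2, 256)),
            [Event(0, "rest"), Event(64, "rest"), Event(128, "rest")],
        )
        epochs = epoch(rec, 1.0)
        assert np.allclose(epochs.data.mean(axis=2), 0.0, atol=1e-12)

    def test_truncated_window_error(self):
        # event valid for the 1-s container invariant but not a 2-s window
        rec = RawRecording(["a"], 64.0, np.zeros((1, 96)), [Event(32, "rest")])
        with pytest.raises(InputError, match="truncated"):
            epoch(rec, 2.0)

    def test_no_events_error(self):
        rec = RawRecording(["a"], 64.0, np.zeros((1, 64)))
        with pytest.raises(InputError):
            epoch(rec, 1.0)


@pytest.fixture(scope="module")
def clean_and_dirty():
    cfg = GeneratorConfig(n_subjects=1, seed=42)
    clean = generate_recording(cfg, 0)
    dirty = inject_artifacts(clean, cfg)
    return cfg, clean, dirty


class TestIca:
    def test_no_blinks_nothing_removed(self):
        cfg = GeneratorConfig(n_subjects=1, seed=3, blink_rate=0.0, line_noise_amp=0.0)
        rec = bandpass(generate_recording(cfg, 0), 1.0, 32.0)
        out, report = remove_artifacts(rec, seed=7)
        assert report.removed == []
        corr = [
            np.corrcoef(out.signal[ch], rec.signal[ch])[0, 1]
            for ch in range(rec.n_channels)
        ]
        assert min(corr) >= 0.99

    def test_blink_energy_halved_on_fp1(self, clean_and_dirty):
        cfg, clean, dirty = clean_and_dirty
        filt = bandpass(dirty, 1.0, 32.0)
        out, report = remove_artifacts(filt, seed=7)
        assert len(report.removed) >= 1

        def low_energy(x):
            p = np.abs(np.fft.rfft(x)) ** 2
            f = np.fft.rfftfreq(len(x), 1 / 512.0)
            return p[f < 4.0].sum()

        fp1 = 0  # Fp1 index in the default montage
        assert low_energy(out.signal[fp1]) <= 0.5 * low_energy(filt.signal[fp1])

    def test_component_count_contract(self, clean_and_dirty):
        _, _, dirty = clean_and_dirty
        with pytest.raises(ParameterError):
            remove_artifacts(dirty, n_components=17)

    def test_short_recording_contract(self):
        rec = RawRecording(
            [f"c{i}" for i in range(16)], 512.0, np.zeros((16, 200))
        )
        with pytest.raises(ParameterError, match="too short"):
            remove_artifacts(rec)


class TestChainProperties:
    def test_stage_order_is_fixed(self):
        assert PREPROCESS_ORDER == (
            "bandpass", "notch", "remove_artifacts", "rereference_average",
            "downsample", "epoch",
        )

    def test_linearity_of_linear_stages(self):
        """Everything except ICA flagging commutes with scalar multiplication."""
        cfg = GeneratorConfig(n_subjects=1, seed=9)
        rec = generate_recording(cfg, 0)
        scaled = rec.copy()
        scaled.signal = 3.0 * scaled.signal
        out1, _ = preprocess(rec, run_ica=False)
        out2, _ = preprocess(scaled, run_ica=False)
        assert np.allclose(out2.data, 3.0 * out1.data, atol=1e-8)

    def test_passband_energy_preserved(self):
        rec = tone_recording(10.0, duration=8.0)
        out = notch(bandpass(rec, 1.0, 32.0), 50.0)
        e_in = np.sum(central_rms(rec) ** 2)
        e_out = np.sum(central_rms(out) ** 2)
        assert abs(e_out - e_in) / e_in < 0.05


class TestIo:
    def test_recording_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=1, seed=1, rest_duration_s=1.0, n_games=2)
        rec = generate_recording(cfg, 0)
        sig_path, _ = save_recording(rec, tmp_path / "rec.csv")
        loaded = load_recording(sig_path, rate=rec.rate, subject=0)
        assert loaded.channels == rec.channels
        assert np.allclose(loaded.signal, rec.signal, atol=1e-5)
        assert [e.onset for e in loaded.events] == [e.onset for e in rec.events]
        assert loaded.events[-1].condition == "coordination"
        assert loaded.events[-1].response_time == pytest.approx(
            rec.events[-1].response_time, abs=1e-5
        )

    def test_epochs_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=1, seed=2, rest_duration_s=2.0, n_games=2)
        rec = generate_recording(cfg, 0)
        epochs, _ = preprocess(rec, run_ica=False)
        save_epochs(epochs, tmp_path / "ep")
        loaded = load_epochs(tmp_path / "ep")
        assert loaded.data.shape == epochs.data.shape
        assert np.allclose(loaded.data, epochs.data, rtol=1e-6, atol=1e-6)
        assert list(loaded.meta["condition"]) == list(epochs.meta["condition"])
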