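"""Synthetic EEG and behavioural data generator."""

import numpy as np
import pytest

from tacitload import (
    GeneratorConfig,
    ParameterError,
    generate_choices,
    generate_recording,
    inject_artifacts,
)
from tacitload.coordmetrics import ci_table
from tacitload.sigproc import downsample, epoch
from tacitload.synthgen import (
    default_salience,
    game_concentrations,
    session_duration_s,
    subject_depths,
)
from tacitload.tbr import band_power_table


def quick_band_table(cfg, subject=0):
    """Band powers from a clean recording (no filtering/ICA: the generator
    is band-limited by construction)."""
    rec = generate_recording(cfg, subject)
    epochs = epoch(downsample(rec, 64.0), 1.0)
    return band_power_table(epochs)


def quick_tbr_medians(cfg, subjects=(0,)):
    """Pooled condition-level median TBR over the given subjects."""
    import pandas as pd

    df = pd.concat([quick_band_table(cfg, s) for s in subjects], ignore_index=True)
    finite = df[np.isfinite(df["tbr"].astype(float))]
    return finite.groupby("condition")["tbr"].median()


class TestDeterminism:
    def test_recordings_bit_identical(self):
        cfg = GeneratorConfig(n_subjects=2, seed=5)
        r1 = generate_recording(cfg, 1)
        r2 = generate_recording(cfg, 1)
        assert np.array_equal(r1.signal, r2.signal)
        assert r1.events == r2.events

    def test_artifact_injection_deterministic(self):
        cfg = GeneratorConfig(n_subjects=1, seed=5)
        rec = generate_recording(cfg, 0)
        assert np.array_equal(
            inject_artifacts(rec, cfg).signal, inject_artifacts(rec, cfg).signal
        )

    def test_choices_bit_identical(self):
        cfg = GeneratorConfig(seed=11)
        t1 = generate_choices(cfg)
        t2 = generate_choices(cfg)
        assert np.array_equal(t1.choices, t2.choices)
        assert np.array_equal(t1.response_time, t2.response_time)

    def test_different_seeds_differ(self):
        t1 = generate_choices(GeneratorConfig(seed=1))
        t2 = generate_choices(GeneratorConfig(seed=2))
        assert not np.array_equal(t1.choices, t2.choices)


class TestRecordingStructure:
    def test_session_layout(self):
        cfg = GeneratorConfig(n_subjects=1, seed=0)
        rec = generate_recording(cfg, 0)
        conditions = [e.condition for e in rec.events]
        assert conditions == ["rest"] * 60 + ["picking"] * 12 + ["coordination"] * 12
        # fixed order: all rest before all picking before all coordination
        assert rec.duration == session_duration_s(cfg)
        games = sorted(e.game for e in rec.events if e.condition == "picking")
        assert games == list(range(1, 13))
        assert all(
            e.response_time is None if e.condition == "rest" else e.response_time > 0
            for e in rec.events
        )

    def test_recording_rts_match_choice_table(self):
        cfg = GeneratorConfig(n_subjects=2, seed=3)
        rec = generate_recording(cfg, 1)
        table = generate_choices(cfg, "coordination")
        for e in rec.events:
            if e.condition == "coordination":
                assert e.response_time == pytest.approx(
                    table.response_time[1, e.game - 1]
                )

    def test_absent_theta_band_gives_zero_tbr(self):
        cfg = GeneratorConfig(
            n_subjects=1, seed=4, pink_noise_scale=0.0,
            condition_theta_amp={"rest": 0.0, "picking": 0.0, "coordination": 0.0},
        )
        medians = quick_tbr_medians(cfg)
        assert (medians < 0.05).all()

    def test_config_errors(self):
        with pytest.raises(ParameterError):
            generate_recording(GeneratorConfig(sample_rate=-1.0), 0)
        with pytest.raises(ParameterError):
            generate_recording(
                GeneratorConfig(condition_theta_amp={"rest": -1.0, "picking": 1, "coordination": 1}), 0
            )
        with pytest.raises(ParameterError):
            generate_recording(GeneratorConfig(n_subjects=2), 5)
        with pytest.raises(ParameterError):
            bad = GeneratorConfig()
            bad.salience_weights = np.full((12, 4), np.nan)
            generate_choices(bad)


class TestPlantedTbrStructure:
    def test_theta_amplitude_monotonicity_noise_free(self):
        """More theta amplitude in a condition => higher TBR there (no noise)."""
        base = dict(n_subjects=1, seed=6, pink_noise_scale=0.0, amp_jitter_sd=0.0,
                    subject_tbr_sd=0.0)
        lo = GeneratorConfig(
            condition_theta_amp={"rest": 10.0, "picking": 10.0, "coordination": 10.0}, **base
        )
        hi = GeneratorConfig(
            condition_theta_amp={"rest": 20.0, "picking": 10.0, "coordination": 10.0}, **base
        )
        m_lo, m_hi = quick_tbr_medians(lo), quick_tbr_medians(hi)
        assert m_hi["rest"] > m_lo["rest"]
        assert m_hi["picking"] == pytest.approx(m_lo["picking"], rel=1e-9)

    def test_median_ordering_across_replicates(self):
        """Pooled default-session epochs show rest > picking > coordination."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = GeneratorConfig(n_subjects=3, seed=1000 + seed)
            med = quick_tbr_medians(cfg, subjects=range(3))
            hits += bool(med["rest"] > med["picking"] > med["coordination"])
        assert hits >= int(0.9 * n_rep)


class TestChoices:
    def test_one_hot_salience_forces_unanimity(self):
        w = np.zeros((12, 4))
        w[:, 2] = 5.0
        cfg = GeneratorConfig(seed=8, salience_weights=w, choice_sharpness=50.0)
        table = generate_choices(cfg)
        assert (table.choices == 2).all()
        assert np.allclose(ci_table(table).ci, 1.0)

    def test_uniform_salience_zero_depth_expected_ci(self):
        """E[CI] = 1/L for uniform choices; checked against a multinomial
        simulation and against generated tables."""
        # closed form vs direct multinomial simulation (10^4 replicates)
        rng = np.random.default_rng(0)
        counts = rng.multinomial(10, [0.25] * 4, size=10_000)
        sim_ci = (counts * (counts - 1)).sum(axis=1) / 90.0
        assert sim_ci.mean() == pytest.approx(0.25, abs=0.01)

        # generator path: zero sharpening → uniform choices
        cfg_ci = []
        for seed in range(150):
            cfg = GeneratorConfig(seed=seed, choice_sharpness=0.0)
            cfg_ci.append(ci_table(generate_choices(cfg)).ci.mean())
        assert np.mean(cfg_ci) == pytest.approx(0.25, abs=0.02)

    def test_depth_sharpens_choices(self):
        """Deeper subjects coordinate better: iCA increases with depth."""
        cfg = GeneratorConfig(seed=13)
        ica = ci_table(generate_choices(cfg)).ica
        depths = subject_depths(cfg)
        assert np.corrcoef(depths, ica)[0, 1] > 0.5

    def test_rt_positive(self):
        table = generate_choices(GeneratorConfig(seed=2), "picking")
        assert (table.response_time > 0).all()


class TestArtifacts:
    def test_noop_when_disabled(self):
        cfg = GeneratorConfig(n_subjects=1, seed=1, blink_rate=0.0, line_noise_amp=0.0)
        rec = generate_recording(cfg, 0)
        out = inject_artifacts(rec, cfg)
        assert out is not rec
        assert np.array_equal(out.signal, rec.signal)

    def test_input_unmodified(self):
        cfg = GeneratorConfig(n_subjects=1, seed=1)
        rec = generate_recording(cfg, 0)
        before = rec.signal.copy()
        inject_artifacts(rec, cfg)
        assert np.array_equal(rec.signal, before)

    def test_line_noise_peak_on_every_channel(self):
        cfg = GeneratorConfig(n_subjects=1, seed=2, blink_rate=0.0, line_noise_amp=3.0)
        rec = generate_recording(cfg, 0)
        out = inject_artifacts(rec, cfg)
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.rate)
        spec_out = np.abs(np.fft.rfft(out.signal, axis=1))
        spec_in = np.abs(np.fft.rfft(rec.signal, axis=1))
        at_50 = np.argmin(np.abs(freqs - 50.0))
        assert np.all(spec_out[:, at_50] > 10 * spec_in[:, at_50] + 1e-9)

    def test_blink_excursions_exceed_background(self):
        cfg = GeneratorConfig(n_subjects=1, seed=3, line_noise_amp=0.0)
        rec = generate_recording(cfg, 0)
        out = inject_artifacts(rec, cfg)
        diff = out.signal - rec.signal  # pure injected blink train
        fp1 = rec.channels.index("Fp1")
        background_rms = np.sqrt(np.mean(rec.signal[fp1] ** 2))
        blink_samples = np.abs(diff[fp1]) > 1e-9
        assert blink_samples.any()
        assert np.max(np.abs(diff[fp1])) > 5 * background_rms


def test_default_salience_spans_difficulty():
    w = default_salience()
    conc = game_concentrations(GeneratorConfig())
    assert w.shape == (12, 4)
    assert conc.min() < 0.35 and conc.max() > 0.6  # hard and easy games exist
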