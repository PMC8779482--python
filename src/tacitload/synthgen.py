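"""Synthetic EEG and tacit-coordination behavioural data.

The generator emulates a three-condition session (resting state, then 12
"picking" games, then 12 "coordination" games) recorded from a 16-channel
10–20 montage at 512 Hz.  Signals are amplitude-modulated narrow-band
sinusoids (theta 4–8 Hz, beta 16–32 Hz carriers with random phase and
frequency jitter) on top of 1/f pink noise; blinks and 50 Hz line noise are
injected separately so the artifact-removal stage has something to remove.

A single latent "depth of reasoning" scalar per subject drives both choice
sharpening (better coordinators concentrate on the salient label) and
elevated cognitive load — hence lower theta/beta ratio — during
coordination.  Game difficulty (diffuse salience) raises load the same way.
Response times increase with planted per-trial load.  All randomness flows
from one seed through named substreams, so any stage can be regenerated in
isolation and identical ``(config, seed)`` gives bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import windows

from .containers import (
    CHANNELS_1020_16,
    CONDITIONS,
    COORDINATION,
    FRONTAL_CHANNELS,
    ChoiceTable,
    Event,
    InputError,
    ParameterError,
    PICKING,
    RawRecording,
    REST,
)

# Session timeline (seconds).  The rest block is cut into 1-s sub-epochs.
LEAD_S = 2.0
BREAK_S = 4.0
TRIAL_SPACING_S = 2.5
TAIL_S = 2.0

# Carrier ranges (Hz) for the two bands of interest.
THETA_RANGE = (4.5, 7.5)
BETA_RANGE = (17.0, 30.0)

# Oscillation gain topography: workload oscillations are frontal-weighted.
_OSC_FRONTAL_GAIN = 1.0
_OSC_OTHER_GAIN = 0.45

# Blink topography by channel name (anything unnamed gets the floor value).
_BLINK_TOPOGRAPHY = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.35, "F8": 0.35, "F3": 0.30, "F4": 0.30,
}
_BLINK_FLOOR = 0.08
_BLINK_DURATION_S = 0.4


def _stream(seed: int, *tokens) -> np.random.Generator:
    """Named RNG substream: stable across runs and platforms."""
    keys = [
        int.from_bytes(
            hashlib.blake2s(repr(t).encode(), digest_size=4).digest(), "big"
        )
        for t in tokens
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + keys))


def default_salience(n_games: int = 12, n_labels: int = 4) -> np.ndarray:
    """Per-game label salience (focal-point strength), shape (games, labels).

    Peak strengths span near-uniform games (no prominent focal point, hard to
    coordinate) to strongly focal ones; the peak label rotates across games so
    no label is globally privileged.
    """
    peaks = np.array([1.6, 0.7, 0.7, 0.5, 2.3, 1.0, 2.6, 1.6, 0.15, 1.0, 0.7, 2.3])
    w = np.zeros((n_games, n_labels))
    for g in range(n_games):
        p = peaks[g % len(peaks)]
        w[g, g % n_labels] = p
        w[g, (g + 1) % n_labels] = 0.3 * p
    return w


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session.

    Amplitudes are µV; ``load_coupling`` and ``difficulty_coupling`` scale a
    dimensionless load term that multiplies theta by ``exp(-load)`` and beta
    by ``exp(+load)`` (so planted log-TBR shifts by ``-4 * load``);
    ``rt_coupling`` is seconds of response time per unit load.
    """

    n_subjects: int = 10
    n_games: int = 12
    n_labels: int = 4
    sample_rate: float = 512.0
    n_channels: int = 16
    channels: tuple[str, ...] = CHANNELS_1020_16
    condition_theta_amp: dict = field(
        default_factory=lambda: {REST: 22.0, PICKING: 20.0, COORDINATION: 17.0}
    )
    condition_beta_amp: dict = field(
        default_factory=lambda: {REST: 9.6, PICKING: 10.0, COORDINATION: 10.3}
    )
    pink_noise_scale: float = 4.0
    line_noise_amp: float = 2.0
    blink_rate: float = 12.0  # events/min, frontal-weighted
    blink_amp: float = 200.0
    salience_weights: np.ndarray | None = None
    load_coupling: float = 0.4
    difficulty_coupling: float = 0.5
    rt_coupling: float = 0.8
    choice_sharpness: float = 5.0
    picking_sharpness: float = 0.3  # fraction of sharpness retained when picking
    amp_jitter_sd: float = 0.2  # per-band log-amplitude jitter per trial
    subject_tbr_sd: float = 0.15  # subject-level log-TBR offset (not load-linked)
    rest_duration_s: float = 60.0
    rt_base: dict = field(default_factory=lambda: {PICKING: 1.2, COORDINATION: 2.2})
    rt_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.salience_weights is None:
            self.salience_weights = default_salience(self.n_games, self.n_labels)
        self.salience_weights = np.asarray(self.salience_weights, dtype=float)

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if self.sample_rate <= 2 * BETA_RANGE[1]:
            raise ParameterError(
                "sample_rate must exceed twice the highest oscillation frequency"
            )
        if self.n_subjects < 1 or self.n_games < 1 or self.n_labels < 2:
            raise ParameterError("need >=1 subject, >=1 game, >=2 labels")
        if self.n_channels != len(self.channels):
            raise ParameterError("n_channels does not match channel name list")
        for name, amps in (
            ("condition_theta_amp", self.condition_theta_amp),
            ("condition_beta_amp", self.condition_beta_amp),
        ):
            for cond in CONDITIONS:
                if cond not in amps:
                    raise ParameterError(f"{name} missing condition {cond!r}")
                if amps[cond] < 0:
                    raise ParameterError(f"{name}[{cond!r}] must be >= 0")
        for val, name in (
            (self.pink_noise_scale, "pink_noise_scale"),
            (self.line_noise_amp, "line_noise_amp"),
            (self.blink_rate, "blink_rate"),
            (self.blink_amp, "blink_amp"),
        ):
            if val < 0:
                raise ParameterError(f"{name} must be >= 0")
        w = self.salience_weights
        if w.shape != (self.n_games, self.n_labels):
            raise ParameterError(
                f"salience_weights shape {w.shape} != (n_games, n_labels)"
            )
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ParameterError("salience_weights must be finite and non-negative")
        if self.rest_duration_s < 1.0:
            raise ParameterError("rest block must cover at least one 1-s epoch")


# ---------------------------------------------------------------------------
# Latent structure
# ---------------------------------------------------------------------------

def subject_depths(config: GeneratorConfig) -> np.ndarray:
    """Latent depth-of-reasoning levels, evenly spaced over [0, 1].

    Fixed spacing (rather than random draws) guarantees the population spans
    the full ability range in every run, which is what the planted-effect
    recovery analyses rely on.
    """
    n = config.n_subjects
    if n == 1:
        return np.array([0.5])
    return np.arange(n) / (n - 1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _sharpness(config: GeneratorConfig, depth: float) -> float:
    """Softmax sharpening for a subject of the given latent depth.

    A baseline floor keeps even the shallowest reasoner weakly responsive to
    salience (a player who perceives no salience at all would pick uniformly,
    which would break unanimity even in games with a single overwhelming
    focal point); depth scales the remainder.
    """
    return config.choice_sharpness * (0.15 + 0.85 * depth)


def game_concentrations(config: GeneratorConfig) -> np.ndarray:
    """Choice-probability concentration per game (higher = easier game).

    Computed as the collision probability of the softmax choice distribution
    at the population-average sharpening; used as the game-difficulty input to
    the load model.
    """
    beta_bar = _sharpness(config, 0.5)
    return np.array(
        [
            np.sum(_softmax(beta_bar * w) ** 2)
            for w in config.salience_weights
        ]
    )


def _subject_band_offsets(config: GeneratorConfig, subject: int) -> tuple[float, float]:
    """Subject-level band multipliers giving a log-TBR offset ~N(0, subject_tbr_sd)."""
    rng = _stream(config.seed, "subject", subject)
    o = rng.normal(0.0, config.subject_tbr_sd)
    return float(np.exp(o / 4.0)), float(np.exp(-o / 4.0))


def _trial_load(config: GeneratorConfig, subject: int, condition: str, game: int) -> float:
    """Planted dimensionless load for one game trial (0 for rest/picking)."""
    if condition != COORDINATION:
        return 0.0
    d = subject_depths(config)[subject]
    c = game_concentrations(config)
    return float(
        config.load_coupling * (d - 0.5)
        + config.difficulty_coupling * (c.mean() - c[game - 1])
    )


@dataclass(frozen=True)
class _TrialParams:
    amp_theta: float
    amp_beta: float
    f_theta: float
    f_beta: float
    phase_theta: float
    phase_beta: float
    load: float
    response_time: float | None


def _trial_params(
    config: GeneratorConfig, subject: int, condition: str, game: int
) -> _TrialParams:
    """Everything stochastic about one 1-s trial/rest window.

    The same named stream is used by both :func:`generate_recording` and
    :func:`generate_choices`, so event response times in the EEG match the
    behavioural table exactly.
    """
    rng = _stream(config.seed, "trial", subject, condition, game)
    jit_t, jit_b = np.exp(config.amp_jitter_sd * rng.standard_normal(2))
    f_t = rng.uniform(*THETA_RANGE)
    f_b = rng.uniform(*BETA_RANGE)
    ph_t, ph_b = rng.uniform(0.0, 2 * np.pi, 2)
    load = _trial_load(config, subject, condition, game)
    off_t, off_b = _subject_band_offsets(config, subject)
    amp_t = config.condition_theta_amp[condition] * np.exp(-load) * jit_t * off_t
    amp_b = config.condition_beta_amp[condition] * np.exp(+load) * jit_b * off_b
    if condition == REST:
        rt = None
    else:
        rt = config.rt_base[condition] + config.rt_coupling * load
        rt += rng.normal(0.0, config.rt_noise_sd)
        rt = max(0.3, float(rt))
    return _TrialParams(amp_t, amp_b, f_t, f_b, ph_t, ph_b, load, rt)


# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, rate: float, rms: float) -> np.ndarray:
    """Gaussian 1/f noise normalised to the requested RMS."""
    if rms == 0.0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec * shape, n)
    return x * (rms / x.std())


def _oscillation_gains(config: GeneratorConfig, subject: int) -> np.ndarray:
    """Per-channel gain of the shared workload oscillation source."""
    gains = np.full(config.n_channels, _OSC_OTHER_GAIN)
    for i, name in enumerate(config.channels):
        if name in FRONTAL_CHANNELS:
            gains[i] = _OSC_FRONTAL_GAIN
    rng = _stream(config.seed, "gains", subject)
    return gains * rng.uniform(0.9, 1.1, config.n_channels)


def _session_events(config: GeneratorConfig, subject: int) -> list[tuple[int, str, int]]:
    """(onset, condition, game-or-rest-index) schedule in presentation order.

    Game order is randomised per subject within each condition; the fixed
    condition order is rest → picking → coordination.
    """
    rate = config.sample_rate
    win = int(round(rate))
    schedule: list[tuple[int, str, int]] = []
    t = LEAD_S
    n_rest = int(config.rest_duration_s)
    for k in range(n_rest):
        schedule.append((int(round(t * rate)), REST, k))
        t += 1.0
    for condition in (PICKING, COORDINATION):
        t += BREAK_S
        order = _stream(config.seed, "order", subject, condition).permutation(config.n_games) + 1
        for game in order:
            schedule.append((int(round(t * rate)), condition, int(game)))
            t += TRIAL_SPACING_S
    # sanity: windows must not overlap the schedule end
    assert all(schedule[i][0] + win <= schedule[i + 1][0] for i in range(len(schedule) - 1))
    return schedule


def session_duration_s(config: GeneratorConfig) -> float:
    n_rest = int(config.rest_duration_s)
    return (
        LEAD_S + n_rest + 2 * (BREAK_S + config.n_games * TRIAL_SPACING_S) + TAIL_S
    )


def generate_recording(config: GeneratorConfig, subject_id: int) -> RawRecording:
    """One continuous artifact-free recording for a single subject.

    Contains a ≥60 s resting block segmented into 1-s rest events, then the
    picking and coordination trials, one event each.  Theta/beta oscillations
    are injected per event window with condition-, subject- and
    game-dependent amplitudes; blinks and line noise are added separately by
    :func:`inject_artifacts`.
    """
    config.validate()
    if not 0 <= subject_id < config.n_subjects:
        raise ParameterError(f"subject_id {subject_id} outside [0, {config.n_subjects})")
    rate = config.sample_rate
    win = int(round(rate))
    n_samples = int(round(session_duration_s(config) * rate))
    signal = np.empty((config.n_channels, n_samples))
    for ch in range(config.n_channels):
        rng = _stream(config.seed, "pink", subject_id, ch)
        signal[ch] = _pink_noise(rng, n_samples, rate, config.pink_noise_scale)

    gains = _oscillation_gains(config, subject_id)
    taper = windows.tukey(win, 0.2)
    t = np.arange(win) / rate
    events: list[Event] = []
    for onset, condition, game in _session_events(config, subject_id):
        p = _trial_params(config, subject_id, condition, game)
        source = (
            p.amp_theta * np.sin(2 * np.pi * p.f_theta * t + p.phase_theta)
            + p.amp_beta * np.sin(2 * np.pi * p.f_beta * t + p.phase_beta)
        ) * taper
        signal[:, onset:onset + win] += gains[:, None] * source[None, :]
        events.append(
            Event(
                onset=onset,
                condition=condition,
                game=None if condition == REST else game,
                response_time=p.response_time,
            )
        )
    return RawRecording(
        channels=config.channels, rate=rate, signal=signal, events=events,
        subject=subject_id,
    )


def inject_artifacts(rec: RawRecording, config: GeneratorConfig) -> RawRecording:
    """Add blinks (frontal, < 4 Hz, high amplitude) and 50 Hz line noise.

    Returns a new recording; the input is left unmodified.  With
    ``blink_rate == 0`` and ``line_noise_amp == 0`` the output equals the
    input.
    """
    if config.blink_rate < 0:
        raise ParameterError("blink_rate must be >= 0")
    out = rec.copy()
    subject = rec.subject if rec.subject is not None else 0
    n = rec.n_samples

    if config.line_noise_amp > 0:
        if rec.rate <= 100.0:
            raise ParameterError("sampling rate too low to carry 50 Hz line noise")
        rng = _stream(config.seed, "line", subject)
        phase = rng.uniform(0, 2 * np.pi)
        ch_amp = config.line_noise_amp * rng.uniform(0.9, 1.1, rec.n_channels)
        tt = np.arange(n) / rec.rate
        out.signal += ch_amp[:, None] * np.sin(2 * np.pi * 50.0 * tt + phase)[None, :]

    if config.blink_rate > 0 and config.blink_amp > 0:
        rng = _stream(config.seed, "blink", subject)
        n_blinks = rng.poisson(config.blink_rate * rec.duration / 60.0)
        length = int(round(_BLINK_DURATION_S * rec.rate))
        topo = np.array(
            [_BLINK_TOPOGRAPHY.get(name, _BLINK_FLOOR) for name in rec.channels]
        )
        bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(length) / length))
        for _ in range(n_blinks):
            start = int(rng.integers(int(rec.rate), n - length - int(rec.rate)))
            amp = config.blink_amp * np.exp(0.2 * rng.standard_normal())
            out.signal[:, start:start + length] += amp * topo[:, None] * bump[None, :]
    return out


# ---------------------------------------------------------------------------
# Behavioural data
# ---------------------------------------------------------------------------

def generate_choices(config: GeneratorConfig, condition: str = COORDINATION) -> ChoiceTable:
    """Choices and response times for all subjects in one game condition.

    Each subject's choice in game ``g`` is a draw from
    ``softmax(sharpness_i * salience_weights[g])`` where ``sharpness_i``
    grows with the subject's latent depth — deeper reasoners concentrate on
    the focal label, spreading individual coordination ability across the
    population.  In the picking condition the sharpening is attenuated.
    """
    config.validate()
    if condition not in (PICKING, COORDINATION):
        raise ParameterError(f"condition must be picking/coordination, got {condition!r}")
    depths = subject_depths(config)
    factor = 1.0 if condition == COORDINATION else config.picking_sharpness
    choices = np.empty((config.n_subjects, config.n_games), dtype=int)
    rts = np.empty((config.n_subjects, config.n_games))
    for s in range(config.n_subjects):
        beta = _sharpness(config, depths[s]) * factor
        for g in range(config.n_games):
            rng = _stream(config.seed, "choice", s, condition, g + 1)
            p = _softmax(beta * config.salience_weights[g])
            choices[s, g] = rng.choice(config.n_labels, p=p)
            rts[s, g] = _trial_params(config, s, condition, g + 1).response_time
    return ChoiceTable(
        choices=choices, response_time=rts, condition=condition,
        n_labels=config.n_labels,
    )


# ---------------------------------------------------------------------------
# Text serialisation
# ---------------------------------------------------------------------------

def save_recording(rec: RawRecording, path: str | Path) -> tuple[Path, Path]:
    """Write signal (one column per channel, header row of names) + event sidecar.

    Returns ``(signal_path, events_path)``.
    """
    path = Path(path)
    frame = pd.DataFrame(rec.signal.T, columns=list(rec.channels))
    frame.to_csv(path, index=False, float_format="%.6f")
    events_path = path.with_name(path.stem + "_events.csv")
    pd.DataFrame(
        {
            "onset_sample": [e.onset for e in rec.events],
            "condition": [e.condition for e in rec.events],
            "game": [e.game if e.game is not None else "" for e in rec.events],
            "rt": [e.response_time if e.response_time is not None else "" for e in rec.events],
        }
    ).to_csv(events_path, index=False)
    return path, events_path


def save_choices(table: ChoiceTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path
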