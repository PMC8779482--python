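"""EEG preprocessing: filtering, artifact removal, re-referencing, epoching.

The chain order is fixed (see :data:`PREPROCESS_ORDER`): zero-phase
band-pass, 50 Hz notch, ICA-based blink removal, average re-reference,
polyphase downsampling to 64 Hz, then baseline-corrected 1-s epochs relative
to each event onset.  All filters are applied forward-backward so epoch
timing is not phase-shifted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (
    Event,
    EpochSet,
    InputError,
    ParameterError,
    RawRecording,
    TacitloadError,
)

log = logging.getLogger(__name__)

#: The preprocessing stages in their mandatory order.
PREPROCESS_ORDER = (
    "bandpass", "notch", "remove_artifacts", "rereference_average",
    "downsample", "epoch",
)

DEFAULT_BANDPASS = (1.0, 32.0)
DEFAULT_NOTCH_HZ = 50.0
DEFAULT_TARGET_RATE = 64.0

# Blink-component flagging rule: a component is removed when its loading is
# concentrated on the prefrontal pair AND its energy is mostly below 4 Hz.
FRONTAL_LOADING_THRESHOLD = 0.4
LOWFREQ_ENERGY_THRESHOLD = 0.6
_BLINK_CHANNELS = ("Fp1", "Fp2")

# ICA is estimated on a decimated copy of the data (the unmixing matrix is
# then applied to the full-rate signal); 6x decimation of a >100 s recording (alias-free: the signal is already
# band-limited to 32 Hz)
# leaves far more samples than the n_channels**2 identifiability heuristic.
_ICA_DECIM = 6
_ICA_MAX_ITER = 100
_ICA_TOL = 1e-3


class IcaError(TacitloadError):
    """ICA decomposition failure; carries the iteration count reached."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


@dataclass
class IcaReport:
    """Which components were removed and why."""

    removed: list[int]
    frontal_fraction: np.ndarray
    lowfreq_fraction: np.ndarray
    n_iter: int
    converged: bool


def bandpass(rec: RawRecording, low: float, high: float) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass, per channel."""
    nyq = rec.rate / 2.0
    if not (0 < low < high < nyq):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got ({low}, {high})"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    out = rec.copy()
    out.signal = sps.sosfiltfilt(sos, out.signal, axis=1)
    return out


def notch(rec: RawRecording, freq: float = DEFAULT_NOTCH_HZ, quality: float = 30.0) -> RawRecording:
    """Zero-phase second-order IIR notch (quality factor 30 by default)."""
    nyq = rec.rate / 2.0
    if not (0 < freq < nyq):
        raise ParameterError(f"notch frequency must lie in (0, {nyq}); got {freq}")
    b, a = sps.iirnotch(freq, quality, fs=rec.rate)
    out = rec.copy()
    out.signal = sps.filtfilt(b, a, out.signal, axis=1)
    return out


def _lowfreq_fraction(sources: np.ndarray, rate: float, edge_hz: float = 4.0) -> np.ndarray:
    """Fraction of spectral power below ``edge_hz`` for each column of ``sources``."""
    power = np.abs(np.fft.rfft(sources, axis=0)) ** 2
    freqs = np.fft.rfftfreq(sources.shape[0], d=1.0 / rate)
    total = power.sum(axis=0)
    total[total == 0] = 1.0
    return power[freqs < edge_hz].sum(axis=0) / total


def remove_artifacts(
    rec: RawRecording,
    n_components: int | None = None,
    *,
    frontal_threshold: float = FRONTAL_LOADING_THRESHOLD,
    lowfreq_threshold: float = LOWFREQ_ENERGY_THRESHOLD,
    seed: int = 0,
) -> tuple[RawRecording, IcaReport]:
    """Remove blink-like independent components from a recording.

    Fixed-point negentropy-maximising ICA (FastICA, deflation) decomposes the
    channels; components whose absolute loading on Fp1+Fp2 exceeds
    ``frontal_threshold`` of the total loading AND whose sub-4 Hz energy
    fraction exceeds ``lowfreq_threshold`` are dropped before reconstruction.

    Returns the cleaned recording and an :class:`IcaReport`.  A decomposition
    yielding non-finite mixing coefficients raises :class:`IcaError` with the
    iteration count.
    """
    from sklearn.decomposition import FastICA  # deferred: heavy import

    if n_components is None:
        n_components = rec.n_channels
    if n_components > rec.n_channels:
        raise ParameterError(
            f"n_components ({n_components}) cannot exceed channels ({rec.n_channels})"
        )
    if rec.n_samples <= rec.n_channels**2:
        raise ParameterError(
            "recording too short for a stable decomposition "
            f"(need > n_channels**2 = {rec.n_channels ** 2} samples)"
        )
    X = rec.signal.T  # samples x channels
    ica = FastICA(
        n_components=n_components,
        algorithm="deflation",
        fun="logcosh",
        max_iter=_ICA_MAX_ITER,
        tol=_ICA_TOL,
        whiten="unit-variance",
        random_state=seed & 0x7FFFFFFF,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ica.fit(X[::_ICA_DECIM])
    if any("did not converge" in str(w.message) for w in caught):
        converged = False
    n_iter = int(np.max(ica.n_iter_)) if np.ndim(ica.n_iter_) else int(ica.n_iter_)
    mixing = ica.mixing_  # channels x components
    if not np.all(np.isfinite(mixing)):
        raise IcaError("ICA produced non-finite mixing coefficients", n_iter)

    sources = (X - ica.mean_) @ ica.components_.T  # samples x components
    abs_load = np.abs(mixing)
    front_idx = [rec.channels.index(c) for c in _BLINK_CHANNELS if c in rec.channels]
    frontal_fraction = abs_load[front_idx].sum(axis=0) / abs_load.sum(axis=0)
    lowfreq_fraction = _lowfreq_fraction(sources, rec.rate)
    removed = [
        int(k)
        for k in range(mixing.shape[1])
        if frontal_fraction[k] > frontal_threshold
        and lowfreq_fraction[k] > lowfreq_threshold
    ]
    out = rec.copy()
    if removed:
        keep = np.ones(mixing.shape[1], dtype=bool)
        keep[removed] = False
        out.signal = (sources[:, keep] @ mixing[:, keep].T + ica.mean_).T
        log.info("ICA removed %d blink-like component(s): %s", len(removed), removed)
    report = IcaReport(
        removed=removed,
        frontal_fraction=frontal_fraction,
        lowfreq_fraction=lowfreq_fraction,
        n_iter=n_iter,
        converged=converged,
    )
    return out, report


def rereference_average(rec: RawRecording) -> RawRecording:
    """Subtract the instantaneous across-channel mean (average reference)."""
    if rec.n_channels < 2:
        raise ParameterError("average reference requires at least 2 channels")
    out = rec.copy()
    out.signal = out.signal - out.signal.mean(axis=0, keepdims=True)
    return out


def downsample(rec: RawRecording, target: float = DEFAULT_TARGET_RATE) -> RawRecording:
    """Polyphase anti-aliased resampling; event onsets are rescaled.

    The anti-alias FIR cuts at the new Nyquist (``target/2``), so content
    above it — e.g. 40 Hz when resampling to 64 Hz — is attenuated.
    """
    if target >= rec.rate:
        raise ParameterError(f"target rate {target} must be below current rate {rec.rate}")
    if target <= 0:
        raise ParameterError("target rate must be positive")
    ratio = Fraction(target / rec.rate).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    data = sps.resample_poly(rec.signal, up, down, axis=1)
    scale = target / rec.rate
    new_win = int(round(target))
    events = []
    for e in rec.events:
        onset = int(round(e.onset * scale))
        onset = min(onset, data.shape[1] - new_win)  # guard rounding at the tail
        events.append(replace(e, onset=onset))
    return RawRecording(
        channels=rec.channels, rate=target, signal=data, events=events,
        subject=rec.subject,
    )


def epoch(rec: RawRecording, window_s: float = 1.0) -> EpochSet:
    """Cut one baseline-corrected epoch per event.

    Baseline correction subtracts each epoch's own per-channel mean, so every
    channel of every epoch is zero-mean.  Events whose window would be
    truncated raise :class:`InputError` listing the offenders.
    """
    if not rec.events:
        raise InputError("recording has no events to epoch")
    win = int(round(window_s * rec.rate))
    if win < 1:
        raise ParameterError("window too short for the sampling rate")
    bad = [e for e in rec.events if e.onset < 0 or e.onset + win > rec.n_samples]
    if bad:
        raise InputError(
            "epoch window truncated for events at samples "
            + ", ".join(str(e.onset) for e in bad)
        )
    data = np.stack([rec.signal[:, e.onset:e.onset + win] for e in rec.events])
    data = data - data.mean(axis=2, keepdims=True)
    meta = pd.DataFrame(
        {
            "subject": [rec.subject for _ in rec.events],
            "condition": [e.condition for e in rec.events],
            "game": [e.game for e in rec.events],
            "response_time": [e.response_time for e in rec.events],
        }
    )
    return EpochSet(data=data, rate=rec.rate, channels=rec.channels, meta=meta)


def preprocess(
    rec: RawRecording,
    *,
    band: tuple[float, float] = DEFAULT_BANDPASS,
    notch_hz: float = DEFAULT_NOTCH_HZ,
    target_rate: float = DEFAULT_TARGET_RATE,
    window_s: float = 1.0,
    run_ica: bool = True,
    ica_seed: int = 0,
) -> tuple[EpochSet, IcaReport | None]:
    """Run the full fixed-order preprocessing chain on one recording."""
    stages = list(PREPROCESS_ORDER)
    assert stages == [
        "bandpass", "notch", "remove_artifacts", "rereference_average",
        "downsample", "epoch",
    ]
    rec = bandpass(rec, *band)
    rec = notch(rec, notch_hz)
    report = None
    if run_ica:
        rec, report = remove_artifacts(rec, seed=ica_seed)
    rec = rereference_average(rec)
    rec = downsample(rec, target_rate)
    return epoch(rec, window_s), report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_recording(path: str | Path, rate: float = 512.0, subject: int | None = None) -> RawRecording:
    """Read a recording written by :func:`tacitload.synthgen.save_recording`.

    ``path`` is the signal file (header row of channel names, one column per
    channel); the event sidecar ``<stem>_events.csv`` is read if present.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    events: list[Event] = []
    sidecar = path.with_name(path.stem + "_events.csv")
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        for _, row in ev.iterrows():
            game = row["game"]
            rt = row["rt"]
            events.append(
                Event(
                    onset=int(row["onset_sample"]),
                    condition=str(row["condition"]),
                    game=None if pd.isna(game) else int(game),
                    response_time=None if pd.isna(rt) else float(rt),
                )
            )
    return RawRecording(
        channels=list(frame.columns), rate=rate, signal=frame.to_numpy().T,
        events=events, subject=subject,
    )


def read_raw_edf(path: str | Path) -> RawRecording:
    """Optional EDF ingestion (requires the ``mne`` extra)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - depends on extras
        raise ImportError(
            "EDF ingestion requires mne; install tacitload[edf]"
        ) from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RawRecording(
        channels=list(raw.ch_names),
        rate=float(raw.info["sfreq"]),
        signal=raw.get_data() * 1e6,  # volts -> µV
        events=[],
    )


def save_epochs(epochs: EpochSet, directory: str | Path) -> Path:
    """Write an epoch set as a directory of delimited text.

    ``data.csv`` holds the tensor flattened epoch-major to
    ``(n_epochs * n_channels, n_samples)`` rows; ``meta.csv`` the per-epoch
    metadata; ``shape.csv`` the tensor shape, rate and channel names.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_e, n_c, n_s = epochs.data.shape
    np.savetxt(directory / "data.csv", epochs.data.reshape(n_e * n_c, n_s),
               delimiter=",", fmt="%.8g")
    epochs.meta.to_csv(directory / "meta.csv", index=False)
    pd.DataFrame(
        {
            "n_epochs": [n_e], "n_channels": [n_c], "n_samples": [n_s],
            "rate": [epochs.rate], "channels": ["|".join(epochs.channels)],
        }
    ).to_csv(directory / "shape.csv", index=False)
    return directory


def load_epochs(directory: str | Path) -> EpochSet:
    directory = Path(directory)
    shape = pd.read_csv(directory / "shape.csv").iloc[0]
    n_e, n_c, n_s = int(shape["n_epochs"]), int(shape["n_channels"]), int(shape["n_samples"])
    data = np.loadtxt(directory / "data.csv", delimiter=",").reshape(n_e, n_c, n_s)
    meta = pd.read_csv(directory / "meta.csv")
    meta["game"] = meta["game"].astype("float").where(meta["game"].notna())
    return EpochSet(
        data=data, rate=float(shape["rate"]),
        channels=str(shape["channels"]).split("|"), meta=meta,
    )
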