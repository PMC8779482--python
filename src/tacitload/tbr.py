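"""Theta/beta-ratio extraction via the discrete wavelet transform.

At 64 Hz a 3-level dyadic decomposition maps exactly onto the classical EEG
bands: detail 1 → beta (16–32 Hz), detail 2 → alpha (8–16 Hz), detail 3 →
theta (4–8 Hz) and the level-3 approximation → delta (0–4 Hz).  Band energy
is the sum of squared coefficients in the sub-band; with an orthogonal
wavelet and periodised boundaries the four band energies sum exactly to the
epoch's signal energy (Parseval).  The theta/beta ratio is
``E_theta / E_beta`` — identical whether raw or relative (sum-normalised)
powers are used, since the normalisation cancels in the ratio.

Default wavelet: Daubechies-4, the most common choice for EEG band-power
work, which keeps band edges reasonably sharp at these short (64-sample)
epochs.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pywt

from .containers import BAND_NAMES, EpochSet, FRONTAL_CHANNELS, InputError

log = logging.getLogger(__name__)

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 3

#: Sentinel for a 0/0 theta-beta ratio; dropped from all aggregates.
TBR_UNDEFINED = np.nan


class BandEnergies(NamedTuple):
    delta: float
    theta: float
    alpha: float
    beta: float


def dwt_band_energies(
    x: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> BandEnergies:
    """Band energies (µV²·sample) of one 1-s epoch vector sampled at 64 Hz.

    The vector length must be divisible by ``2**levels`` (64 samples for the
    canonical 1-s epoch); samples must be finite.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InputError(f"expected a 1-d sample vector, got {x.ndim}-d")
    if x.size == 0 or x.size % (2**levels) != 0:
        raise InputError(
            f"vector length {x.size} is not divisible by 2**levels = {2 ** levels}"
        )
    if not np.all(np.isfinite(x)):
        raise InputError("samples must be finite")
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=levels)
    approx, *details = coeffs  # details ordered coarse (theta) .. fine (beta)
    e_delta = float(np.sum(approx**2))
    e_theta = float(np.sum(details[0] ** 2))
    e_alpha = float(np.sum(details[1] ** 2))
    e_beta = float(np.sum(details[2] ** 2))
    return BandEnergies(e_delta, e_theta, e_alpha, e_beta)


def compute_tbr(energies: BandEnergies | Sequence[float]) -> float:
    """Theta/beta ratio from band energies.

    ``E_beta == 0`` with positive theta returns ``+inf``; ``0/0`` returns the
    NaN sentinel (excluded from aggregates).  Negative energies are invalid.
    """
    if isinstance(energies, BandEnergies):
        e_theta, e_beta = energies.theta, energies.beta
    else:
        _, e_theta, _, e_beta = energies
    if e_theta < 0 or e_beta < 0:
        raise InputError("band energies must be non-negative")
    if e_beta == 0.0:
        return np.inf if e_theta > 0 else TBR_UNDEFINED
    return e_theta / e_beta


def band_power_table(
    epochs: EpochSet,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Long-format per-epoch, per-channel band powers and TBR.

    Columns: epoch metadata (``subject, condition, game, response_time``),
    ``epoch``, ``channel``, raw energies ``E_delta..E_beta``, relative powers
    ``P_delta..P_beta`` (fractions summing to 1) and ``tbr``.
    """
    n_e, n_c, n_s = epochs.data.shape
    if n_s % (2**levels) != 0:
        raise InputError(
            f"epoch length {n_s} incompatible with a {levels}-level dyadic DWT"
        )
    coeffs = pywt.wavedec(epochs.data, wavelet, mode="periodization",
                          level=levels, axis=2)
    # coeffs: [approx(delta), detail3(theta), detail2(alpha), detail1(beta)]
    energies = np.stack([np.sum(c**2, axis=2) for c in coeffs], axis=-1)
    energies = energies.reshape(n_e * n_c, 4)  # delta, theta, alpha, beta

    total = energies.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = energies / total[:, None]
        tbr = np.where(
            energies[:, 3] > 0,
            energies[:, 1] / np.where(energies[:, 3] > 0, energies[:, 3], 1.0),
            np.where(energies[:, 1] > 0, np.inf, TBR_UNDEFINED),
        )

    idx_epoch = np.repeat(np.arange(n_e), n_c)
    meta = epochs.meta.iloc[idx_epoch].reset_index(drop=True)
    out = meta.copy()
    out["epoch"] = idx_epoch
    out["channel"] = np.tile(np.asarray(epochs.channels, dtype=object), n_e)
    for j, band in enumerate(BAND_NAMES):
        out[f"E_{band}"] = energies[:, j]
    for j, band in enumerate(BAND_NAMES):
        out[f"P_{band}"] = rel[:, j]
    out["tbr"] = tbr
    return out


def aggregate_tbr(
    records: pd.DataFrame,
    by: Sequence[str] = ("condition",),
    stat: str = "median",
    channels: Iterable[str] | None = FRONTAL_CHANNELS,
) -> pd.DataFrame:
    """Grouped TBR summary with 25th/50th/75th percentiles.

    Non-finite TBR values (undefined or infinite ratios) are dropped with a
    logged count; a group left empty after dropping is flagged with NaN
    summaries rather than fabricated.
    """
    by = list(by)
    if not by:
        raise InputError("need at least one grouping key")
    if stat not in ("median", "mean"):
        raise InputError(f"stat must be 'median' or 'mean', got {stat!r}")
    df = records
    if channels is not None:
        df = df[df["channel"].isin(set(channels))]
    if df.empty:
        raise InputError("no records after channel selection")
    n_dropped_total = int((~np.isfinite(df["tbr"].to_numpy(dtype=float))).sum())
    if n_dropped_total:
        log.info("aggregate_tbr: dropped %d non-finite TBR value(s)", n_dropped_total)
    rows = []
    for key, grp in df.groupby(by, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        all_vals = grp["tbr"].to_numpy(dtype=float)
        vals = all_vals[np.isfinite(all_vals)]
        row = dict(zip(by, key))
        row["n"] = vals.size
        row["n_dropped"] = int(all_vals.size - vals.size)
        if vals.size == 0:
            row.update({stat: np.nan, "q25": np.nan, "q50": np.nan, "q75": np.nan})
        else:
            row[stat] = float(np.median(vals) if stat == "median" else np.mean(vals))
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            row.update({"q25": q25, "q50": q50, "q75": q75})
        rows.append(row)
    return pd.DataFrame(rows)
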