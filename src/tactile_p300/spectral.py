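"""Frequency-domain analyses and the delta/theta/alpha/beta filter bank.

PSD uses Welch's averaged periodogram.  ERSP and ITC are computed from
complex Morlet wavelet coefficients (7 cycles by default): ERSP is mean
power in dB relative to the per-frequency pre-stimulus baseline,
10*log10(P/P_baseline); ITC is the magnitude of the mean unit-normalized
coefficient across epochs, in [0, 1].

The classification band bank follows the conventional EEG rhythm split —
delta 0.5-3, theta 4-7, alpha 8-13, beta 14-20 Hz — and the band-selection
rule keeps bands whose CSP+classifier CV accuracy beats chance, which in
this design retains 4-20 Hz and drops delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .classify import PipelineSpec, crossval
from .containers import EpochSet
from .preprocess import FilterSpec, filter_array

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "TimeFreqMap",
    "welch_psd",
    "ersp",
    "itc",
    "band_filter_bank",
    "band_contribution",
    "select_bands",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float
    high: float


DEFAULT_BANDS = (
    BandSpec("delta", 0.5, 3.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 14.0, 20.0),
)

#: Band used for the final classification model (theta+alpha+beta).
CLASSIFICATION_BAND = (4.0, 20.0)


@dataclass
class TimeFreqMap:
    """values indexed by (freqs,) for PSD or (freqs, times) for ERSP/ITC."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray | None
    kind: str
    degenerate: bool = False
    skipped: int = 0


def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_len: int | None = None,
    overlap: float = 0.5,
) -> TimeFreqMap:
    """Welch PSD (density scaling: integral over frequency ~ variance)."""
    x = np.asarray(x, float)
    n = x.shape[-1]
    if segment_len is None:
        segment_len = min(n, 1024)
    if segment_len > n:
        raise ValueError(f"segment_len {segment_len} exceeds signal length {n}")
    f, pxx = signal.welch(
        x, fs=fs, nperseg=segment_len, noverlap=int(segment_len * overlap),
        detrend="constant", scaling="density",
    )
    return TimeFreqMap(values=pxx, freqs=f, times=None, kind="PSD")


def morlet_wavelet(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet: Gaussian envelope, sigma_t = n_cycles/(2*pi*f).

    Support is +/- 4 sigma_t; L2-normalised.  Wavelets may be longer than
    the analysed epoch — convolution zero-pads, so edge estimates are
    smoothed toward zero, which cancels in ITC (unit-normalised) and in
    baseline-relative ERSP.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs  # symmetric, odd length
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.linalg.norm(w)


def _wavelet_coeffs(
    epochs: EpochSet, channel, freqs: np.ndarray, n_cycles: float
) -> np.ndarray:
    """Complex Morlet coefficients, shape (n_epochs, n_freqs, n_times)."""
    freqs = np.asarray(freqs, float)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError(f"frequency {freqs.max()} Hz at or above Nyquist")
    ci = epochs.channel_index(channel) if isinstance(channel, str) else int(channel)
    data = epochs.data[:, ci, :]
    out = np.empty((epochs.n_epochs, len(freqs), epochs.n_times), complex)
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(float(f), epochs.fs, n_cycles)[None, :]
        out[:, fi, :] = signal.fftconvolve(data, w, mode="same", axes=1)
    return out


def ersp(
    epochs: EpochSet,
    channel,
    freqs=None,
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    n_cycles: float = 7.0,
) -> TimeFreqMap:
    """Event-related spectral perturbation in dB vs the baseline window."""
    if epochs.n_epochs < 2:
        raise ValueError("ERSP needs at least 2 epochs")
    if freqs is None:
        freqs = np.arange(2.0, 31.0)
    freqs = np.asarray(freqs, float)
    coeffs = _wavelet_coeffs(epochs, channel, freqs, n_cycles)
    power = (np.abs(coeffs) ** 2).mean(axis=0)  # (freqs, times)
    t = epochs.times
    bmask = (t >= baseline_window[0] - 1e-9) & (t <= baseline_window[1] + 1e-9)
    if not bmask.any():
        raise ValueError("baseline window outside epoch")
    base = power[:, bmask].mean(axis=1, keepdims=True)
    values = 10.0 * np.log10(power / base)
    return TimeFreqMap(values=values, freqs=freqs, times=t.copy(), kind="ERSP")


def itc(
    epochs: EpochSet,
    channel,
    freqs=None,
    n_cycles: float = 7.0,
) -> TimeFreqMap:
    """Inter-trial coherence: |mean_k c_k/|c_k||, in [0, 1].

    Coefficients with zero magnitude are skipped (count reported on the
    result).  A single epoch yields ITC = 1 everywhere and is flagged
    ``degenerate``.
    """
    if freqs is None:
        freqs = np.arange(2.0, 31.0)
    freqs = np.asarray(freqs, float)
    coeffs = _wavelet_coeffs(epochs, channel, freqs, n_cycles)
    mag = np.abs(coeffs)
    nonzero = mag > 0
    skipped = int((~nonzero).sum())
    unit = np.where(nonzero, coeffs / np.where(nonzero, mag, 1.0), 0.0)
    counts = nonzero.sum(axis=0)
    values = np.abs(unit.sum(axis=0)) / np.maximum(counts, 1)
    values = np.clip(values, 0.0, 1.0)
    return TimeFreqMap(
        values=values,
        freqs=freqs,
        times=epochs.times.copy(),
        kind="ITC",
        degenerate=epochs.n_epochs == 1,
        skipped=skipped,
    )


def band_filter_bank(
    epochs: EpochSet, bands=DEFAULT_BANDS, order: int = 4
) -> dict[str, EpochSet]:
    """Filter the broadband epochs independently per band (zero-phase)."""
    out = {}
    for band in bands:
        spec = FilterSpec(band.low, band.high, order=order)
        filtered = epochs.copy()
        filtered.data = filter_array(epochs.data, spec, epochs.fs, axis=2)
        out[band.name] = filtered
    return out


def band_contribution(
    epochs: EpochSet,
    bands=DEFAULT_BANDS,
    m: int = 3,
    classifier: str = "lda",
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-band CV accuracy of the CSP+classifier pipeline.

    Input epochs must carry two attended-side classes.  Returns a table
    with one row per band (band, low, high, accuracy, sd) — the basis of
    the keep-if-above-chance band-selection rule.
    """
    labels = set(np.unique(epochs.labels))
    if len(labels) < 2:
        raise ValueError("band_contribution needs two labelled classes")
    rows = []
    for band in bands:
        spec = PipelineSpec(band=(band.low, band.high), m=m, classifier=classifier)
        rep = crossval(epochs, spec, k=k, seed=seed)
        rows.append(
            {"band": band.name, "low": band.low, "high": band.high,
             "accuracy": rep.mean, "sd": rep.sd}
        )
    return pd.DataFrame(rows)


def select_bands(table: pd.DataFrame, chance: float = 0.5) -> list[str]:
    """Bands whose accuracy exceeds chance (drop-at-or-below-chance rule)."""
    return list(table.loc[table["accuracy"] > chance, "band"])
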