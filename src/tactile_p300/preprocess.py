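"""Preprocessing chain: re-reference, broadband filter, EOG removal, epoching.

The main analysis applies, in this fixed order: average-mastoid re-reference
(TP9/TP10) -> 0.5-30 Hz fourth-order Butterworth band-pass (zero-phase) ->
ICA-based EOG removal (optional) -> stimulus-locked epoching with -200..0 ms
baseline subtraction.  Zero-phase filtering runs the causal filter forward
and backward (effective order 2x, no group delay); causal mode exists for
real-time emulation in the sliding-window evaluator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import ContinuousRecording, EpochSet

__all__ = [
    "FilterSpec",
    "bandpass",
    "filter_array",
    "rereference",
    "epoch",
    "remove_eog",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass: ``low``-``high`` Hz, order per pass."""

    low: float
    high: float
    order: int = 4
    mode: str = "zero-phase"  # or "causal"

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got {self.low}..{self.high}")
        if self.mode not in ("zero-phase", "causal"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def _design(spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.high >= fs / 2:
        raise ValueError(
            f"band edge {spec.high} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    return signal.butter(spec.order, [spec.low, spec.high], btype="bandpass",
                         fs=fs, output="sos")


def filter_array(x: np.ndarray, spec: FilterSpec, fs: float, axis: int = -1) -> np.ndarray:
    """Apply the band-pass along ``axis`` of an array."""
    sos = _design(spec, fs)
    if spec.mode == "zero-phase":
        return signal.sosfiltfilt(sos, x, axis=axis)
    return signal.sosfilt(sos, x, axis=axis)


def bandpass(recording: ContinuousRecording, spec: FilterSpec) -> ContinuousRecording:
    """Band-pass every channel of a continuous recording."""
    out = recording.copy()
    out.data = filter_array(recording.data, spec, recording.fs, axis=1)
    return out


def rereference(
    recording: ContinuousRecording, ref_channels: tuple[str, ...] = ("TP9", "TP10")
) -> ContinuousRecording:
    """Subtract the mean of the reference channels from every channel."""
    idx = []
    for name in ref_channels:
        if name not in recording.channel_names:
            raise KeyError(f"reference channel {name!r} not in recording")
        idx.append(recording.channel_names.index(name))
    out = recording.copy()
    ref = recording.data[idx].mean(axis=0)
    out.data = recording.data - ref
    out.reference_label = "avg(" + ",".join(ref_channels) + ")"
    return out


def epoch(
    recording: ContinuousRecording,
    events: pd.DataFrame,
    tmin: float = -200.0,
    tmax: float = 1000.0,
    baseline: tuple[float, float] | None = (-200.0, 0.0),
) -> EpochSet:
    """Cut stimulus-locked epochs with per-channel baseline subtraction.

    ``events`` needs onset_sample (or onset_ms) and label columns.  The
    window is inclusive of both endpoints at sample resolution (1201 samples
    for -200..1000 ms at 1,000 Hz; sample 0 = stimulus onset).  Events whose
    window would leave the recording are dropped; the count is logged and
    recorded on the returned EpochSet.
    """
    fs = recording.fs
    if baseline is not None and not (tmin <= baseline[0] <= baseline[1] <= 0):
        raise ValueError("baseline window must lie within [tmin, 0]")
    ev = events.copy()
    if "onset_sample" not in ev.columns:
        ev["onset_sample"] = np.round(ev["onset_ms"].to_numpy(float) * fs / 1000.0).astype(int)
    off_lo = int(round(tmin * fs / 1000.0))
    off_hi = int(round(tmax * fs / 1000.0))
    n_times = off_hi - off_lo + 1

    chunks, labels, dropped = [], [], 0
    for _, row in ev.iterrows():
        s0 = int(row["onset_sample"]) + off_lo
        s1 = s0 + n_times
        if s0 < 0 or s1 > recording.n_samples:
            dropped += 1
            continue
        chunks.append(recording.data[:, s0:s1])
        labels.append(str(row["label"]) if "label" in ev.columns else "event")
    if dropped:
        logger.warning("epoch: dropped %d events with clipped windows", dropped)
    data = np.stack(chunks) if chunks else np.empty((0, recording.n_channels, n_times))

    if baseline is not None and len(chunks):
        t = tmin + np.arange(n_times) * 1000.0 / fs
        bmask = (t >= baseline[0] - 1e-9) & (t <= baseline[1] + 1e-9)
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)

    out = EpochSet(
        data=data,
        tmin=tmin,
        tmax=tmax,
        fs=fs,
        labels=np.array(labels, dtype=object),
        channel_names=list(recording.channel_names),
        baseline_window=baseline,
    )
    out.dropped = dropped
    return out


def remove_eog(
    recording: ContinuousRecording,
    n_components: int | None = None,
    frontal_channels: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4"),
    low_band: float = 3.0,
    frontal_fraction: float = 0.6,
    low_freq_fraction: float = 0.5,
    max_iter: int = 2000,
    tol: float = 1e-3,
    on_nonconvergence: str = "warn",
    seed: int = 0,
) -> tuple[ContinuousRecording, list[int]]:
    """Remove ocular components by ICA with a two-threshold automatic rule.

    The recording is unmixed with FastICA (whitened, deflation-free
    parallel updates).  A component is flagged as ocular when both hold:
    (a) the fraction of its squared mixing topography on the frontal
    channels is at least ``frontal_fraction``, and (b) the fraction of its
    source power below ``low_band`` Hz is at least ``low_freq_fraction`` —
    frontal-dominant, low-frequency components.  The recording is rebuilt
    without the flagged components.  Returns (cleaned recording, flagged
    component indices).

    The FastICA contrast cannot fully converge on subspaces that are close
    to Gaussian (rotations there are unidentifiable); the strongly
    non-Gaussian ocular components are still isolated.  Hitting the
    iteration cap therefore warns by default; pass
    ``on_nonconvergence="error"`` to raise with iteration diagnostics.
    """
    if on_nonconvergence not in ("warn", "error"):
        raise ValueError("on_nonconvergence must be 'warn' or 'error'")
    if recording.duration < 30.0:
        raise ValueError(
            f"recording is {recording.duration:.1f} s; need >= 30 s for a "
            "stable unmixing"
        )
    frontal_idx = [recording.channel_index(c) for c in frontal_channels
                   if c in recording.channel_names]
    if not frontal_idx:
        raise KeyError(f"none of the frontal channels {frontal_channels} present")

    X = recording.data.T  # samples x channels
    mean = X.mean(axis=0)
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    if on_nonconvergence == "error":
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(X - mean)  # samples x components
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"ICA did not converge within {max_iter} iterations "
                    f"(tol={tol}): {exc}"
                ) from exc
    else:
        sources = ica.fit_transform(X - mean)
    A = ica.mixing_  # channels x components

    flagged: list[int] = []
    nperseg = min(int(recording.fs * 4), sources.shape[0])
    for j in range(A.shape[1]):
        topo2 = A[:, j] ** 2
        front = topo2[frontal_idx].sum() / topo2.sum()
        f, pxx = signal.welch(sources[:, j], fs=recording.fs, nperseg=nperseg)
        low = pxx[f <= low_band].sum() / pxx.sum()
        if front >= frontal_fraction and low >= low_freq_fraction:
            flagged.append(j)

    out = recording.copy()
    if flagged:
        out.data = recording.data - (A[:, flagged] @ sources[:, flagged].T)
        logger.info("remove_eog: removed components %s", flagged)
    return out, flagged
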