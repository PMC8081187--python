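"""Performance metrics: information transfer rate, ERP summaries, paired tests.

The ITR follows the Wolpaw definition.  Bits per decision for accuracy P
over N equiprobable commands:

    B = log2(N) + P*log2(P) + (1-P)*log2((1-P)/(N-1)),

with 0*log(0) := 0 at the endpoints, and ITR = B*M bits/min where M is the
number of decisions per minute (the study's M = 9.5238 corresponds to one
decision per two 3.15 s trials).  At N = 2, B equals 1 minus the binary
entropy of P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import EpochSet

__all__ = [
    "ITRParams",
    "ERPSummary",
    "bits_per_trial",
    "itr",
    "grand_average",
    "paired_compare",
]

#: decisions per minute used throughout the study (one per 6.3 s)
DEFAULT_DECISIONS_PER_MIN = 9.5238


@dataclass(frozen=True)
class ITRParams:
    """P (accuracy), N (commands), M (decisions/min) and derived B, ITR."""

    P: float
    N: int = 2
    M: float = DEFAULT_DECISIONS_PER_MIN

    @property
    def B(self) -> float:
        return bits_per_trial(self.P, self.N)

    @property
    def bits_per_min(self) -> float:
        return itr(self.P, self.N, self.M)


@dataclass
class ERPSummary:
    """Grand-average waveform with its standard-error band and peak."""

    mean: np.ndarray  # (n_channels, n_times)
    se: np.ndarray
    times: np.ndarray  # ms
    channel_names: list[str]
    condition: str
    n_epochs: int
    peak_amplitude: float
    peak_latency_ms: float
    peak_channel: str


def bits_per_trial(P: float, N: int = 2) -> float:
    """Wolpaw bits per decision at accuracy ``P`` over ``N`` commands."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (1.0 / N - 1e-12 <= P <= 1.0 + 1e-12):
        raise ValueError(f"P={P} outside [1/N, 1] = [{1.0 / N}, 1]")
    P = min(max(P, 1.0 / N), 1.0)
    b = np.log2(N)
    if P > 0:
        b += P * np.log2(P)
    if P < 1:
        b += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(b)


def itr(P: float, N: int = 2, M: float = DEFAULT_DECISIONS_PER_MIN) -> float:
    """Information transfer rate in bits/min: bits_per_trial(P, N) * M."""
    if M <= 0:
        raise ValueError("M must be > 0")
    return bits_per_trial(P, N) * M


def grand_average(
    epochs: EpochSet,
    condition: str | None = None,
    channels: list[str] | None = None,
    peak_window: tuple[float, float] = (250.0, 450.0),
) -> ERPSummary:
    """Grand-average ERP (mean +/- SE per time point) with peak search.

    The peak is the most positive deflection of the channel-averaged trace
    within ``peak_window`` (positivity convention for the P300), reported
    with the single channel attaining the largest amplitude there.
    """
    sub = epochs.select(condition) if condition is not None else epochs
    if sub.n_epochs == 0:
        raise ValueError(f"no epochs for condition {condition!r}")
    if channels is not None:
        idx = [sub.channel_index(c) for c in channels]
        data = sub.data[:, idx, :]
        names = list(channels)
    else:
        data = sub.data
        names = list(sub.channel_names)
    mean = data.mean(axis=0)
    se = data.std(axis=0, ddof=1) / np.sqrt(data.shape[0]) if data.shape[0] > 1 else np.zeros_like(mean)

    t = sub.times
    wmask = (t >= peak_window[0] - 1e-9) & (t <= peak_window[1] + 1e-9)
    if not wmask.any():
        raise ValueError("peak window outside epoch span")
    win = mean[:, wmask]
    ch, ti = np.unravel_index(np.argmax(win), win.shape)
    return ERPSummary(
        mean=mean,
        se=se,
        times=t,
        channel_names=names,
        condition=condition or "all",
        n_epochs=sub.n_epochs,
        peak_amplitude=float(win[ch, ti]),
        peak_latency_ms=float(t[wmask][ti]),
        peak_channel=names[ch],
    )


def paired_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p).

    Degenerate inputs (zero variance of the pairwise differences) raise,
    since the t statistic is undefined there.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples of length >= 2")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return 0.0, 1.0
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
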