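"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContinuousRecording", "EpochSet"]


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG.

    data : (n_channels, n_samples) array in microvolts.
    fs : sampling frequency in Hz.
    channel_names : one name per data row.
    channel_positions : optional {name: (x, y)} montage coordinates.
    events : list of (onset_sample, code) markers, 0-based, half-open.
    reference_label : free-text description of the reference.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    channel_positions: dict[str, tuple[float, float]] | None = None
    events: list[tuple[int, str]] = field(default_factory=list)
    reference_label: str = "as recorded"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.data.shape[1]
        for onset, _ in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            channel_positions=dict(self.channel_positions)
            if self.channel_positions is not None
            else None,
            events=list(self.events),
            reference_label=self.reference_label,
        )


@dataclass
class EpochSet:
    """Stimulus-locked epochs.

    data : (n_epochs, n_channels, n_times) in microvolts.
    tmin, tmax : epoch window in ms relative to stimulus onset; both endpoints
        are included at sample resolution, so n_times = (tmax-tmin)*fs/1000 + 1
        and time 0 is the onset sample.
    labels : per-epoch condition, e.g. left_attended / right_attended /
        ignored / disturbance.
    """

    data: np.ndarray
    tmin: float
    tmax: float
    fs: float
    labels: np.ndarray
    channel_names: list[str]
    baseline_window: tuple[float, float] | None = None
    dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per epoch required")
        expected = int(round((self.tmax - self.tmin) * self.fs / 1000.0)) + 1
        if self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.tmin}..{self.tmax} ms at fs={self.fs} implies "
                f"{expected} samples, got {self.data.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms relative to onset."""
        return self.tmin + np.arange(self.n_times) * 1000.0 / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    def select(self, labels) -> "EpochSet":
        """Subset of epochs whose label is in ``labels``."""
        wanted = {labels} if isinstance(labels, str) else set(labels)
        mask = np.array([lab in wanted for lab in self.labels])
        return self._subset(mask)

    def _subset(self, mask) -> "EpochSet":
        return EpochSet(
            data=self.data[mask],
            tmin=self.tmin,
            tmax=self.tmax,
            fs=self.fs,
            labels=self.labels[mask],
            channel_names=list(self.channel_names),
            baseline_window=self.baseline_window,
        )

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Restrict the time window (ms, inclusive endpoints on samples)."""
        t = self.times
        lo = int(np.searchsorted(t, tmin - 1e-9))
        hi = int(np.searchsorted(t, tmax + 1e-9))  # exclusive
        if lo >= hi:
            raise ValueError(f"empty crop window {tmin}..{tmax} ms")
        return EpochSet(
            data=self.data[:, :, lo:hi],
            tmin=float(t[lo]),
            tmax=float(t[hi - 1]),
            fs=self.fs,
            labels=self.labels,
            channel_names=list(self.channel_names),
            baseline_window=self.baseline_window,
        )

    def copy(self) -> "EpochSet":
        out = self._subset(np.ones(self.n_epochs, bool))
        out.data = out.data.copy()
        out.dropped = self.dropped
        return out
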