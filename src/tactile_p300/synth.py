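"""Synthetic continuous EEG with planted ground truth.

Emulates the recordings the pipeline is built for: 30-channel 10-20 EEG at
1,000 Hz containing (i) a P300-like centro-parietal positive deflection
peaking near 350 ms after attended target stimuli only, (ii) class-dependent
lateralised band-limited variance over the central channels (elevated on the
hemisphere contralateral to the attended hand), (iii) 1/f background noise,
and (iv) optional frontal blink artifacts.  Every draw is reproducible from
the seed.  Somatosensory steady-state responses to the 23/100 Hz stimulator
drives are deliberately not generated; the classification band (4-20 Hz)
excludes most of where they would fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording
from .montage import channel_names, gaussian_topography, load_montage
from .paradigm import StimulusSchedule

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "make_p300_template",
    "make_pink_noise",
    "simulate_run",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic generator.

    Amplitudes are in microvolts, times in ms.  ``lateral_power_ratio`` is
    the variance ratio, between the two attended-side classes, of the
    band-limited lateral source feeding the contralateral central channel;
    1 means no class difference.  ``noise_exponent`` is the 1/f slope of the
    background (PSD proportional to f**-exponent).
    """

    n_channels: int = 30
    fs: float = 1000.0
    p300_latency: float = 350.0
    p300_width: float = 400.0
    p300_amplitude: float = 8.0
    p300_topography: np.ndarray | None = None
    lateral_band: tuple[float, float] = (8.0, 20.0)
    lateral_power_ratio: float = 4.0
    lateral_amplitude: float = 3.0
    noise_exponent: float = 1.0
    noise_scale: float = 5.0
    blink_rate: float = 0.0  # events per minute
    blink_amplitude: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 2 * max(self.lateral_band[1], 30.0):
            raise ValueError("fs must exceed twice the highest generated frequency")
        for name in ("p300_amplitude", "noise_scale", "lateral_amplitude",
                     "blink_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lateral_power_ratio <= 0:
            raise ValueError("lateral_power_ratio must be > 0")
        if self.p300_topography is not None and len(self.p300_topography) != self.n_channels:
            raise ValueError("p300_topography length must equal n_channels")


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery checks."""

    target_events: pd.DataFrame  # onset_ms, onset_sample, site, block, label
    p300_topography: np.ndarray
    lateral_topographies: dict[str, np.ndarray]  # hemisphere -> gain vector
    p300_latency: float
    p300_amplitude: float
    blink_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    blink_topography: np.ndarray | None = None


def make_p300_template(
    latency: float, width: float, amplitude: float, fs: float, length: float
) -> np.ndarray:
    """Raised-cosine (Hann) bump of given peak ``latency`` within ``length`` ms.

    The peak sample is round(latency*fs/1000) with value exactly
    ``amplitude``; the waveform is zero outside latency +/- width/2.
    """
    if not (0 <= latency - width / 2 and latency + width / 2 <= length):
        raise ValueError(
            f"template support {latency - width / 2}..{latency + width / 2} ms "
            f"outside the 0..{length} ms window"
        )
    n = int(round(length * fs / 1000.0))
    peak = int(round(latency * fs / 1000.0))
    hw = width * fs / 2000.0  # half-width in samples
    k = np.arange(n)
    out = np.zeros(n)
    if hw > 0:
        mask = np.abs(k - peak) <= hw
        out[mask] = amplitude * 0.5 * (1 + np.cos(np.pi * (k[mask] - peak) / hw))
    elif 0 <= peak < n:
        out[peak] = amplitude
    return out


def make_pink_noise(
    n_channels: int,
    n_samples: int,
    exponent: float = 1.0,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean coloured noise, PSD ~ f**-exponent, per-channel RMS = scale.

    Channels are independent.  Spectral shaping is done in the frequency
    domain on white Gaussian noise; the DC bin is zeroed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    if scale == 0:
        return np.zeros((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n_samples, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (scale / sd)


def _band_limited_noise(
    n_samples: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS noise restricted to ``band`` (Hz)."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n_samples))
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_run(
    schedule: StimulusSchedule,
    params: GeneratorParams,
    pad_ms: float = 2000.0,
) -> tuple[ContinuousRecording, GroundTruth]:
    """Render a schedule into a continuous recording plus its ground truth.

    Attended-target onsets (targets whose site equals the block's attended
    side) carry the P300 template through the centro-parietal topography;
    ignored targets and disturbances carry none.  Blocks attending left
    (resp. right) get ``sqrt(lateral_power_ratio)``-scaled drive of the
    C4-centred (resp. C3-centred) lateral source in ``lateral_band``.
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    p = params
    fs = p.fs
    names = channel_names()
    if p.n_channels != len(names):
        # generic unnamed montage for non-default channel counts
        names = [f"CH{i + 1}" for i in range(p.n_channels)]
    rng = np.random.default_rng(p.seed)

    n_samples = int(np.ceil((schedule.duration_ms + pad_ms) * fs / 1000.0))
    data = make_pink_noise(p.n_channels, n_samples, p.noise_exponent, p.noise_scale, rng)

    mont = load_montage()
    have_montage = p.n_channels == len(mont)
    if p.p300_topography is not None:
        p300_topo = np.asarray(p.p300_topography, float)
    elif have_montage:
        p300_topo = gaussian_topography((0.0, -0.35), 0.35, names)
    else:
        p300_topo = np.ones(p.n_channels) / np.sqrt(p.n_channels)

    # --- P300 on attended targets -------------------------------------------
    template = make_p300_template(p.p300_latency, p.p300_width, p.p300_amplitude, fs, 1000.0)
    attended = {b: s for b, s in enumerate(schedule.attended_sides)}
    rows = []
    for e in schedule.events:
        if e.kind != "target":
            continue
        onset_sample = int(round(e.onset * fs / 1000.0))
        is_attended = e.site == attended[e.block_index]
        label = f"{e.site}_attended" if is_attended else "ignored"
        rows.append(
            {
                "onset_ms": e.onset,
                "onset_sample": onset_sample,
                "site": e.site,
                "block": e.block_index,
                "label": label,
            }
        )
        if is_attended and p.p300_amplitude > 0:
            stop = min(onset_sample + len(template), n_samples)
            seg = template[: stop - onset_sample]
            data[:, onset_sample:stop] += np.outer(p300_topo, seg)

    # --- lateralised band-limited variance ----------------------------------
    lat_topo = {}
    if have_montage:
        lat_topo["right_hemi"] = gaussian_topography((0.5, 0.0), 0.3, names)
        lat_topo["left_hemi"] = gaussian_topography((-0.5, 0.0), 0.3, names)
    else:
        lat_topo["right_hemi"] = np.eye(p.n_channels)[min(2, p.n_channels - 1)]
        lat_topo["left_hemi"] = np.eye(p.n_channels)[0]
    src_r = _band_limited_noise(n_samples, fs, p.lateral_band, rng)
    src_l = _band_limited_noise(n_samples, fs, p.lateral_band, rng)
    boost = np.sqrt(p.lateral_power_ratio)
    gain_r = np.ones(n_samples)  # drive of the right-hemisphere (C4) source
    gain_l = np.ones(n_samples)  # drive of the left-hemisphere (C3) source
    block_events: dict[int, list] = {}
    for e in schedule.events:
        block_events.setdefault(e.block_index, []).append(e)
    for b, evs in block_events.items():
        lo = int(round(evs[0].onset * fs / 1000.0))
        hi = min(int(round((evs[-1].onset + evs[-1].duration) * fs / 1000.0)), n_samples)
        if attended[b] == "left":
            gain_r[lo:hi] = boost  # contralateral to the left hand
        else:
            gain_l[lo:hi] = boost
    if p.lateral_amplitude > 0:
        data += np.outer(lat_topo["right_hemi"], p.lateral_amplitude * gain_r * src_r)
        data += np.outer(lat_topo["left_hemi"], p.lateral_amplitude * gain_l * src_l)

    # --- blink artifacts -----------------------------------------------------
    blink_onsets = np.empty(0)
    blink_topo = None
    if p.blink_rate > 0:
        duration_s = n_samples / fs
        n_blinks = rng.poisson(p.blink_rate * duration_s / 60.0)
        blink_onsets = np.sort(rng.uniform(0, duration_s - 0.5, size=n_blinks))
        if have_montage:
            blink_topo = gaussian_topography((0.0, 1.05), 0.4, names)
        else:
            blink_topo = np.eye(p.n_channels)[0]
        bump = make_p300_template(150.0, 300.0, 1.0, fs, 300.0)
        for t0 in blink_onsets:
            s0 = int(round(t0 * fs))
            amp = p.blink_amplitude * rng.uniform(0.7, 1.3)
            stop = min(s0 + len(bump), n_samples)
            data[:, s0:stop] += np.outer(blink_topo, amp * bump[: stop - s0])

    events = [
        (
            int(round(e.onset * fs / 1000.0)),
            ("T" if e.kind == "target" else "D") + ("L" if e.site == "left" else "R"),
        )
        for e in schedule.events
    ]
    positions = (
        {n: (float(mont.loc[n, "x"]), float(mont.loc[n, "y"])) for n in names}
        if have_montage
        else None
    )
    rec = ContinuousRecording(
        data=data,
        fs=fs,
        channel_names=names,
        channel_positions=positions,
        events=events,
        reference_label="simulated common reference",
    )
    gt = GroundTruth(
        target_events=pd.DataFrame(
            rows, columns=["onset_ms", "onset_sample", "site", "block", "label"]
        ),
        p300_topography=p300_topo,
        lateral_topographies=lat_topo,
        p300_latency=p.p300_latency,
        p300_amplitude=p.p300_amplitude,
        blink_onsets_s=blink_onsets,
        blink_topography=blink_topo,
    )
    return rec, gt
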