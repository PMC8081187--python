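"""File I/O: BrainVision continuous EEG and tab-separated event tables.

Only the dialect the pipeline needs is implemented: MULTIPLEXED orientation
with INT_16 or IEEE_FLOAT_32 binary data and Marker File Version 1.0.
Anything else is rejected loudly.  Sample indexing is 0-based in memory;
BrainVision marker positions are 1-based on disk and converted on the way
through.  The float path round-trips float32 data bit-exactly; the int path
is exact to within half of the per-channel resolution step.
"""

from __future__ import annotations

import math
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording

__all__ = [
    "UnsupportedDialectError",
    "read_brainvision",
    "write_brainvision",
    "read_events_table",
    "write_events_table",
    "attach_onset_samples",
]


class UnsupportedDialectError(ValueError):
    """BrainVision feature outside the supported subset."""


_BINARY_DTYPES = {"INT_16": np.dtype("<i2"), "IEEE_FLOAT_32": np.dtype("<f4")}


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    """Minimal BrainVision header parser (INI-like, ';' comments)."""
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = sections.setdefault(m.group(1), {})
            continue
        if current is None or "=" not in line:
            continue
        key, _, val = line.partition("=")
        current[key.strip()] = val.strip()
    return sections


def read_brainvision(header_path: str | os.PathLike) -> ContinuousRecording:
    """Read a .vhdr/.vmrk/.eeg triplet into a ContinuousRecording (µV)."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header file not found: {header_path}")
    sections = _parse_ini(header_path.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})

    fmt = common.get("DataFormat", "BINARY")
    if fmt != "BINARY":
        raise UnsupportedDialectError(f"DataFormat={fmt} not supported (BINARY only)")
    orientation = common.get("DataOrientation", "MULTIPLEXED")
    if orientation != "MULTIPLEXED":
        raise UnsupportedDialectError(
            f"DataOrientation={orientation} not supported (MULTIPLEXED only)"
        )
    binfmt = binary.get("BinaryFormat", "")
    if binfmt not in _BINARY_DTYPES:
        raise UnsupportedDialectError(
            f"BinaryFormat={binfmt!r} not supported (INT_16, IEEE_FLOAT_32)"
        )

    n_channels = int(common["NumberOfChannels"])
    sampling_interval_us = float(common["SamplingInterval"])
    fs = 1e6 / sampling_interval_us

    names: list[str] = []
    resolutions = np.ones(n_channels)
    for i in range(n_channels):
        entry = sections.get("Channel Infos", {}).get(f"Ch{i + 1}")
        if entry is None:
            raise ValueError(f"header missing Ch{i + 1} in [Channel Infos]")
        parts = entry.split(",")
        names.append(parts[0])
        if len(parts) > 2 and parts[2]:
            resolutions[i] = float(parts[2])

    data_file = header_path.parent / common.get("DataFile", header_path.stem + ".eeg")
    if not data_file.exists():
        raise FileNotFoundError(f"data file referenced by header not found: {data_file}")
    dtype = _BINARY_DTYPES[binfmt]
    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_channels != 0:
        raise ValueError(
            f"truncated or corrupt data file {data_file}: {raw.size} values "
            f"is not a multiple of {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    if binfmt == "INT_16":
        data *= resolutions[:, None]
    else:
        # float files conventionally store µV directly (resolution 1)
        nontrivial = resolutions != 1.0
        if nontrivial.any():
            data[nontrivial] *= resolutions[nontrivial, None]

    events: list[tuple[int, str]] = []
    marker_file = header_path.parent / common.get("MarkerFile", header_path.stem + ".vmrk")
    if marker_file.exists():
        msec = _parse_ini(marker_file.read_text(encoding="utf-8"))
        for key in sorted(
            msec.get("Marker Infos", {}),
            key=lambda k: int(k[2:]),
        ):
            parts = msec["Marker Infos"][key].split(",")
            mtype, desc, pos = parts[0], parts[1], int(parts[2])
            if mtype == "New Segment":
                continue
            events.append((pos - 1, desc))

    return ContinuousRecording(
        data=data,
        fs=fs,
        channel_names=names,
        events=events,
        reference_label="as recorded",
    )


def write_brainvision(
    recording: ContinuousRecording,
    basepath: str | os.PathLike,
    binary_format: str = "IEEE_FLOAT_32",
    resolution: float | None = None,
) -> tuple[Path, Path, Path]:
    """Write recording as ``basepath``.vhdr/.vmrk/.eeg.

    For INT_16 the per-channel resolution defaults to max|x|/32000 so the
    full range fits; pass ``resolution`` to fix one step size for all
    channels.  Returns the three paths written.
    """
    if binary_format not in _BINARY_DTYPES:
        raise UnsupportedDialectError(f"BinaryFormat={binary_format!r} not supported")
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    n_ch = recording.n_channels
    if binary_format == "INT_16":
        if resolution is None:
            maxabs = np.abs(recording.data).max(axis=1)
            res = np.where(maxabs > 0, maxabs / 32000.0, 1.0)
        else:
            res = np.full(n_ch, float(resolution))
        quant = np.round(recording.data / res[:, None])
        if np.abs(quant).max() > 32767:
            raise ValueError("data exceeds INT_16 range at the given resolution")
        payload = quant.T.astype("<i2")
    else:
        res = np.ones(n_ch)
        payload = recording.data.T.astype("<f4")

    sampling_interval_us = 1e6 / recording.fs
    si = (
        str(int(round(sampling_interval_us)))
        if math.isclose(sampling_interval_us, round(sampling_interval_us))
        else repr(sampling_interval_us)
    )
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={si}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(recording.channel_names):
        lines.append(f"Ch{i + 1}={name},,{np.format_float_positional(res[i], trim='-')},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (onset, code) in enumerate(recording.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,{code},{onset + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    payload.tofile(eeg)
    return vhdr, vmrk, eeg


def write_events_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the paradigm events table as TSV (onset in ms)."""
    rows.to_csv(path, sep="\t", index=False)


def read_events_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an events TSV, validating row structure."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed events table {path}: {exc}") from exc
    if "onset_ms" not in df.columns:
        raise ValueError(f"events table {path} lacks an onset_ms column")
    bad = df.index[pd.to_numeric(df["onset_ms"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(
            f"malformed events table {path}: non-numeric onset_ms at line "
            f"{int(bad[0]) + 2}"  # +2: header line + 1-based
        )
    return df


def attach_onset_samples(events: pd.DataFrame, fs: float) -> pd.DataFrame:
    """Add an onset_sample column (ms -> samples at ``fs``, rounded)."""
    out = events.copy()
    out["onset_sample"] = np.round(out["onset_ms"].to_numpy(float) * fs / 1000.0).astype(int)
    return out
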