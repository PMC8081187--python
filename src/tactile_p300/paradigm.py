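"""Tactile oddball stimulus scheduling.

The protocol is a two-site (left/right index finger) tactile oddball: each run
holds 8 blocks, each block 13 trials, each trial 6 stimuli. The first trial of
a block is all disturbances and marks the block start; in every later trial
exactly one of the 6 stimulus slots carries the rare target (100 Hz, 150 ms)
and the rest carry disturbances (23 Hz, 200 ms), with a 400 ms inter-stimulus
interval. Only one site is stimulated per block, and the subject attends it.
A target trial therefore lasts 150 + 5*200 + 5*400 = 3150 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ParadigmError",
    "ParadigmConfig",
    "StimulusEvent",
    "StimulusSchedule",
    "generate_schedule",
    "trial_duration",
    "schedule_to_events_table",
    "labeled_events_table",
]

SIDES = ("left", "right")


class ParadigmError(ValueError):
    """Invalid paradigm configuration or schedule."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and structure of one run.

    Durations and intervals are in ms; ``inter_block_break`` is in seconds.
    ``target_freq``/``disturb_freq`` (Hz) describe the stimulator drive and
    only travel as metadata — stimulus waveforms are not synthesised, event
    timing is what matters downstream.
    """

    target_freq: float = 100.0
    target_dur: float = 150.0
    disturb_freq: float = 23.0
    disturb_dur: float = 200.0
    isi: float = 400.0
    stimuli_per_trial: int = 6
    trials_per_block: int = 13
    blocks_per_run: int = 8
    inter_block_break: float = 60.0
    inter_trial_gap: float = 0.0

    def __post_init__(self) -> None:
        for name in ("target_freq", "target_dur", "disturb_freq"):
            if getattr(self, name) <= 0:
                raise ParadigmError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("disturb_dur", "isi", "inter_block_break", "inter_trial_gap"):
            if getattr(self, name) < 0:
                raise ParadigmError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.stimuli_per_trial < 1:
            raise ParadigmError(
                f"stimuli_per_trial must be >= 1, got {self.stimuli_per_trial}"
            )
        if self.trials_per_block < 1:
            raise ParadigmError(
                f"trials_per_block must be >= 1, got {self.trials_per_block}"
            )
        if self.blocks_per_run < 1:
            raise ParadigmError(
                f"blocks_per_run must be >= 1, got {self.blocks_per_run}"
            )


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus: onset in integer ms from run start."""

    onset: int
    duration: float
    kind: str  # "target" | "disturbance"
    site: str  # "left" | "right"
    trial_index: int  # 0-based within block
    block_index: int  # 0-based within run


@dataclass(frozen=True)
class StimulusSchedule:
    events: tuple[StimulusEvent, ...]
    attended_sides: tuple[str, ...]  # one per block
    config: ParadigmConfig
    seed: int

    @property
    def n_targets(self) -> int:
        return sum(e.kind == "target" for e in self.events)

    @property
    def duration_ms(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset + last.duration


def trial_duration(config: ParadigmConfig) -> float:
    """Span of one target trial in ms.

    One target plus (stimuli_per_trial - 1) disturbances separated by
    between-stimulus ISIs only (no trailing ISI):
    target_dur + (s-1)*disturb_dur + (s-1)*isi.  Default config: 3150 ms.
    """
    s = config.stimuli_per_trial
    return config.target_dur + (s - 1) * (config.disturb_dur + config.isi)


def generate_schedule(
    config: ParadigmConfig,
    seed: int,
    attended_sides: list[str] | None = None,
    stimulated_sides: list[str] | None = None,
) -> StimulusSchedule:
    """Generate the run's stimulus timeline.

    Per block, trial 0 is six disturbances (the block-start marker); each
    later trial places one target uniformly at random among the 6 slots.
    The stimulated site is constant within a block and, by default, equals
    the attended side, which alternates left, right, left, ...  The same
    seed always yields an identical schedule.
    """
    if not isinstance(config, ParadigmConfig):
        config = ParadigmConfig(**config)  # type: ignore[arg-type]
    if attended_sides is None:
        attended_sides = [SIDES[b % 2] for b in range(config.blocks_per_run)]
    if len(attended_sides) != config.blocks_per_run:
        raise ParadigmError(
            f"attended_sides must list {config.blocks_per_run} blocks, "
            f"got {len(attended_sides)}"
        )
    for s in attended_sides:
        if s not in SIDES:
            raise ParadigmError(f"unknown side {s!r}")
    if stimulated_sides is None:
        stimulated_sides = list(attended_sides)
    if len(stimulated_sides) != config.blocks_per_run:
        raise ParadigmError("stimulated_sides must match blocks_per_run")

    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    t = 0.0
    for b in range(config.blocks_per_run):
        site = stimulated_sides[b]
        for trial in range(config.trials_per_block):
            if trial == 0:
                target_slot = -1  # marker trial: all disturbances
            else:
                target_slot = int(rng.integers(config.stimuli_per_trial))
            for slot in range(config.stimuli_per_trial):
                is_target = slot == target_slot
                dur = config.target_dur if is_target else config.disturb_dur
                events.append(
                    StimulusEvent(
                        onset=int(round(t)),
                        duration=dur,
                        kind="target" if is_target else "disturbance",
                        site=site,
                        trial_index=trial,
                        block_index=b,
                    )
                )
                t += dur
                if slot < config.stimuli_per_trial - 1:
                    t += config.isi
            t += config.inter_trial_gap
        if b < config.blocks_per_run - 1:
            t += config.inter_block_break * 1000.0

    return StimulusSchedule(
        events=tuple(events),
        attended_sides=tuple(attended_sides),
        config=config,
        seed=seed,
    )


def schedule_to_events_table(schedule: StimulusSchedule) -> pd.DataFrame:
    """One row per stimulus, sorted by onset."""
    rows = [
        {
            "onset_ms": e.onset,
            "duration_ms": e.duration,
            "kind": e.kind,
            "site": e.site,
            "block": e.block_index,
            "trial": e.trial_index,
        }
        for e in schedule.events
    ]
    df = pd.DataFrame(
        rows,
        columns=["onset_ms", "duration_ms", "kind", "site", "block", "trial"],
    )
    return df.sort_values("onset_ms", kind="stable").reset_index(drop=True)


def labeled_events_table(schedule: StimulusSchedule) -> pd.DataFrame:
    """Events table plus a condition label per event.

    Targets at the block's attended side are left_attended/right_attended,
    targets elsewhere are ignored, everything else is disturbance.
    """
    df = schedule_to_events_table(schedule)
    attended = {b: s for b, s in enumerate(schedule.attended_sides)}

    def _label(row) -> str:
        if row["kind"] != "target":
            return "disturbance"
        if row["site"] == attended[row["block"]]:
            return f"{row['site']}_attended"
        return "ignored"

    df["label"] = [_label(r) for _, r in df.iterrows()] if len(df) else []
    return df


def with_sides(schedule: StimulusSchedule, attended_sides: list[str]) -> StimulusSchedule:
    """Copy of ``schedule`` with a different attended-side assignment."""
    if len(attended_sides) != len(schedule.attended_sides):
        raise ParadigmError("attended_sides length mismatch")
    return replace(schedule, attended_sides=tuple(attended_sides))
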