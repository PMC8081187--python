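"""Shared helpers for the numbered analysis drivers.

One canonical synthetic session is used throughout: the full protocol run
(8 blocks x 13 trials x 6 stimuli) with inter-block breaks shortened to 2 s
for simulation, rendered at the default generator settings (P300 8 µV at
350 ms, 1/f noise 5 µV RMS, lateral 8-20 Hz power ratio 4).
"""

from pathlib import Path

from tactile_p300 import paradigm, preprocess, synth

RESULTS = Path(__file__).resolve().parent.parent / "results"

SCHEDULE_SEED = 11
GENERATOR_SEED = 12


def make_schedule(seed: int = SCHEDULE_SEED):
    cfg = paradigm.ParadigmConfig(inter_block_break=2.0)
    return paradigm.generate_schedule(cfg, seed=seed)


def make_session(seed: int = SCHEDULE_SEED, gen_seed: int = GENERATOR_SEED):
    """Simulate and preprocess the canonical session.

    Returns (schedule, recording, ground_truth, target_epochs) with the
    recording re-referenced to avg(TP9, TP10) and band-passed 0.5-30 Hz.
    """
    schedule = make_schedule(seed)
    params = synth.GeneratorParams(seed=gen_seed, lateral_power_ratio=4.0)
    rec, gt = synth.simulate_run(schedule, params)
    rec = preprocess.rereference(rec)
    rec = preprocess.bandpass(rec, preprocess.FilterSpec(0.5, 30.0))
    events = paradigm.labeled_events_table(schedule)
    epochs = preprocess.epoch(rec, events[events["kind"] == "target"])
    return schedule, rec, gt, epochs
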