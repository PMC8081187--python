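#!/usr/bin/env python
"""Generate the synthetic session: schedule, continuous EEG, and files.

Writes the stimulus events table (TSV) and the continuous recording as a
BrainVision triplet under results/data/, and prints the protocol counts.
"""

import argparse

from _shared import GENERATOR_SEED, RESULTS, make_schedule

from tactile_p300 import io_formats, paradigm, synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=None, help="schedule seed override")
    args = ap.parse_args()

    schedule = make_schedule(**({"seed": args.seed} if args.seed is not None else {}))
    params = synth.GeneratorParams(
        seed=args.seed + 1 if args.seed is not None else GENERATOR_SEED,
        lateral_power_ratio=4.0,
    )
    rec, gt = synth.simulate_run(schedule, params)

    outdir = RESULTS / "data"
    outdir.mkdir(parents=True, exist_ok=True)
    events = paradigm.labeled_events_table(schedule)
    io_formats.write_events_table(events, outdir / "events.tsv")
    io_formats.write_brainvision(rec, outdir / "synthetic_run")

    n_att = (events["label"] != "disturbance").sum()
    print(f"schedule: {len(schedule.events)} stimuli in "
          f"{schedule.config.blocks_per_run} blocks "
          f"({schedule.n_targets} targets, {n_att} attended)")
    print(f"trial duration: {paradigm.trial_duration(schedule.config):.0f} ms")
    print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
          f"at {rec.fs:.0f} Hz ({rec.duration:.0f} s)")
    print(f"wrote {outdir / 'events.tsv'} and {outdir / 'synthetic_run.vhdr'}")


if __name__ == "__main__":
    main()
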