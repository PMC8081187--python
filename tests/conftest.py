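"""Shared synthetic fixtures.

The heavy simulated datasets are session-scoped and reused across test
modules: ``demo_lr`` is the fixed-seed study-conditions dataset (8 blocks,
96 target epochs, lateral power ratio 4), ``hisnr_epochs`` a high-SNR
variant for parameter-recovery checks.  Inter-block breaks are shortened to
2 s in simulation — they carry no task-locked signal.
"""

import numpy as np
import pytest

from tactile_p300 import paradigm, preprocess, synth

DEMO_SCHEDULE_SEED = 11
DEMO_GENERATOR_SEED = 12
HISNR_SCHEDULE_SEED = 21
HISNR_GENERATOR_SEED = 121


@pytest.fixture(scope="session")
def demo_config():
    return paradigm.ParadigmConfig(inter_block_break=2.0)


@pytest.fixture(scope="session")
def demo_schedule(demo_config):
    return paradigm.generate_schedule(demo_config, seed=DEMO_SCHEDULE_SEED)


@pytest.fixture(scope="session")
def demo_run(demo_schedule):
    params = synth.GeneratorParams(seed=DEMO_GENERATOR_SEED, lateral_power_ratio=4.0)
    return synth.simulate_run(demo_schedule, params)


@pytest.fixture(scope="session")
def demo_epochs(demo_schedule, demo_run):
    rec, _ = demo_run
    rec = preprocess.rereference(rec)
    rec = preprocess.bandpass(rec, preprocess.FilterSpec(0.5, 30.0))
    events = paradigm.labeled_events_table(demo_schedule)
    return preprocess.epoch(rec, events[events["kind"] == "target"])


@pytest.fixture(scope="session")
def demo_lr(demo_epochs):
    return demo_epochs.select(["left_attended", "right_attended"])


@pytest.fixture(scope="session")
def hisnr_schedule(demo_config):
    return paradigm.generate_schedule(demo_config, seed=HISNR_SCHEDULE_SEED)


@pytest.fixture(scope="session")
def hisnr_run(hisnr_schedule):
    params = synth.GeneratorParams(
        seed=HISNR_GENERATOR_SEED, p300_amplitude=20.0, noise_scale=2.0,
        lateral_power_ratio=4.0,
    )
    return synth.simulate_run(hisnr_schedule, params)


@pytest.fixture(scope="session")
def hisnr_epochs(hisnr_schedule, hisnr_run):
    rec, _ = hisnr_run
    rec = preprocess.rereference(rec)
    rec = preprocess.bandpass(rec, preprocess.FilterSpec(0.5, 30.0))
    events = paradigm.labeled_events_table(hisnr_schedule)
    return preprocess.epoch(rec, events[events["kind"] == "target"])


@pytest.fixture(scope="session")
def hisnr_raw_epochs(hisnr_schedule, hisnr_run):
    """High-SNR epochs cut straight from the unprocessed simulation."""
    rec, _ = hisnr_run
    events = paradigm.labeled_events_table(hisnr_schedule)
    return preprocess.epoch(rec, events[events["kind"] == "target"])


def rereferenced(vec: np.ndarray, names: list[str]) -> np.ndarray:
    """Planted topography expressed in the TP9/TP10 average reference."""
    ref = (vec[names.index("TP9")] + vec[names.index("TP10")]) / 2.0
    return vec - ref
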