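"""Filtering, re-referencing, epoching, and ICA-based EOG removal."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from tactile_p300 import paradigm, preprocess, synth
from tactile_p300.containers import ContinuousRecording
from tactile_p300.preprocess import FilterSpec, bandpass, epoch, remove_eog, rereference


def sine_recording(freq, fs=1000.0, seconds=10.0, channels=("Cz",)):
    t = np.arange(int(fs * seconds)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (len(channels), 1))
    return ContinuousRecording(data, fs=fs, channel_names=list(channels))


class TestBandpass:
    def test_passband_preserves_amplitude_and_phase(self):
        # long signal and deep interior: the 0.5 Hz edge transient decays slowly
        rec = sine_recording(10.0, seconds=40.0)
        out = bandpass(rec, FilterSpec(0.5, 30.0))
        mid = slice(15000, 25000)
        x, y = rec.data[0, mid], out.data[0, mid]
        gain = np.sqrt((y**2).mean() / (x**2).mean())
        assert abs(gain - 1.0) < 0.01
        # zero-phase: phase shift of the fundamental < 1 degree
        proj = np.vdot(x, y) / np.sqrt(np.vdot(x, x) * np.vdot(y, y))
        assert np.degrees(np.arccos(np.clip(np.real(proj), -1, 1))) < 1.0

    def test_stopband_matches_designed_response(self):
        rec = sine_recording(50.0, seconds=40.0)
        spec = FilterSpec(0.5, 30.0)
        out = bandpass(rec, spec)
        mid = slice(15000, 25000)
        measured = np.sqrt((out.data[0, mid] ** 2).mean() / (rec.data[0, mid] ** 2).mean())
        sos = signal.butter(spec.order, [spec.low, spec.high], btype="bandpass",
                            fs=rec.fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[50.0], fs=rec.fs)
        designed = np.abs(h[0]) ** 2  # forward-backward: |H|^2
        assert measured < 0.1  # > 90% attenuation
        assert abs(measured - designed) <= 0.02 * max(designed, 0.01)

    def test_dc_removed(self):
        rec = ContinuousRecording(np.full((1, 5000), 7.0), 1000.0, ["Cz"])
        out = bandpass(rec, FilterSpec(0.5, 30.0))
        assert np.abs(out.data[0, 1000:4000]).mean() < 0.07

    def test_band_edge_at_nyquist_errors(self):
        rec = sine_recording(10.0, fs=100.0, seconds=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, FilterSpec(0.5, 60.0))

    def test_causal_mode_delays(self):
        rec = sine_recording(10.0)
        zp = bandpass(rec, FilterSpec(0.5, 30.0, mode="zero-phase"))
        ca = bandpass(rec, FilterSpec(0.5, 30.0, mode="causal"))
        assert not np.allclose(zp.data, ca.data)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            FilterSpec(30.0, 0.5)


class TestRereference:
    def make(self, data):
        names = ["Cz", "Pz", "TP9", "TP10"]
        return ContinuousRecording(np.asarray(data, float), 1000.0, names)

    def test_zero_reference_channels_noop(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 100))
        data[2:] = 0.0
        rec = self.make(data)
        out = rereference(rec)
        assert np.allclose(out.data, rec.data)

    def test_common_mode_rejected(self):
        rec = self.make(np.full((4, 50), 3.3))
        assert np.allclose(rereference(rec).data, 0.0)

    def test_idempotent_after_first_application(self):
        rng = np.random.default_rng(1)
        rec = self.make(rng.standard_normal((4, 200)))
        once = rereference(rec)
        twice = rereference(once)
        assert np.allclose(once.data, twice.data)
        assert once.reference_label == "avg(TP9,TP10)"

    def test_missing_channel_named(self):
        rec = ContinuousRecording(np.zeros((2, 10)), 1000.0, ["Cz", "Pz"])
        with pytest.raises(KeyError, match="TP9"):
            rereference(rec)


class TestEpoch:
    def test_sample_count_convention(self, demo_epochs):
        assert demo_epochs.n_times == 1201  # -200..1000 ms inclusive at 1 kHz
        assert demo_epochs.times[0] == -200.0
        assert demo_epochs.times[-1] == 1000.0

    def test_target_epoch_count_matches_schedule(self, demo_schedule, demo_epochs):
        assert demo_epochs.n_epochs == demo_schedule.n_targets == 96
        assert demo_epochs.dropped == 0

    def test_constant_recording_gives_zero_epochs(self):
        rec = ContinuousRecording(np.full((2, 5000), 11.0), 1000.0, ["Cz", "Pz"])
        ev = pd.DataFrame({"onset_ms": [1000, 2000], "label": ["a", "b"]})
        ep = epoch(rec, ev)
        assert np.allclose(ep.data, 0.0)

    def test_clipped_windows_dropped_and_counted(self):
        rec = ContinuousRecording(np.zeros((1, 2000)), 1000.0, ["Cz"])
        ev = pd.DataFrame({"onset_ms": [100, 500, 1500], "label": ["a", "a", "a"]})
        ep = epoch(rec, ev)
        assert ep.n_epochs == 1
        assert ep.dropped == 2

    def test_baseline_outside_window_errors(self):
        rec = ContinuousRecording(np.zeros((1, 2000)), 1000.0, ["Cz"])
        ev = pd.DataFrame({"onset_ms": [500], "label": ["a"]})
        with pytest.raises(ValueError):
            epoch(rec, ev, baseline=(-500.0, 0.0))

    def test_zero_phase_filter_keeps_peak_sample(self):
        """The 0.5-30 Hz zero-phase filter must not move the P300 peak."""
        from tactile_p300.synth import make_p300_template

        x = np.zeros(6000)
        x[2000:3000] += make_p300_template(350, 400, 10.0, 1000, 1000)
        rec = ContinuousRecording(x[None, :], 1000.0, ["Cz"])
        out = bandpass(rec, FilterSpec(0.5, 30.0))
        w = slice(2200, 2500)
        assert abs(int(np.argmax(out.data[0, w])) - int(np.argmax(rec.data[0, w]))) <= 1


def _blinky_recording(blink_rate, seed, seconds_pad=8000.0):
    cfg = paradigm.ParadigmConfig(
        blocks_per_run=2, trials_per_block=7, inter_block_break=2.0
    )
    sched = paradigm.generate_schedule(cfg, seed=seed)
    params = synth.GeneratorParams(fs=250.0, seed=seed + 1, blink_rate=blink_rate)
    rec, gt = synth.simulate_run(sched, params, pad_ms=seconds_pad)
    return rec, gt


def _frontal_low_variance(rec):
    x = preprocess.filter_array(rec.data, FilterSpec(0.5, 3.0), rec.fs, axis=1)
    idx = [rec.channel_index(c) for c in ("Fp1", "Fp2")]
    return x[idx].var()


class TestRemoveEog:
    def test_nothing_to_remove(self):
        rec, _ = _blinky_recording(blink_rate=0.0, seed=60)
        clean, flagged = remove_eog(rec, seed=0)
        rel = np.sqrt(((clean.data - rec.data) ** 2).mean() / (rec.data**2).mean())
        assert rel < 0.05
        assert len(flagged) <= 1

    def test_planted_blinks_flagged_and_removed(self):
        rec, gt = _blinky_recording(blink_rate=15.0, seed=62)
        assert len(gt.blink_onsets_s) > 3
        before = _frontal_low_variance(rec)
        clean, flagged = remove_eog(rec, seed=0)
        assert flagged
        assert _frontal_low_variance(clean) <= 0.2 * before

    def test_second_pass_flags_nothing_new(self):
        rec, _ = _blinky_recording(blink_rate=15.0, seed=64)
        clean, flagged = remove_eog(rec, seed=0)
        _, flagged2 = remove_eog(clean, seed=0)
        assert len(flagged2) == 0

    def test_error_mode_raises_on_nonconvergence(self):
        rec, _ = _blinky_recording(blink_rate=0.0, seed=60)
        with pytest.raises(RuntimeError, match="iteration"):
            remove_eog(rec, max_iter=2, on_nonconvergence="error", seed=0)

    def test_too_short_recording_errors(self):
        rec = ContinuousRecording(
            np.random.default_rng(0).standard_normal((4, 1000)),
            1000.0,
            ["Fp1", "Fp2", "Cz", "Pz"],
        )
        with pytest.raises(ValueError, match="30"):
            remove_eog(rec)
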