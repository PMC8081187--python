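"""PSD, ERSP, ITC, the rhythm filter bank, and band contribution scoring."""

import numpy as np
import pytest

from tactile_p300 import paradigm, preprocess, spectral, synth
from tactile_p300.containers import EpochSet
from tactile_p300.spectral import (
    DEFAULT_BANDS,
    band_contribution,
    band_filter_bank,
    ersp,
    itc,
    select_bands,
    welch_psd,
)

FS = 256.0
TIMES = np.arange(-0.2, 1.0 + 1e-9, 1 / FS) * 1000  # ms
N_TIMES = len(TIMES)


def epochs_from(data, labels=None):
    n = data.shape[0]
    return EpochSet(
        data=data, tmin=TIMES[0], tmax=TIMES[-1], fs=FS,
        labels=np.asarray(labels if labels is not None else ["x"] * n, dtype=object),
        channel_names=["Cz"] if data.shape[1] == 1 else
        [f"C{i}" for i in range(data.shape[1])],
    )


class TestWelchPsd:
    def test_sine_peak_at_its_frequency(self):
        t = np.arange(32768) / 1000.0
        ps = welch_psd(np.sin(2 * np.pi * 10 * t), fs=1000.0, segment_len=2048)
        assert np.isclose(ps.freqs[np.argmax(ps.values)], 10.0, atol=0.5)

    def test_white_noise_flat(self):
        x = np.random.default_rng(0).standard_normal(2**17)
        ps = welch_psd(x, fs=1000.0, segment_len=1024)
        m = (ps.freqs >= 1) & (ps.freqs <= 100)
        edges = np.arange(0, 101, 10)
        bands = [
            ps.values[m][(ps.freqs[m] >= lo) & (ps.freqs[m] < hi)].mean()
            for lo, hi in zip(edges, edges[1:])
        ]
        assert max(bands) / min(bands) < 2.0

    def test_zero_signal(self):
        ps = welch_psd(np.zeros(4096), fs=1000.0)
        assert not ps.values.any()

    def test_parseval_within_five_percent(self):
        x = np.random.default_rng(1).standard_normal(65536)
        ps = welch_psd(x, fs=256.0, segment_len=1024)
        integral = np.trapezoid(ps.values, ps.freqs)
        assert abs(integral / x.var() - 1.0) < 0.05

    def test_segment_longer_than_signal_errors(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), fs=100.0, segment_len=200)


class TestErsp:
    def test_stationary_epochs_near_zero_db(self):
        rng = np.random.default_rng(2)
        ep = epochs_from(rng.standard_normal((80, 1, N_TIMES)))
        tf = ersp(ep, "Cz", freqs=np.arange(6.0, 20.0))
        interior = (tf.times >= -100) & (tf.times <= 900)
        assert np.abs(tf.values[:, interior]).mean() < 1.0

    def test_planted_burst_positive_db(self):
        rng = np.random.default_rng(3)
        burst = np.where(
            (TIMES >= 300) & (TIMES <= 700),
            3.0 * np.cos(2 * np.pi * 10 * TIMES / 1000),
            0.0,
        )
        ep = epochs_from(rng.standard_normal((40, 1, N_TIMES)) + burst)
        tf = ersp(ep, "Cz", freqs=np.arange(4.0, 20.0))
        fi = np.argmin(np.abs(tf.freqs - 10))
        tm = (tf.times >= 400) & (tf.times <= 600)
        assert tf.values[fi, tm].mean() > 3.0

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((10, 1, N_TIMES))
        a = ersp(epochs_from(data), "Cz", freqs=[8.0, 12.0])
        b = ersp(epochs_from(2 * data), "Cz", freqs=[8.0, 12.0])
        assert np.allclose(a.values, b.values)

    def test_above_nyquist_errors(self):
        ep = epochs_from(np.zeros((4, 1, N_TIMES)) + 1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ersp(ep, "Cz", freqs=[200.0])

    def test_needs_two_epochs(self):
        ep = epochs_from(np.ones((1, 1, N_TIMES)))
        with pytest.raises(ValueError):
            ersp(ep, "Cz")


class TestItc:
    def test_identical_epochs_give_one(self):
        sig = np.cos(2 * np.pi * 10 * TIMES / 1000)
        ep = epochs_from(np.tile(sig, (8, 1, 1)))
        tf = itc(ep, "Cz", freqs=[2.0, 8.0, 10.0])
        assert np.allclose(tf.values, 1.0, atol=1e-9)
        assert not tf.degenerate

    def test_single_epoch_degenerate(self):
        sig = np.cos(2 * np.pi * 10 * TIMES / 1000)
        tf = itc(epochs_from(sig[None, None, :]), "Cz", freqs=[10.0])
        assert np.allclose(tf.values, 1.0)
        assert tf.degenerate

    def test_random_phase_expectation(self):
        """E[ITC] for n random phases approaches sqrt(pi/4)/sqrt(n)."""
        rng = np.random.default_rng(5)
        fs, n_t = 128.0, 64
        tt = np.arange(n_t) / fs
        draws = []
        for _ in range(200):
            phases = rng.uniform(0, 2 * np.pi, 20)
            data = np.cos(2 * np.pi * 8 * tt[None, :] + phases[:, None])[:, None, :]
            ep = EpochSet(
                data, tmin=0.0, tmax=(n_t - 1) / fs * 1000, fs=fs,
                labels=np.array(["x"] * 20, dtype=object), channel_names=["Cz"],
            )
            draws.append(itc(ep, "Cz", freqs=[8.0], n_cycles=3).values[0, n_t // 2])
        theory = np.sqrt(np.pi / 4) / np.sqrt(20)
        assert abs(np.mean(draws) / theory - 1.0) < 0.10

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(6)
        ep = epochs_from(rng.standard_normal((12, 1, N_TIMES)))
        tf = itc(ep, "Cz", freqs=np.arange(4.0, 30.0, 4))
        assert (tf.values >= 0).all() and (tf.values <= 1).all()

    def test_agrees_with_mne_interior(self):
        mtf = pytest.importorskip("mne.time_frequency")
        rng = np.random.default_rng(7)
        data = rng.standard_normal((10, 1, N_TIMES))
        ours = itc(epochs_from(data), "Cz", freqs=[15.0, 20.0], n_cycles=5)
        coeffs = mtf.tfr_array_morlet(
            data, sfreq=FS, freqs=[15.0, 20.0], n_cycles=5, output="complex",
        )[:, 0]
        ref = np.abs((coeffs / np.abs(coeffs)).mean(axis=0))
        interior = slice(80, 230)
        assert np.abs(ours.values[:, interior] - ref[:, interior]).mean() < 0.03


class TestFilterBank:
    def test_alpha_sine_routed_to_alpha_band(self):
        sig = np.sin(2 * np.pi * 10 * TIMES / 1000)
        ep = epochs_from(np.tile(sig, (3, 1, 1)))
        banks = band_filter_bank(ep)
        mid = slice(60, 240)
        power = {
            name: (b.data[0, 0, mid] ** 2).mean() for name, b in banks.items()
        }
        ref = (sig[mid] ** 2).mean()
        assert power["alpha"] > 0.8 * ref
        assert power["theta"] < 0.2 * ref and power["beta"] < 0.2 * ref

    def test_dc_epochs_vanish(self):
        ep = epochs_from(np.full((2, 1, N_TIMES), 5.0))
        banks = band_filter_bank(ep)
        for b in banks.values():
            assert np.abs(b.data).max() < 0.25

    def test_band_names_and_edges(self):
        names = [b.name for b in DEFAULT_BANDS]
        assert names == ["delta", "theta", "alpha", "beta"]
        assert DEFAULT_BANDS[0].low == 0.5 and DEFAULT_BANDS[-1].high == 20.0


def small_lateral_epochs(band, seed, ratio=6.0):
    cfg = paradigm.ParadigmConfig(blocks_per_run=4, inter_block_break=2.0)
    sched = paradigm.generate_schedule(cfg, seed=seed)
    params = synth.GeneratorParams(
        seed=seed + 1, lateral_band=band, lateral_power_ratio=ratio,
        p300_amplitude=0.0,
    )
    rec, _ = synth.simulate_run(sched, params)
    rec = preprocess.rereference(rec)
    rec = preprocess.bandpass(rec, preprocess.FilterSpec(0.5, 30.0))
    ev = paradigm.labeled_events_table(sched)
    ep = preprocess.epoch(rec, ev[ev["kind"] == "target"])
    return ep.select(["left_attended", "right_attended"])


class TestBandContribution:
    def test_alpha_planting_recovered(self):
        lr = small_lateral_epochs(band=(8.0, 13.0), seed=70)
        table = band_contribution(lr, k=6, seed=0)
        best = table.loc[table["accuracy"].idxmax(), "band"]
        assert best == "alpha"
        assert "alpha" in select_bands(table)

    def test_no_planting_all_near_chance(self):
        lr = small_lateral_epochs(band=(8.0, 13.0), seed=72, ratio=1.0)
        table = band_contribution(lr, k=6, seed=0)
        half_width = 2.576 * np.sqrt(0.25 / lr.n_epochs)
        assert (np.abs(table["accuracy"] - 0.5) <= half_width + 1e-9).all()

    def test_single_class_errors(self, demo_lr):
        only_left = demo_lr.select("left_attended")
        with pytest.raises(ValueError):
            band_contribution(only_left)
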