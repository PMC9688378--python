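"""Morlet decomposition and dB baselining: localization, linearity, identities."""

import numpy as np
import pytest

from betadesync.simulate import EEGEpoch, NeuralSimConfig, synth_epoch
from betadesync.task import TrialTimeline
from betadesync.tfr import (
    MorletBank,
    MorletConfig,
    TFRMatrix,
    condition_average,
    db_normalize,
    morlet_transform,
    window_columns,
)


def make_epoch(data_1d, fs=256.0, timeline=None):
    timeline = timeline or TrialTimeline()
    n = len(data_1d)
    times = timeline.epoch_start_s + np.arange(n) / fs
    data = np.tile(data_1d, (6, 1))
    return EEGEpoch(
        channels=("F3", "F4", "C3", "C4", "P3", "P4"),
        fs=fs,
        times=times,
        data=data,
        participant="P0",
        group="younger",
        condition="1:1",
        trial=0,
    )


@pytest.fixture(scope="module")
def grid():
    fs = 256.0
    n = int(6.5 * fs) + 1
    times = TrialTimeline().epoch_start_s + np.arange(n) / fs
    return fs, n, times


class TestMorletTransform:
    def test_zero_signal_zero_power(self, grid):
        fs, n, _ = grid
        ep = make_epoch(np.zeros(n), fs)
        tfr = morlet_transform(ep, "C3")
        assert np.all(tfr.power == 0)
        assert tfr.scale == "raw"

    def test_pure_tone_peak_at_nearest_grid_frequency(self, grid):
        """Mid-epoch power argmax lands on the grid point nearest the tone;
        oracle: the FFT spectrum of the same signal peaks at 20 Hz."""
        fs, n, times = grid
        tone = np.sin(2 * np.pi * 20.0 * times)
        spec = np.abs(np.fft.rfft(tone))
        f_fft = np.fft.rfftfreq(n, 1 / fs)
        assert f_fft[np.argmax(spec)] == pytest.approx(20.0, abs=0.2)

        ep = make_epoch(tone, fs)
        tfr = morlet_transform(ep, "C3")
        mid = np.argmin(np.abs(tfr.times))
        peak_f = tfr.freqs[np.argmax(tfr.power[:, mid])]
        nearest = tfr.freqs[np.argmin(np.abs(tfr.freqs - 20.0))]
        assert peak_f == nearest

    def test_amplitude_scaling_quadratic(self, grid):
        """Scaling the signal by k scales every raw power cell by k^2."""
        fs, n, times = grid
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        t1 = morlet_transform(make_epoch(x, fs), "C3")
        t2 = morlet_transform(make_epoch(3.0 * x, fs), "C3")
        v = t1.valid_or_all()
        assert np.allclose(t2.power[v], 9.0 * t1.power[v], rtol=1e-9)
        # +6.02 dB per amplitude doubling at every retained cell
        t3 = morlet_transform(make_epoch(2.0 * x, fs), "C3")
        nz = v & (t1.power > 1e-300)
        db = 10 * np.log10(t3.power[nz] / t1.power[nz])
        assert np.allclose(db, 20 * np.log10(2.0), atol=1e-9)

    def test_frequency_localization(self, grid):
        """>= 90% of mid-epoch power mass concentrates near a beta-band tone.

        The neighborhood is +-4 Hz: with the default cycle counts the
        spectral SD at the top of the band is f/cycles ~ 3.3 Hz, so this is
        roughly a 1.2-sigma box around the tone.
        """
        fs, n, times = grid
        for f0 in (14.0, 18.0, 20.0, 24.0, 28.0):
            tone = np.sin(2 * np.pi * f0 * times)
            tfr = morlet_transform(make_epoch(tone, fs), "C3")
            mid = np.argmin(np.abs(tfr.times))
            col = tfr.power[:, mid]
            near = np.abs(tfr.freqs - f0) <= 4.0
            assert col[near].sum() / col.sum() >= 0.90

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError):
            MorletBank(100.0, 1000, MorletConfig(f_max=35.0))

    def test_matches_mne_morlet(self, grid):
        """Independent oracle: MNE's Morlet TFR agrees on the dB pattern."""
        mne = pytest.importorskip("mne")
        fs, n, times = grid
        cfg = NeuralSimConfig(background_rms=0.01, amp_mod_sd=0.0, seed=1)
        ep = synth_epoch(cfg, "P0", "older", "1:1", seed=1)
        ours = morlet_transform(ep, "C3")

        freqs = ours.freqs
        cycles = MorletConfig().cycles
        mne_power = mne.time_frequency.tfr_array_morlet(
            ep.data[None, 2:3, :],
            sfreq=fs,
            freqs=freqs,
            n_cycles=cycles,
            output="power",
            zero_mean=False,
        )[0, 0][:, :: MorletConfig().decim]
        # compare dB-normalized values (absolute scales differ by convention)
        cols = window_columns(ours.times, (-2.5, -2.2))
        ours_db = 10 * np.log10(
            ours.power / ours.power[:, cols].mean(axis=1, keepdims=True)
        )
        mne_db = 10 * np.log10(
            mne_power / mne_power[:, cols].mean(axis=1, keepdims=True)
        )
        v = ours.valid_or_all()
        beta = (freqs >= 13) & (freqs <= 30)
        sel = v & beta[:, None]
        assert np.allclose(ours_db[sel], mne_db[sel], atol=0.15)


class TestConditionAverage:
    def test_single_trial_identity(self, grid):
        fs, n, _ = grid
        rng = np.random.default_rng(1)
        t = morlet_transform(make_epoch(rng.normal(size=n), fs), "C3")
        avg = condition_average([t])
        assert np.array_equal(avg.power, t.power)

    def test_matches_loop_oracle(self, grid):
        fs, n, _ = grid
        rng = np.random.default_rng(2)
        tfrs = [
            morlet_transform(make_epoch(rng.normal(size=n), fs), "C3")
            for _ in range(4)
        ]
        avg = condition_average(tfrs)
        oracle = sum(t.power for t in tfrs) / 4
        assert np.allclose(avg.power, oracle, rtol=1e-12)

    def test_grid_mismatch_rejected(self, grid):
        fs, n, _ = grid
        rng = np.random.default_rng(3)
        a = morlet_transform(make_epoch(rng.normal(size=n), fs), "C3")
        b = morlet_transform(
            make_epoch(rng.normal(size=n), fs), "C3", MorletConfig(n_freqs=17)
        )
        with pytest.raises(ValueError):
            condition_average([a, b])


class TestDbNormalize:
    def _flat_tfr(self, value=2.0):
        freqs = np.linspace(3, 35, 9)
        times = np.linspace(-3, 3.5, 105)
        power = np.full((9, 105), value)
        return TFRMatrix(power, freqs, times, "raw")

    def test_self_baseline_zero_db(self):
        t = self._flat_tfr()
        db = db_normalize(t, [t])
        assert np.allclose(db.power, 0.0)

    def test_tenfold_power_is_ten_db(self):
        base = self._flat_tfr(1.0)
        t = self._flat_tfr(10.0)
        db = db_normalize(t, [base])
        assert np.allclose(db.power, 10.0)

    def test_condition_average_baseline_window_zero(self, grid):
        """The across-condition mean dB inside the baseline window is 0."""
        fs, n, _ = grid
        rng = np.random.default_rng(4)
        cond_avgs = [
            morlet_transform(make_epoch(1 + 0.1 * rng.normal(size=n), fs), "C3")
            for _ in range(3)
        ]
        dbs = [db_normalize(t, cond_avgs) for t in cond_avgs]
        cols = window_columns(dbs[0].times, (-2.5, -2.2))
        lin = np.mean([10 ** (d.power[:, cols] / 10) for d in dbs], axis=0)
        # mean of the linear-power ratios is exactly 1 in the window
        assert np.allclose(lin.mean(axis=1), 1.0, atol=1e-9)

    def test_nonpositive_baseline_rejected(self):
        t = self._flat_tfr(0.0)
        with pytest.raises(ValueError):
            db_normalize(t, [t])

    def test_window_outside_axis_rejected(self):
        t = self._flat_tfr()
        with pytest.raises(ValueError):
            db_normalize(t, [t], window=(10.0, 11.0))

    def test_injected_depth_recovered_noise_free(self, timeline):
        """Noise-free epochs: mean beta-band dB over the execution window
        equals the injected depth within 0.3 dB."""
        depth = -4.0
        cfg = NeuralSimConfig(
            background_rms=0.0,
            amp_mod_sd=0.0,
            execution_depth={k: depth for k in NeuralSimConfig().execution_depth},
        )
        ep = synth_epoch(cfg, "P0", "older", "1:1", seed=5)
        raw = morlet_transform(ep, "C4")
        db = db_normalize(raw, [raw], timeline=timeline)
        cols = window_columns(db.times, timeline.exec_window)
        row = np.argmin(np.abs(db.freqs - cfg.beta_freq))
        got = db.power[row, cols].mean()
        assert got == pytest.approx(depth, abs=0.3)
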