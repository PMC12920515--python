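import numpy as np
import pytest
from scipy import signal as sps

from envtrf.errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from envtrf.preprocess import (
    AveragedResponse,
    EpochSet,
    alpha_power,
    average_repetitions,
    bandpass_fir,
    baseline_normalize,
    epoch,
    resample,
)


class TestBandpassFIR:
    def test_passband_sinusoid_preserved(self):
        fs = 256.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * 30 * t)
        y = bandpass_fir(x, 1.0, 57.0, fs)
        core = slice(int(fs), -int(fs))  # ignore edge transients
        ratio = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert abs(ratio - 1) < 0.05

    def test_dc_attenuated(self):
        fs = 256.0
        y = bandpass_fir(np.full(int(8 * fs), 5.0), 1.0, 57.0, fs)
        assert np.abs(y).max() < 5.0 * 10 ** (-20 / 20)

    def test_high_edge_above_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            bandpass_fir(np.zeros(1000), 1.0, 200.0, 256.0)


class TestResample:
    def test_identity(self):
        x = np.arange(100.0)
        assert np.array_equal(resample(x, 256, 256), x)

    def test_2048_to_256_divides_exactly(self):
        x = np.zeros(2048)
        assert resample(x, 2048, 256).shape == (256,)

    def test_sinusoid_preserved(self):
        fs0, fs1 = 2048.0, 256.0
        t = np.arange(int(4 * fs0)) / fs0
        y = resample(np.sin(2 * np.pi * 10 * t), fs0, fs1)
        t1 = np.arange(len(y)) / fs1
        # least-squares sine fit at 10 Hz recovers amplitude within 2%
        A = np.column_stack([np.sin(2 * np.pi * 10 * t1), np.cos(2 * np.pi * 10 * t1)])
        core = slice(int(fs1), -int(fs1))
        coef, *_ = np.linalg.lstsq(A[core], y[core], rcond=None)
        assert abs(np.hypot(*coef) - 1.0) < 0.02


class TestEpoch:
    def test_onset_sample_is_t0(self):
        fs = 256.0
        data = np.arange(768.0)[None, :]
        es = epoch(data, [128], fs, ["Cz"], window=(-0.5, 2.5))
        assert es.data.shape == (1, 1, 768)
        assert es.data[0, 0, 0] == 0.0  # covers samples 0..767
        assert es.times[128] == pytest.approx(0.0)

    def test_zero_onsets_gives_empty_set(self):
        es = epoch(np.zeros((2, 1000)), [], 256.0, ["a", "b"])
        assert es.n_epochs == 0

    def test_out_of_bounds_onsets_reported(self):
        with pytest.raises(InvalidInputError, match="900"):
            epoch(np.zeros((1, 1000)), [128, 900], 256.0, ["Cz"])

    def test_item_reps_layout(self):
        # 10 sentences x 4 repetitions -> 40 epochs with labels
        onsets = np.arange(40) * 800 + 200
        labels = np.repeat(np.arange(10), 4)
        es = epoch(np.zeros((1, 40 * 800 + 1000)), onsets, 256.0, ["Cz"],
                   item_labels=labels)
        assert es.n_epochs == 40
        assert len(np.unique(es.item_labels)) == 10


class TestAveraging:
    def _epochs(self, data, fs=256.0, labels=None):
        n = data.shape[0]
        return EpochSet(data, fs, (-0.5, 2.5), [f"c{i}" for i in range(data.shape[1])],
                        item_labels=np.zeros(n, int) if labels is None else labels)

    def test_identical_epochs_average_to_themselves(self):
        rngv = np.random.default_rng(0)
        one = rngv.standard_normal((1, 2, 768))
        es = self._epochs(np.repeat(one, 2, axis=0))
        avg = average_repetitions(es, post_band=None)
        np.testing.assert_allclose(avg.data[0], one[0])

    def test_missing_labels_rejected(self):
        es = self._epochs(np.zeros((4, 1, 768)))
        es.item_labels = None
        with pytest.raises(InvalidInputError):
            average_repetitions(es, post_band=None)

    def test_hundred_reps_reduce_noise_tenfold(self, rng):
        signal = np.sin(2 * np.pi * 5 * np.arange(768) / 256.0)
        noise = rng.standard_normal((100, 2, 768))
        es = self._epochs(signal + noise)
        avg = average_repetitions(es, post_band=None)
        resid = avg.data[0] - signal
        ratio = noise.std() / resid.std()
        assert 8 < ratio < 12

    def test_post_average_band_is_1_to_15(self, rng):
        es = self._epochs(rng.standard_normal((20, 2, 768)))
        avg = average_repetitions(es)  # default 1-15 Hz
        f, p = sps.welch(avg.data, fs=256.0, nperseg=256, axis=-1)
        pm = p.mean(axis=(0, 1))
        in_band = pm[(f >= 2) & (f <= 14)].mean()
        out_band = pm[f >= 25].mean()
        assert 10 * np.log10(in_band / out_band) > 20


class TestBaselineNormalize:
    def _resp(self, data):
        return AveragedResponse(data, 256.0, (-0.5, 2.5),
                                [f"c{i}" for i in range(data.shape[1])],
                                item_labels=np.arange(data.shape[0]))

    def test_pooled_baseline_statistics(self, rng):
        data = rng.normal(3.0, 2.0, size=(5, 4, 768))
        out = baseline_normalize(self._resp(data))
        base = out.data[:, :, :128]
        assert abs(base.mean()) < 0.01
        assert abs(base.std() - 1) < 0.01

    def test_single_scalar_preserves_channel_ratios(self, rng):
        data = rng.normal(0.0, 1.0, size=(3, 2, 768))
        data[:, 1] *= 5.0  # channel 1 five times stronger
        ratio_in = data[:, 1].std() / data[:, 0].std()
        out = baseline_normalize(self._resp(data))
        ratio_out = out.data[:, 1].std(ddof=0) / out.data[:, 0].std(ddof=0)
        assert ratio_out == pytest.approx(ratio_in, rel=1e-9)

    def test_constant_baseline_rejected(self):
        data = np.zeros((2, 2, 768))
        data[:, :, 200:] = 5.0
        with pytest.raises(DegenerateInputError):
            baseline_normalize(self._resp(data))

    def test_idempotent(self, rng):
        out1 = baseline_normalize(self._resp(rng.standard_normal((4, 3, 768))))
        out2 = baseline_normalize(out1)
        np.testing.assert_allclose(out2.data, out1.data, atol=1e-10)

    def test_commutes_with_channel_reordering(self, rng):
        data = rng.standard_normal((3, 4, 768))
        resp = self._resp(data)
        out = baseline_normalize(resp)
        perm = [2, 0, 3, 1]
        resp_p = AveragedResponse(data[:, perm], 256.0, (-0.5, 2.5),
                                  [f"c{i}" for i in perm],
                                  item_labels=np.arange(3))
        out_p = baseline_normalize(resp_p)
        np.testing.assert_allclose(out_p.data, out.data[:, perm])


class TestAlphaPower:
    def _epochs(self, data, fs=256.0):
        return EpochSet(data, fs, (-0.5, 2.5), ["Pz", "POz"])

    def test_pure_10hz_band_power_matches_parseval(self):
        fs = 256.0
        amp = 2.0
        t = np.arange(768) / fs
        x = amp * np.sin(2 * np.pi * 10 * t)
        es = self._epochs(np.tile(x, (3, 2, 1)))
        res = alpha_power(es)
        # integrated PSD over the band must carry the sinusoid power A^2/2
        f = np.fft.rfftfreq(256, 1 / fs)
        band_width_bins = ((f >= 8) & (f <= 12)).sum()
        integrated = res.power * band_width_bins * (f[1] - f[0])
        assert integrated == pytest.approx(amp**2 / 2, rel=0.05)

    def test_dc_signal_has_negligible_alpha(self):
        es = self._epochs(np.full((2, 2, 768), 3.0))
        ref = self._epochs(np.tile(np.sin(2 * np.pi * 10 * np.arange(768) / 256.0),
                                   (2, 2, 1)))
        assert alpha_power(es).power < alpha_power(ref).power * 1e-4

    def test_missing_site_named_in_error(self):
        es = EpochSet(np.zeros((1, 1, 768)), 256.0, (-0.5, 2.5), ["Cz"])
        with pytest.raises(InvalidInputError, match="Pz"):
            alpha_power(es)


def test_full_chain_confines_spectrum_to_averaging_band(rng):
    """Noise through filter -> resample -> epoch -> average -> 1-15 Hz."""
    fs0, fs1 = 2048.0, 256.0
    cont = rng.standard_normal((2, int(30 * fs0)))
    filt = bandpass_fir(cont, 1.0, 57.0, fs0)
    down = resample(filt, fs0, fs1)
    onsets = (np.arange(8) * 3.2 * fs1 + fs1).astype(int)
    es = epoch(down, onsets, fs1, ["a", "b"], item_labels=np.zeros(8, int))
    avg = average_repetitions(es)
    f, p = sps.welch(avg.data, fs=fs1, nperseg=256, axis=-1)
    pm = p.mean(axis=(0, 1))
    in_band = pm[(f >= 2) & (f <= 14)].mean()
    out_band = pm[f >= 25].mean()
    assert 10 * np.log10(in_band / out_band) > 20
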