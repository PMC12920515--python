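import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from envtrf.errors import InvalidInputError, InvalidParameterError
from envtrf.stats import (
    ComponentWindow,
    compare_gfp,
    fdr_bh,
    find_clusters,
    gfp,
    gfp_vs_baseline,
    label_clusters,
    paired_t,
    paired_t_series,
    topographic_dominance,
    window_amplitude,
)
from envtrf.trf import LagSpec, TRFModel


def _model(W, subject="", condition="", fs=256.0):
    # lag grid starting at -100 ms with exactly W.shape[1] lags
    lag0 = int(np.floor(-100 / 1000 * fs))
    t_max = (lag0 + W.shape[1] - 1) / fs * 1000
    spec = LagSpec(-100, t_max, fs)
    labels = [f"c{i}" for i in range(W.shape[0])]
    return TRFModel(W, np.zeros(W.shape[0]), spec, 1.0, labels, condition, subject)


class TestGFP:
    def test_spatially_constant_weights_give_zero(self):
        g = gfp(_model(np.full((8, 26), 3.0)))
        np.testing.assert_allclose(g.values, 0.0)

    def test_two_channel_plus_minus_one(self):
        W = np.zeros((2, 26))
        W[0, 5], W[1, 5] = 1.0, -1.0
        assert gfp(_model(W)).values[5] == pytest.approx(1.0)

    def test_matches_per_lag_spatial_sd_oracle(self, rng):
        W = rng.standard_normal((64, 181))
        g = gfp(_model(W, fs=256.0))
        oracle = np.array([np.sqrt(np.mean((W[:, j] - W[:, j].mean()) ** 2))
                           for j in range(181)])
        np.testing.assert_allclose(g.values, oracle, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            gfp(_model(np.zeros((1, 26))))


class TestPairedT:
    def test_identical_samples(self):
        t, p, df = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert (t, p, df) == (0.0, 1.0, 2)

    def test_hand_computed_example(self):
        # d = [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        t, p, df = paired_t([2.0, 4, 6], [1.0, 2, 3])
        assert t == pytest.approx(3.4641016, abs=1e-6)
        assert df == 2
        assert 0.05 < p < 0.1

    def test_zero_variance_nonzero_mean_is_infinite(self):
        t, p, _ = paired_t([2.0, 2, 2], [1.0, 1, 1])
        assert np.isinf(t) and p == 0.0

    def test_df_is_n_minus_one(self, rng):
        _, _, df = paired_t(rng.random(50), rng.random(50))
        assert df == 49


class TestFdrBH:
    def test_all_four_significant(self):
        q, mask = fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert mask.all()

    def test_all_ones(self):
        q, mask = fdr_bh([1.0, 1.0, 1.0], alpha=0.05)
        assert not mask.any() and np.allclose(q, 1.0)

    def test_single_p(self):
        _, mask = fdr_bh([0.04], alpha=0.05)
        assert mask.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            fdr_bh([0.5, 1.5])

    def test_never_more_discoveries_than_uncorrected(self, rng):
        for _ in range(20):
            p = rng.random(30)
            _, mask = fdr_bh(p, alpha=0.05)
            assert mask.sum() <= (p < 0.05).sum()

    def test_q_at_least_p(self, rng):
        p = rng.random(40)
        q, _ = fdr_bh(p)
        assert np.all(q >= p - 1e-12)


class TestFindClusters:
    def test_two_runs(self):
        times = np.arange(5.0)
        wins = find_clusters([False, True, True, False, True], times)
        assert len(wins) == 2
        assert (wins[0].t_start, wins[0].t_end) == (1.0, 2.0)

    def test_all_false_gives_empty(self):
        assert find_clusters(np.zeros(10, bool), np.arange(10.0)) == []

    def test_min_length_filter(self):
        wins = find_clusters([True, False, True, True], np.arange(4.0), min_len=2)
        assert len(wins) == 1 and wins[0].t_start == 2.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_clusters_partition_true_entries(self, mask):
        times = np.arange(len(mask), dtype=float)
        wins = find_clusters(mask, times)
        covered = np.zeros(len(mask), bool)
        for w in wins:
            covered |= (times >= w.t_start) & (times <= w.t_end)
        np.testing.assert_array_equal(covered, np.asarray(mask))

    def test_canonical_labels(self):
        wins = [ComponentWindow("cluster_0", 80, 103), ComponentWindow("cluster_1", 376, 408)]
        names = [w.name for w in label_clusters(wins)]
        assert names == ["N1_TRF", "P400_TRF"]


class TestWindowAmplitude:
    def test_constant_weights_mean(self):
        W = np.full((3, 181), 2.5)
        amp = window_amplitude(_model(W), ComponentWindow("P2_TRF", 131, 185))
        assert amp.value == pytest.approx(2.5)

    def test_peak_mode_takes_signed_extremum(self):
        W = np.zeros((2, 181))
        spec_times = _model(W).lag_spec.times_ms
        tri = np.clip(3 - np.abs(spec_times - 160) / 10, 0, None)
        W[:] = tri
        amp = window_amplitude(_model(W), ComponentWindow("P2_TRF", 131, 185), mode="peak")
        assert amp.value == pytest.approx(3.0, abs=0.2)

    def test_n1_peak_uses_minimum(self):
        W = np.zeros((2, 181))
        model = _model(W)
        mask = (model.lag_spec.times_ms >= 80) & (model.lag_spec.times_ms <= 103)
        W[:, mask] = -2.0
        amp = window_amplitude(model, ComponentWindow("N1_TRF", 80, 103), mode="peak")
        assert amp.value == pytest.approx(-2.0)

    def test_missing_channel_rejected(self):
        with pytest.raises(InvalidInputError):
            window_amplitude(_model(np.zeros((2, 181))),
                             ComponentWindow("P2_TRF", 131, 185), channels=["Cz"])


class TestTopographicDominance:
    def test_identical_conditions_give_zero_t(self, rng):
        models = [_model(rng.standard_normal((8, 181)), subject=f"s{i}") for i in range(6)]
        res = topographic_dominance(models, models, ComponentWindow("P2_TRF", 131, 185))
        np.testing.assert_array_equal(res.t_values, 0.0)
        assert not res.sig_mask.any()

    def test_injected_channel_effect_detected(self, rng):
        # +2 sd shift at channel 5 only: that channel flags, others mostly not
        n_subj, n_ch = 30, 12
        win = ComponentWindow("P2_TRF", 131, 185)
        hits = np.zeros(n_ch)
        n_sims = 30
        for _ in range(n_sims):
            shifted = rng.standard_normal((n_subj, n_ch, 181))
            shifted[:, 5, :] += 2.0
            ms_a = [_model(w) for w in shifted]
            ms_b = [_model(w) for w in rng.standard_normal((n_subj, n_ch, 181))]
            res = topographic_dominance(ms_a, ms_b, win)
            hits += res.sig_mask
        assert hits[5] / n_sims > 0.9
        others = np.delete(hits, 5) / n_sims
        assert others.mean() <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (n_sims * (n_ch - 1)))

    def test_unpaired_subjects_rejected(self, rng):
        models = [_model(rng.standard_normal((4, 181))) for _ in range(3)]
        with pytest.raises(InvalidInputError):
            topographic_dominance(models, models[:2], ComponentWindow("P2_TRF", 131, 185))


class TestGfpVsBaseline:
    def test_constant_gfp_gives_zero_t(self):
        times = np.linspace(-100, 600, 181)
        g = np.tile(np.full(181, 2.0), (10, 1)) * np.arange(1, 11)[:, None]
        res = gfp_vs_baseline(g, times)
        np.testing.assert_array_equal(res.t_values, 0.0)

    def test_post_onset_bump_detected(self, rng):
        times = np.linspace(-100, 600, 181)
        bump = np.exp(-((times - 300) ** 2) / (2 * 30**2))
        g = 1.0 + 0.05 * rng.standard_normal((50, 181)) + 0.5 * bump
        res = gfp_vs_baseline(np.abs(g), times)
        bump_lags = (times > 250) & (times < 350)
        assert res.sig_mask[bump_lags].mean() > 0.9

    def test_missing_baseline_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            gfp_vs_baseline(np.abs(rng.standard_normal((5, 50))),
                            np.linspace(10, 600, 50))


def test_compare_gfp_detects_planted_condition_difference(rng):
    times = np.linspace(-100, 600, 181)
    bump = np.exp(-((times - 390) ** 2) / (2 * 30**2))
    a = 1 + 0.1 * rng.standard_normal((40, 181))
    b = a + 0.5 * bump + 0.05 * rng.standard_normal((40, 181))
    res = compare_gfp(b, a, times)
    window = (times >= 350) & (times <= 430)
    assert res.sig_mask[window].mean() > 0.9
    assert res.t_values[window].mean() > 0
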