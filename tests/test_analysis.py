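import numpy as np
import pytest

from vqent.analysis import (
    channel_relevance,
    cluster_permutation_test,
    features_from_courses,
    incremental_channel_accuracy,
    lda_cv_accuracy,
    trial_similarity,
    tune_grid,
)
from vqent.core_io import default_montage


def ring_montage(n=4, k=2):
    names = [f"ch{i}" for i in range(n)]
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pos = {nm: (np.cos(a), np.sin(a)) for nm, a in zip(names, ang)}
    return default_montage(names, positions=pos, n_neighbors=k)


class TestFeatures:
    def test_flattening_shape(self, rng):
        x = rng.standard_normal((5, 2, 11))
        assert features_from_courses(x).shape == (5, 22)
        assert features_from_courses(x, channels=[1]).shape == (5, 11)

    def test_window_interval_selection(self, rng):
        x = rng.standard_normal((5, 1, 10))
        t = np.linspace(0.0, 0.9, 10)
        feats = features_from_courses(x, time_axis=t, window_interval=(0.3, 0.6))
        assert feats.shape == (5, 3)

    def test_nan_imputed_with_feature_median(self):
        x = np.arange(12.0).reshape(4, 1, 3)
        x[1, 0, 2] = np.nan
        feats = features_from_courses(x)
        # medians of column 2 over remaining trials: 2, 8, 11 -> 8
        assert feats[1, 2] == 8.0

    def test_empty_channel_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            features_from_courses(rng.standard_normal((4, 2, 3)), channels=[])


class TestLdaAccuracy:
    def test_separable_clusters_perfect(self, rng):
        a = rng.normal(0.0, 1.0, size=(30, 4))
        b = rng.normal(10.0, 1.0, size=(30, 4))
        feats = np.vstack([a, b])
        labels = ["left"] * 30 + ["right"] * 30
        acc, sd, folds = lda_cv_accuracy(feats, labels, seed=0)
        assert acc == 100.0
        assert len(folds) == 10

    def test_shuffled_labels_near_chance(self, rng):
        feats = rng.standard_normal((100, 5))
        labels = np.array(["left", "right"] * 50)
        accs = []
        for s in range(8):
            shuffled = labels.copy()
            np.random.default_rng(s).shuffle(shuffled)
            accs.append(lda_cv_accuracy(feats, shuffled, seed=0)[0])
        assert abs(np.mean(accs) - 50.0) < 6.0

    def test_deterministic_and_column_order_invariant(self, rng):
        feats = rng.standard_normal((40, 6))
        labels = ["left", "right"] * 20
        a1 = lda_cv_accuracy(feats, labels, seed=3)
        a2 = lda_cv_accuracy(feats, labels, seed=3)
        assert a1[0] == a2[0]
        perm = rng.permutation(6)
        a3 = lda_cv_accuracy(feats[:, perm], labels, seed=3)
        assert a3[0] == pytest.approx(a1[0], abs=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            lda_cv_accuracy(rng.standard_normal((20, 3)), ["left"] * 20)


class TestTrialSimilarity:
    def test_identical_courses_all_ones(self, rng):
        c = rng.standard_normal((10, 1, 6))
        labels = ["left"] * 5 + ["right"] * 5
        sim = trial_similarity({"a": c, "b": c.copy()}, ("a", "b"), labels)
        assert sim.values.shape == (5, 5)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        # same trial, same course: exact 1 everywhere on matching indices
        assert (sim.values <= 1.0 + 1e-12).all() and (sim.values > 0).all()

    def test_known_distance_maps_to_exp_minus_one(self):
        # construct courses where ||dH||^2 equals sigma2_X exactly
        n, w = 4, 2
        a = np.zeros((n, 1, w))
        b = np.zeros((n, 1, w))
        b[:, 0, 0] = 1.0  # constant offset course
        labels = ["left", "left", "right", "right"]
        sim = trial_similarity({"a": a, "b": b}, ("a", "b"), labels)
        off_diag = sim.values[~np.eye(2, dtype=bool)]
        expected = np.exp(-1.0 / sim.sigma2_X)
        np.testing.assert_allclose(off_diag, expected)

    def test_zero_variance_rejected(self):
        c = np.zeros((4, 1, 3))
        with pytest.raises(ValueError):
            trial_similarity({"a": c, "b": c}, ("a", "b"), ["left", "left", "right", "right"])


class TestChannelRelevance:
    def test_identical_class_means_zero_weight(self, rng):
        x = rng.standard_normal((20, 3, 5))
        x[:, 1, :] = 1.0  # identical across trials -> identical class means
        rel = channel_relevance(x, ["left", "right"] * 10)
        assert rel.weights[1] == 0.0

    def test_permutation_invariance(self, rng):
        x = rng.standard_normal((16, 3, 5))
        labels = np.array(["left", "right"] * 8)
        rel1 = channel_relevance(x, labels)
        perm = rng.permutation(16)
        rel2 = channel_relevance(x[perm], labels[perm])
        np.testing.assert_allclose(rel1.weights, rel2.weights, atol=1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_relevance(rng.standard_normal((4, 2, 3)), ["left"] * 4)

    def test_informative_channel_ranks_first(self, rng):
        x = rng.standard_normal((30, 4, 6)) * 0.1
        labels = np.array(["left", "right"] * 15)
        x[labels == "right", 2, :] += 2.0
        rel = channel_relevance(x, labels)
        assert rel.ranking[0] == 2


class TestIncrementalAccuracy:
    def test_curve_length_and_ranking_subset(self, rng):
        x = rng.standard_normal((40, 5, 4))
        labels = np.array(["left", "right"] * 20)
        x[labels == "left", 0, :] += 3.0
        rel = channel_relevance(x, labels)
        curve = incremental_channel_accuracy(x, labels, rel, seed=0)
        assert len(curve) == 5
        restricted = incremental_channel_accuracy(
            x, labels, rel, channels=[0, 1], seed=0
        )
        assert len(restricted) == 2
        assert restricted[0] > 80.0  # informative channel first


class TestTuneGrid:
    def test_small_grid_bookkeeping_and_argmax(self, small_trials_bp):
        from vqent.preprocess import extract_window

        ts = extract_window(small_trials_bp, (2.5, 4.5))
        res = tune_grid(
            ts, taus=(1.0, 2.0), Ms=(2,), rhos=(0.2, 0.5),
            estimator="sampen", seed=0, folds=4,
        )
        assert len(res.grid) == 4
        assert res.best in res.grid
        assert res.best_accuracy == res.accuracy_mean.max()
        # argmax property: best accuracy >= every evaluated configuration
        assert (res.best_accuracy >= res.accuracy_mean - 1e-9).all()

    def test_vqent_reports_codebook_size(self, small_trials_bp):
        from vqent.preprocess import extract_window

        ts = extract_window(small_trials_bp, (2.5, 4.5))
        res = tune_grid(
            ts, taus=(1.0,), Ms=(2,), rhos=(0.3,),
            estimator="vqent", seed=0, folds=4,
        )
        assert res.q_prime_median is not None and res.q_prime_median >= 1


class TestClusterPermutation:
    def test_programmed_effect_detected_in_right_place(self, rng):
        mont = ring_montage(4)
        x = rng.standard_normal((24, 4, 12))
        labels = np.array(["left", "right"] * 12)
        x[labels == "right", 1, 4:8] += 1.5
        res = cluster_permutation_test(x, labels, mont, n_permutations=500, seed=0)
        sig = res.significant(0.05)
        assert sig, "programmed effect not detected"
        assert 1 in sig[0]["channels"]
        assert set(sig[0]["windows"]) & {4, 5, 6, 7}

    def test_determinism(self, rng):
        mont = ring_montage(4)
        x = rng.standard_normal((20, 4, 10))
        labels = ["left", "right"] * 10
        r1 = cluster_permutation_test(x, labels, mont, n_permutations=300, seed=5)
        r2 = cluster_permutation_test(x, labels, mont, n_permutations=300, seed=5)
        assert [c["p_value"] for c in r1.clusters] == [c["p_value"] for c in r2.clusters]

    def test_too_few_trials_rejected(self, rng):
        mont = ring_montage(4)
        x = rng.standard_normal((6, 4, 10))
        with pytest.raises(ValueError, match="5 trials"):
            cluster_permutation_test(x, ["left"] * 3 + ["right"] * 3, mont)

    def test_t_map_matches_direct_computation(self, rng):
        from scipy import stats as sps

        mont = ring_montage(3, k=1)
        x = rng.standard_normal((14, 3, 6))
        labels = np.array(["left"] * 7 + ["right"] * 7)
        res = cluster_permutation_test(x, labels, mont, n_permutations=200, seed=0)
        direct = sps.ttest_ind(
            x[labels == "left"], x[labels == "right"], axis=0
        ).statistic
        np.testing.assert_allclose(res.t_obs, direct, atol=1e-8)
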