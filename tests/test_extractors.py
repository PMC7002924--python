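"""The six importance estimators: constructions with known answers,
shared-contract invariants, and repeated-fit averaging."""

import warnings

import numpy as np
import pytest

from mdimportance.extractors import (
    ExtractorSpec,
    ae_lrp_importance,
    kl_importance,
    mlp_lrp_importance,
    pca_importance,
    rbm_lrp_importance,
    rf_importance,
    run_repeated,
)
from mdimportance.extractors import _j_max
from mdimportance.featurization import LabelSet, minmax_scale
from tests.conftest import make_feature_matrix


class TestPcaImportance:
    def test_eigengap_criterion_on_stated_spectrum(self):
        # lambda_1/lambda_2 = 0.90/0.05 = 18 >= 10 -> one component
        assert _j_max(np.array([0.90, 0.05, 0.03, 0.02]), ("eigengap", 10.0)) == 1
        assert _j_max(np.array([0.4, 0.3, 0.2, 0.1]), ("eigengap", 10.0)) == 4

    def test_cumulative_variance_criterion(self):
        lambdas = np.array([0.5, 0.3, 0.15, 0.05])
        assert _j_max(lambdas, ("cumulative_variance", 0.75)) == 2
        assert _j_max(lambdas, ("cumulative_variance", 0.95)) == 3

    def test_two_cluster_feature_dominates(self, rng):
        x0 = np.repeat([1.0, -1.0], 50)
        X = rng.normal(scale=1e-3, size=(100, 5))
        X[:, 0] = x0
        prof = pca_importance(make_feature_matrix(X, scaled=True), ("fixed", 1))
        assert prof.per_feature.argmax() == 0
        assert np.isclose(prof.per_feature.max(), 1.0)

    def test_duplicated_columns_equal_importance(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 2] = X[:, 0]
        prof = pca_importance(make_feature_matrix(X, scaled=True), ("fixed", 2))
        np.testing.assert_allclose(prof.per_feature[0], prof.per_feature[2], atol=1e-10)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="samples"):
            pca_importance(make_feature_matrix(np.ones((1, 3))))


class TestKlImportance:
    def test_symmetric_kl_two_bin_worked_value(self, rng):
        # direct evaluation of 0.5*KL(P||Q)+0.5*KL(Q||P) for P=(.5,.5),
        # Q=(.9,.1): 0.5*(0.5 ln(5/9)+0.5 ln 5) + 0.5*(0.9 ln(9/5)+0.1 ln .2)
        p, q = np.array([0.5, 0.5]), np.array([0.9, 0.1])
        expected = 0.5 * (p * np.log(p / q)).sum() + 0.5 * (q * np.log(q / p)).sum()
        assert np.isclose(expected, 0.4394, atol=2e-4)
        # realize those histograms with 2 bins: state 0 has 50/50 low/high
        # samples, state 1 has 90/10, bin width fraction 0.5
        values = np.concatenate([
            np.repeat([0.1, 0.9], [50, 50]),
            np.repeat([0.1, 0.9], [90, 10]),
        ])[:, None]
        labels = LabelSet(np.repeat([0, 1], 100), 2)
        prof = kl_importance(make_feature_matrix(values), labels, bin_width_fraction=0.5)
        # single feature normalizes to 1; the raw divergence sits per state
        np.testing.assert_allclose(prof.per_feature, [1.0])

    def test_identical_distributions_give_zero(self, rng):
        X = np.tile(rng.uniform(size=50), 2)[:, None]
        labels = LabelSet(np.repeat([0, 1], 50), 2)
        prof = kl_importance(make_feature_matrix(X), labels)
        assert prof.all_zero
        np.testing.assert_allclose(prof.per_feature, [0.0], atol=1e-6)

    def test_disjoint_supports_attain_maximum(self, rng):
        n = 100
        X = rng.uniform(size=(2 * n, 3))
        X[:n, 0] = rng.uniform(0.0, 0.4, n)
        X[n:, 0] = rng.uniform(0.6, 1.0, n)
        labels = LabelSet(np.repeat([0, 1], n), 2)
        prof = kl_importance(make_feature_matrix(X, scaled=True), labels)
        assert prof.per_feature.argmax() == 0
        assert np.isclose(prof.per_feature[0], 1.0)

    def test_separation_monotone_in_distance(self, rng):
        # two Gaussian states moving apart at fixed variance
        prev = -1.0
        for sep in [0.0, 0.5, 1.0, 2.0, 4.0]:
            a = rng.normal(0, 1, 400)
            b = rng.normal(sep, 1, 400)
            values = np.concatenate([a, b])[:, None]
            labels = LabelSet(np.repeat([0, 1], 400), 2)
            prof = kl_importance(
                make_feature_matrix(values), labels, bin_width_fraction=0.05
            )
            raw = prof.per_state[0, 0]
            assert raw >= prev - 1e-9
            prev = raw

    def test_empty_state_rejected(self, rng):
        with pytest.raises(ValueError, match="empty state"):
            kl_importance(
                make_feature_matrix(rng.uniform(size=(4, 2))), LabelSet([0, 0, 1, 1], 3)
            )


class TestRfImportance:
    def test_label_feature_dominates(self, rng):
        y = rng.integers(0, 2, 300)
        X = rng.uniform(size=(300, 5))
        X[:, 2] = y
        prof = rf_importance(make_feature_matrix(X, scaled=True), LabelSet(y, 2), seed=0)
        assert prof.per_feature.argmax() == 2
        assert np.isclose(prof.per_feature[2], 1.0)

    def test_one_vs_rest_produces_per_state_rows(self, rng):
        y = rng.integers(0, 3, 300)
        X = rng.uniform(size=(300, 4))
        for s in range(3):
            X[y == s, s] += 2.0
        prof = rf_importance(
            make_feature_matrix(X), LabelSet(y, 3), mode="one_vs_rest", seed=0
        )
        assert prof.per_state.shape == (3, 4)
        for s in range(3):
            assert prof.per_state[s].argmax() == s

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rf_importance(make_feature_matrix(rng.uniform(size=(10, 2))), LabelSet(np.zeros(10, dtype=int), 1))


class TestMlpLrpImportance:
    def test_informative_feature_dominates_across_seeds(self, rng):
        # two features, perfectly separable in the first
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.uniform(0, 1, (n, 2))
        X[:, 0] = np.where(y == 0, rng.uniform(0, 0.25, n), rng.uniform(0.75, 1, n))
        fm = make_feature_matrix(X, scaled=True)
        labels = LabelSet(y, 2)
        for seed in range(10):
            prof = mlp_lrp_importance(fm, labels, hidden_layers=(10,), max_iter=2000, seed=seed)
            assert np.isclose(prof.per_feature[0], 1.0)
            # the bounded-input rule leaves a weight-magnitude baseline on
            # unused inputs, so the noise feature stays low but not zero
            assert prof.per_feature[1] < 0.3

    def test_per_frame_shape_and_per_state_rows(self, two_cluster_data):
        fm, labels = two_cluster_data
        prof = mlp_lrp_importance(fm, labels, hidden_layers=(10,), seed=0)
        assert prof.per_frame.shape == (fm.n_samples, fm.n_features)
        assert prof.per_state.shape == (2, fm.n_features)

    def test_requires_scaled_input(self, rng):
        fm = make_feature_matrix(rng.normal(size=(50, 3)) * 5)
        with pytest.raises(ValueError, match="scaled"):
            mlp_lrp_importance(fm, LabelSet(rng.integers(0, 2, 50), 2))

    def test_shuffled_labels_give_chance_cv_accuracy(self, two_cluster_data, rng):
        fm, labels = two_cluster_data
        shuffled = LabelSet(rng.permutation(labels.state_index), 2)
        prof = run_repeated(
            ExtractorSpec("MLP", {"hidden_layers": (10,), "max_iter": 60}),
            fm,
            shuffled,
            n_iterations=1,
            n_folds=3,
            seed=0,
        )
        assert abs(prof.model_score - 0.5) < 0.1


class TestAeLrpImportance:
    def test_dominant_variance_feature_found(self, rng):
        # only feature 0 varies; the others are zero, so under the z+
        # input rule they can receive no relevance at all
        X = np.zeros((200, 5))
        X[:, 0] = rng.uniform(0, 1, 200)
        prof = ae_lrp_importance(make_feature_matrix(X), hidden_layers=(3,), seed=0, epochs=300)
        assert prof.per_feature.argmax() == 0
        np.testing.assert_allclose(prof.per_feature[1:], 0.0, atol=1e-12)
        assert prof.per_feature.shape == (5,)

    def test_asymmetric_hidden_layers_rejected(self, rng):
        fm = make_feature_matrix(rng.uniform(size=(20, 4)), scaled=True)
        with pytest.raises(ValueError, match="symmetric"):
            ae_lrp_importance(fm, hidden_layers=(10, 5))

    def test_seed_determinism(self, rng):
        fm = make_feature_matrix(rng.uniform(size=(60, 4)), scaled=True)
        a = ae_lrp_importance(fm, hidden_layers=(3,), seed=5, epochs=50)
        b = ae_lrp_importance(fm, hidden_layers=(3,), seed=5, epochs=50)
        np.testing.assert_array_equal(a.per_feature, b.per_feature)


class TestRbmLrpImportance:
    def test_out_of_range_input_rejected(self, rng):
        fm = make_feature_matrix(rng.normal(size=(30, 3)) * 4)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            rbm_lrp_importance(fm)

    def test_high_learning_rate_warns(self, rng):
        fm = make_feature_matrix(rng.uniform(size=(40, 3)), scaled=True)
        with pytest.warns(UserWarning, match="learning rate"):
            rbm_lrp_importance(fm, learning_rate=1.0, n_iter=2)

    def test_separating_feature_in_top_decile(self, rng):
        n = 150
        X = rng.uniform(0.4, 0.6, size=(2 * n, 20))
        X[:n, 0] = rng.uniform(0.0, 0.1, n)
        X[n:, 0] = rng.uniform(0.9, 1.0, n)
        fm = make_feature_matrix(X, prescaled=True)
        hits = 0
        for seed in range(10):
            prof = rbm_lrp_importance(fm, n_hidden=5, seed=seed)
            rank = (prof.per_feature >= prof.per_feature[0]).sum()
            hits += rank <= 2  # top 10% of 20 features
        assert hits >= 8


class TestSharedContracts:
    @pytest.fixture()
    def labeled_data(self, rng):
        n = 120
        y = rng.integers(0, 2, n)
        X = rng.uniform(size=(n, 6))
        X[:, 1] = np.where(y == 0, rng.uniform(0, 0.3, n), rng.uniform(0.7, 1, n))
        return minmax_scale(make_feature_matrix(X)), LabelSet(y, 2)

    @pytest.mark.parametrize("method", ["PCA", "KL", "RF", "MLP", "AE", "RBM"])
    def test_profile_bounds_and_normalization(self, labeled_data, method):
        fm, labels = labeled_data
        spec = ExtractorSpec(method, {"hidden_layers": (5,)} if method in ("MLP", "AE") else {})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = spec.run(fm, labels if method in ("KL", "RF", "MLP") else None, seed=0)
        assert np.all(np.isfinite(prof.per_feature))
        assert prof.per_feature.max() <= 1.0 + 1e-12
        assert np.isclose(prof.per_feature.max(), 1.0) or prof.all_zero

    @pytest.mark.parametrize("method", ["PCA", "KL"])
    def test_feature_permutation_equivariance_exact(self, labeled_data, method):
        fm, labels = labeled_data
        spec = ExtractorSpec(method)
        base = spec.run(fm, labels if method == "KL" else None, seed=0).per_feature
        perm = np.random.default_rng(1).permutation(fm.n_features)
        fm_p = fm.subset_features(perm)
        permuted = spec.run(fm_p, labels if method == "KL" else None, seed=0).per_feature
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)

    def test_duplicated_feature_symmetry_pca_kl(self, labeled_data):
        fm, labels = labeled_data
        values = np.c_[fm.values, fm.values[:, 1]]
        dup = make_feature_matrix(values)
        dup_kl = kl_importance(dup, labels)
        np.testing.assert_allclose(dup_kl.per_feature[1], dup_kl.per_feature[-1], atol=1e-10)
        dup_pca = pca_importance(dup, ("fixed", 3))
        np.testing.assert_allclose(dup_pca.per_feature[1], dup_pca.per_feature[-1], atol=1e-10)


class TestRunRepeated:
    def test_single_iteration_single_fold_structure(self, two_cluster_data):
        fm, labels = two_cluster_data
        prof = run_repeated(ExtractorSpec("KL"), fm, labels, n_iterations=1, n_folds=2, seed=0)
        assert prof.n_iterations == 1
        assert prof.std.shape == (fm.n_features,)

    def test_kl_deterministic_on_fixed_folds(self, two_cluster_data):
        fm, labels = two_cluster_data
        a = run_repeated(ExtractorSpec("KL"), fm, labels, n_iterations=2, n_folds=3, seed=4)
        b = run_repeated(ExtractorSpec("KL"), fm, labels, n_iterations=2, n_folds=3, seed=4)
        np.testing.assert_array_equal(a.per_feature, b.per_feature)

    def test_rf_mean_profile_consistent_with_single_run(self, two_cluster_data):
        fm, labels = two_cluster_data
        single = rf_importance(fm, labels, n_estimators=200, seed=0)
        repeated = run_repeated(
            ExtractorSpec("RF", {"n_estimators": 200}), fm, labels, n_iterations=5, n_folds=3, seed=0
        )
        tol = 2.0 * np.maximum(repeated.std, 0.05)
        assert np.all(np.abs(repeated.per_feature - single.per_feature) <= tol)
        assert repeated.model_score > 0.9  # separable data

    def test_supervised_without_labels_rejected(self, two_cluster_data):
        fm, _ = two_cluster_data
        with pytest.raises(ValueError, match="supervised"):
            ExtractorSpec("RF").run(fm, None)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            ExtractorSpec("SVM")
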