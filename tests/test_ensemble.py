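"""Balancing, the three classifiers, fusion, and the fitted model."""

import math

import numpy as np
import pandas as pd
import pytest

from neurovibe import ensemble as ens
from neurovibe.config import PipelineConfig


@pytest.fixture(scope="module")
def separable_2d():
    rng = np.random.default_rng(10)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 0.5, (n, 2))
    X[y == 1] += 3.0
    return X, y


class TestSmote:
    def test_identical_minority_points_reproduce_themselves(self):
        X = np.tile([2.0, 5.0], (6, 1))
        out = ens.smote_oversample(X, k=3, n_new=4, seed=0)
        assert np.allclose(out, [2.0, 5.0])

    def test_fixed_lambda_midpoint(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        out = ens.smote_oversample(X, k=1, n_new=5, seed=0, lam=0.5)
        assert np.allclose(out, [1.0, 1.0])

    def test_synthetic_rows_inside_bounding_box(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-3, 7, (20, 4))
        out = ens.smote_oversample(X, k=5, n_new=50, seed=3)
        assert np.all(out >= X.min(axis=0) - 1e-12)
        assert np.all(out <= X.max(axis=0) + 1e-12)

    def test_minority_not_larger_than_k_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            ens.smote_oversample(np.zeros((3, 2)), k=3, n_new=1)


class TestUndersample:
    def test_keep_all_is_identity(self):
        X = np.arange(10.0).reshape(5, 2)
        assert np.array_equal(ens.random_undersample(X, 1.0, 0), X)

    def test_half_keeps_exact_count_from_input(self):
        X = np.arange(20.0).reshape(10, 2)
        out = ens.random_undersample(X, 0.5, 1)
        assert out.shape == (5, 2)
        rows = {tuple(r) for r in out}
        assert rows <= {tuple(r) for r in X}

    def test_same_seed_same_subset(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        a = ens.random_undersample(X, 0.4, 7)
        b = ens.random_undersample(X, 0.4, 7)
        assert np.array_equal(a, b)


class TestBalance:
    @pytest.mark.parametrize("n0,n1", [(50, 10), (12, 40), (25, 25)])
    def test_counts_equal_within_one(self, n0, n1):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(n0 + n1, 3))
        y = np.array([0] * n0 + [1] * n1)
        Xb, yb = ens.balance_classes(X, y, smote_k=5, seed=0)
        counts = np.bincount(yb)
        assert abs(int(counts[0]) - int(counts[1])) <= 1


class TestIrf:
    def test_uniform_weights_reduce_to_plain_majority_vote(self, separable_2d):
        X, y = separable_2d
        model = ens.train_irf(X, y, n_trees=15, seed=0)
        uniform = model.with_uniform_weights()
        votes = np.stack([t.predict(X) for t in model.trees])
        plain_majority = (votes.mean(axis=0) > 0.5).astype(int)
        assert np.array_equal(uniform.predict(X), plain_majority)

    def test_single_tree_is_that_tree(self, separable_2d):
        X, y = separable_2d
        model = ens.train_irf(X, y, n_trees=1, seed=1)
        assert np.array_equal(model.predict(X), model.trees[0].predict(X))

    def test_stub_weighted_vote_by_hand(self, separable_2d):
        X, y = separable_2d
        model = ens.train_irf(X, y, n_trees=3, seed=2)

        class Stub:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.full(len(X), self.label)

        stub = ens.IRFModel([Stub(1), Stub(0), Stub(0)],
                            np.array([0.6, 0.2, 0.2]), 0)
        assert stub.predict(X[:1])[0] == 1      # 0.6 > 0.4

    def test_vote_shares_sum_to_one(self, separable_2d):
        X, y = separable_2d
        model = ens.train_irf(X, y, n_trees=20, seed=3)
        share1 = model.vote_share(X)
        assert np.all((share1 >= -1e-12) & (share1 <= 1 + 1e-12))
        assert model.weights.sum() == pytest.approx(1.0)

    def test_deterministic_given_seed(self, separable_2d):
        X, y = separable_2d
        a = ens.train_irf(X, y, n_trees=10, seed=9)
        b = ens.train_irf(X, y, n_trees=10, seed=9)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.predict(X), b.predict(X))


class TestGbm:
    def test_zero_learning_rate_stays_at_prior(self):
        X = np.linspace(0, 1, 20)[:, None]
        y = np.array([0, 1] * 10)
        model = ens.train_gbm(X, y, learning_rate=0.0, rounds=5, min_leaf=2)
        prior = y.mean()
        assert np.allclose(model.predict_proba(X), prior)

    def test_one_round_depth_one_matches_hand_gradient_step(self):
        # 4 points, perfectly split at x = 5.5; prior log-odds 0, residuals
        # +-1/2, leaf values are mean residuals, step is rho * leaf value
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        model = ens.train_gbm(X, y, learning_rate=0.1, max_leaves=2,
                              max_depth=1, min_leaf=1, rounds=1)
        assert model.init_score == pytest.approx(0.0)
        assert np.allclose(model.raw_score(X, 1),
                           [-0.05, -0.05, 0.05, 0.05])

    def test_staged_scores_reproducible_round_by_round(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        model = ens.train_gbm(X, y, rounds=10, min_leaf=2)
        full = model.raw_score(X)
        staged = np.full(len(X), model.init_score)
        for t in range(len(model.trees)):
            staged = staged + model.learning_rate * model.trees[t].predict(X)
        assert np.allclose(staged, full)

    def test_separable_data_reaches_perfect_training_accuracy(self):
        X = np.concatenate([np.linspace(0, 1, 20),
                            np.linspace(3, 4, 20)])[:, None]
        y = np.repeat([0, 1], 20)
        model = ens.train_gbm(X, y, rounds=50, min_leaf=2)
        assert (model.predict(X) == y).mean() == 1.0

    def test_leaf_cap_respected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        model = ens.train_gbm(X, y, max_leaves=4, rounds=3, min_leaf=5)
        for tree in model.trees:
            n_leaves = sum("feature" not in node for node in tree.nodes)
            assert n_leaves <= 4


class TestHybrid:
    def test_delta_zero_is_pure_svm(self, separable_2d):
        X, y = separable_2d
        model = ens.train_hybrid(X, y, delta=0.0)
        _, branch, _ = model.predict_with_audit(X)
        assert set(branch) == {"svm"}

    def test_delta_infinity_is_pure_knn(self, separable_2d):
        X, y = separable_2d
        model = ens.train_hybrid(X, y, delta=np.inf)
        labels, branch, _ = model.predict_with_audit(X)
        knn_labels = model.knn.predict(X)
        assert set(branch) == {"knn"}
        assert np.array_equal(labels, knn_labels)

    def test_branch_follows_margin_threshold(self, separable_2d):
        X, y = separable_2d
        model = ens.train_hybrid(X, y, delta=0.2)
        label, branch, value = ens.hybrid_predict(model, X[0])
        assert branch == ("svm" if abs(value) > 0.2 else "knn")

    def test_knn_fraction_monotone_in_delta(self, separable_2d):
        X, y = separable_2d
        fractions = []
        sets = []
        for delta in np.arange(0.0, 1.05, 0.1):
            model = ens.train_hybrid(X, y, delta=delta)
            _, branch, _ = model.predict_with_audit(X)
            routed = frozenset(np.flatnonzero(branch == "knn"))
            sets.append(routed)
            fractions.append(len(routed) / len(X))
        assert all(a <= b for a, b in zip(sets, sets[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_k_at_least_n_rejected(self, separable_2d):
        X, y = separable_2d
        with pytest.raises(ValueError):
            ens.train_hybrid(X[:5], y[:5], k=5)


class TestWeightedVote:
    def test_single_classifier_identity(self):
        assert ens.weighted_vote([1], [1.0]) == 1
        assert ens.weighted_vote([0], [1.0]) == 0

    def test_hand_summed_shares(self):
        # votes (1, 0, 1) with weights (0.5, 0.3, 0.2): share = 0.7
        assert ens.weighted_vote([1, 0, 1], [0.5, 0.3, 0.2]) == 1

    def test_exact_tie_goes_to_normal(self):
        assert ens.weighted_vote([1, 0], [0.5, 0.5]) == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ens.weighted_vote([1, 0], [1.0])


class TestFittedEnsemble:
    def _tables(self, seed=0, n=80, shift=3.0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        beh = pd.DataFrame({
            "beh_mean": rng.normal(0, 1, n) + shift * y,
            "beh_var": rng.normal(1, 0.1, n),
            "beh_skew": rng.normal(0, 0.3, n),
            "idtw_class0": rng.normal(2, 0.5, n) + shift * y,
        })
        voi = pd.DataFrame({
            "pitch": rng.normal(150, 5, n),
            "jitter": rng.normal(0.01, 0.002, n) + 0.01 * shift * y,
            "shimmer": rng.normal(0.03, 0.005, n),
            "hnr": rng.normal(20, 2, n),
        })
        return beh, voi, y

    def test_training_rows_of_separable_fixture_predicted_back(self):
        beh, voi, y = self._tables()
        cfg = PipelineConfig(seed=0, mrfe_target_behavior=3,
                             mrfe_target_voice=3)
        model = ens.fit_neurovibenet(beh, voi, y, cfg)
        preds = ens.predict(model, beh, voi)
        assert (preds["label"].to_numpy() == y).mean() >= 0.95

    def test_refit_same_seed_identical_fusion_weights(self):
        beh, voi, y = self._tables()
        cfg = PipelineConfig(seed=4, mrfe_target_behavior=3,
                             mrfe_target_voice=3)
        m1 = ens.fit_neurovibenet(beh, voi, y, cfg)
        m2 = ens.fit_neurovibenet(beh, voi, y, cfg)
        assert np.array_equal(m1.fusion_weights, m2.fusion_weights)
        assert m1.behavior_features == m2.behavior_features

    def test_audit_fields_present(self):
        beh, voi, y = self._tables()
        cfg = PipelineConfig(seed=1, mrfe_target_behavior=3,
                             mrfe_target_voice=3)
        model = ens.fit_neurovibenet(beh, voi, y, cfg)
        preds = ens.predict(model, beh.iloc[:3], voi.iloc[:3])
        assert list(preds.columns) == ["label", "irf_vote", "gbm_vote",
                                       "hybrid_vote", "hybrid_branch",
                                       "svm_decision"]
        assert set(preds["hybrid_branch"]) <= {"svm", "knn"}

    def test_unanimous_votes_win_regardless_of_weights(self):
        beh, voi, y = self._tables()
        cfg = PipelineConfig(seed=2, mrfe_target_behavior=3,
                             mrfe_target_voice=3)
        model = ens.fit_neurovibenet(beh, voi, y, cfg)
        preds = ens.predict(model, beh, voi)
        unanimous = (preds["irf_vote"] == preds["gbm_vote"]) & \
            (preds["gbm_vote"] == preds["hybrid_vote"])
        assert (preds.loc[unanimous, "label"]
                == preds.loc[unanimous, "irf_vote"]).all()

    def test_missing_selected_feature_rejected(self):
        beh, voi, y = self._tables()
        cfg = PipelineConfig(seed=3, mrfe_target_behavior=3,
                             mrfe_target_voice=3)
        model = ens.fit_neurovibenet(beh, voi, y, cfg)
        with pytest.raises(ValueError, match="missing selected"):
            ens.predict(model, beh.drop(columns=[model.behavior_features[0]]),
                        voi)

    def test_save_load_round_trip(self, tmp_path):
        beh, voi, y = self._tables()
        cfg = PipelineConfig(seed=5, mrfe_target_behavior=3,
                             mrfe_target_voice=3)
        model = ens.fit_neurovibenet(beh, voi, y, cfg)
        model.save(tmp_path / "model")
        back = ens.EnsembleModel.load(tmp_path / "model")
        a = ens.predict(model, beh, voi)
        b = ens.predict(back, beh, voi)
        pd.testing.assert_frame_equal(a, b)
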