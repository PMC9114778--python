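"""Shrinkage LDA: splits, training-set assembly, fitting, prediction,
accuracy, and the cross-condition matrix."""

import numpy as np
import pytest

import sonomyo as so
from sonomyo.grasp_classifier import strategies_for


def _toy_problem(rng, n_per_class=12, p=5, n_classes=3, spread=2.0):
    means = rng.normal(0, spread, (n_classes, p))
    X = np.concatenate(
        [rng.normal(means[k], 1.0, (n_per_class, p)) for k in range(n_classes)]
    )
    y = np.repeat(np.arange(n_classes), n_per_class)
    return X, y


def _dense_lda_oracle(X, y, lam):
    """Brute-force Gaussian discriminant: explicit shrunk covariance,
    explicit inverse, score -0.5 (x-mu)' S^-1 (x-mu) + log prior."""
    classes = np.unique(y)
    n, p = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    Xc = X.copy()
    for i, c in enumerate(classes):
        Xc[y == c] -= means[i]
    S = Xc.T @ Xc / (n - len(classes))
    sigma = (1 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)
    inv = np.linalg.inv(sigma)
    priors = np.array([np.mean(y == c) for c in classes])

    def predict(Xt):
        scores = np.stack(
            [
                -0.5 * np.einsum("ij,jk,ik->i", Xt - m, inv, Xt - m) + np.log(pr)
                for m, pr in zip(means, priors)
            ],
            axis=1,
        )
        return classes[np.argmax(scores, axis=1)]

    return predict


class TestSplitRepeats:
    def test_static_session_splits_21_21(self, static_session_b):
        split = so.split_repeats(static_session_b, seed=3)
        train = [r for r in static_session_b if split.is_train(r)]
        test = [r for r in static_session_b if not split.is_train(r)]
        assert len(train) == 21 and len(test) == 21
        assert {id(r) for r in train} | {id(r) for r in test} == {
            id(r) for r in static_session_b
        }
        assert {id(r) for r in train} & {id(r) for r in test} == set()

    def test_deterministic_given_seed(self, static_session_b):
        s1 = so.split_repeats(static_session_b, seed=3)
        s2 = so.split_repeats(static_session_b, seed=3)
        assert s1.train_repeat == s2.train_repeat

    def test_missing_repeat_names_cell(self, static_session_b):
        broken = [r for r in static_session_b if r.repeat_index == 1 or
                  r.arm_condition.key != "Drinking Glass" or
                  r.grasp is not so.GraspLabel.REST]
        with pytest.raises(ValueError, match="Drinking Glass"):
            so.split_repeats(broken, seed=3)


class TestAssembleTrainingSet:
    def test_single_position_frame_counts(self, static_session_b):
        split = so.split_repeats(static_session_b, seed=3)
        train = [r for r in static_session_b if split.is_train(r)]
        X, y = so.assemble_training_set(
            train, so.TrainingStrategy("static_single", "Drinking Glass"),
            so.Load.LOAD_B,
        )
        # 3 grasps x 1 repeat x 57-58 frames
        assert 171 <= len(X) <= 174
        assert X.shape[1] == so.N_FEATURES
        assert set(np.unique(y)) == {0, 1, 2}

    def test_all_positions_pool_seven_times_more(self, static_session_b):
        split = so.split_repeats(static_session_b, seed=3)
        train = [r for r in static_session_b if split.is_train(r)]
        X1, _ = so.assemble_training_set(
            train, so.TrainingStrategy("static_single", "Drinking Glass"),
            so.Load.LOAD_B,
        )
        X7, _ = so.assemble_training_set(
            train, so.TrainingStrategy("static_all"), so.Load.LOAD_B
        )
        assert 7 * 171 <= len(X7) <= 7 * 174
        assert len(X7) >= 7 * len(X1) - 7  # frame-count jitter across cells

    def test_continuous_dynamic_vector_counts(self, gen_config):
        session = so.generate_session(
            so.continuous_dynamic_protocol(so.Load.LOAD_B), gen_config, seed=5
        )
        X, y = so.assemble_training_set(
            session, so.TrainingStrategy("continuous_dynamic"), so.Load.LOAD_B
        )
        per_grasp = np.bincount(y)
        assert all(460 <= c <= 462 for c in per_grasp)  # 2 repeats x 230-231

    def test_empty_selection_rejected(self, static_session_b):
        with pytest.raises(ValueError, match="no records"):
            so.assemble_training_set(
                static_session_b, so.TrainingStrategy("dynamic_all"), so.Load.LOAD_B
            )


class TestFitLda:
    def test_scalar_toy_boundary_at_midpoint(self):
        X = np.array([[0.0], [0.2], [1.0], [1.2]])
        y = np.array([0, 0, 1, 1])
        clf = so.fit_lda(X, y, shrinkage=0.0)
        assert clf.predict_features(np.array([[0.59]]))[0] == 0
        assert clf.predict_features(np.array([[0.61]]))[0] == 1

    def test_full_shrinkage_is_nearest_class_mean(self, rng):
        X, y = _toy_problem(rng, n_per_class=10, p=4)
        clf = so.fit_lda(X, y, shrinkage=1.0)
        means = np.stack([X[y == k].mean(axis=0) for k in range(3)])
        Xt = rng.normal(0, 2, (50, 4))
        nearest = np.argmin(
            ((Xt[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        assert np.array_equal(clf.predict_features(Xt), nearest)

    def test_duplicating_samples_leaves_model_unchanged(self, rng):
        X, y = _toy_problem(rng)
        c1 = so.fit_lda(X, y, shrinkage=0.3)
        c2 = so.fit_lda(np.vstack([X, X]), np.concatenate([y, y]), shrinkage=0.3)
        assert np.allclose(c1.means, c2.means)
        # covariance dof differs (n - K), so compare the decision geometry
        s1 = c1.decision_scores(X)
        s2 = c2.decision_scores(X)
        assert np.array_equal(np.argmax(s1, axis=1), np.argmax(s2, axis=1))

    def test_oracle_equivalence_on_20_random_problems(self, rng):
        for trial in range(20):
            lam = float(rng.uniform(0.05, 1.0))
            X, y = _toy_problem(rng, n_per_class=15, p=5, spread=1.5)
            clf = so.fit_lda(X, y, shrinkage=lam)
            oracle = _dense_lda_oracle(X, y, lam)
            Xt = rng.normal(0, 2, (80, 5))
            assert np.array_equal(clf.predict_features(Xt), oracle(Xt)), trial

    def test_sklearn_agreement_on_dense_problem(self, rng):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        X, y = _toy_problem(rng, n_per_class=30, p=8)
        lam = 0.4
        ours = so.fit_lda(X, y, shrinkage=lam)
        ref = sklearn_lda(solver="lsqr", shrinkage=lam).fit(X, y)
        Xt = rng.normal(0, 2, (200, 8))
        agreement = np.mean(ours.predict_features(Xt) == ref.predict(Xt))
        assert agreement > 0.97  # dof convention (n vs n-K) may flip boundary points

    def test_woodbury_path_matches_dense_solve(self, rng):
        # p = 600 > max(n, 512) forces the low-rank Woodbury solve
        n_per, p, lam = 20, 600, 0.5
        means = rng.normal(0, 1, (3, p))
        X = np.concatenate(
            [rng.normal(means[k], 1.0, (n_per, p)) for k in range(3)]
        )
        y = np.repeat(np.arange(3), n_per)
        clf = so.fit_lda(X, y, shrinkage=lam)
        oracle = _dense_lda_oracle(X, y, lam)
        Xt = rng.normal(0, 1, (40, p))
        assert np.array_equal(clf.predict_features(Xt), oracle(Xt))

    def test_auto_shrinkage_in_unit_interval(self, rng):
        X, y = _toy_problem(rng)
        clf = so.fit_lda(X, y, shrinkage="auto")
        assert 0.0 <= clf.shrinkage <= 1.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            so.fit_lda(X, np.zeros(10, dtype=int))

    def test_class_with_one_sample_rejected(self, rng):
        X = rng.normal(0, 1, (5, 3))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="TRIPOD"):
            so.fit_lda(X, y)

    def test_zero_shrinkage_high_dim_rejected(self, rng):
        X = rng.normal(0, 1, (20, 600))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="singular"):
            so.fit_lda(X, y, shrinkage=0.0)


class TestPredict:
    def test_frame_at_class_mean_predicts_that_class(self, rng):
        frames, labels = [], []
        for k, base in enumerate((60, 128, 200)):
            for _ in range(3):
                px = np.clip(
                    base + rng.integers(-2, 3, so.FRAME_SHAPE), 0, 255
                ).astype(np.uint8)
                frames.append(so.Frame(px))
                labels.append(k)
        X = np.stack([so.vectorize(f) for f in frames])
        clf = so.fit_lda(X, np.array(labels), shrinkage=1.0)
        mean_frame = so.devectorize(np.clip(clf.means[1], 0, 1))
        assert clf.predict(mean_frame) is so.GraspLabel.TRIPOD

    def test_tie_broken_by_class_order(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        clf = so.fit_lda(X, y, shrinkage=1.0)
        # x = 0 is exactly equidistant; REST precedes TRIPOD in class order
        assert clf.predict_features(np.array([[0.0]]))[0] == 0

    def test_wrong_feature_count_rejected(self, rng):
        X, y = _toy_problem(rng)
        clf = so.fit_lda(X, y, shrinkage=0.5)
        with pytest.raises(ValueError, match="features"):
            clf.decision_scores(np.zeros((1, 7)))


class TestAccuracy:
    def test_simple_fractions(self):
        assert so.classification_accuracy([1] * 58, [1] * 58) == 100.0
        assert so.classification_accuracy([1, 1, 0], [1, 1, 1]) == pytest.approx(
            66.6667, abs=1e-3
        )
        assert so.classification_accuracy([0] * 57, [1] * 57) == 0.0

    def test_permutation_invariance(self, rng):
        pred = rng.integers(0, 3, 100)
        true = rng.integers(0, 3, 100)
        acc = so.classification_accuracy(pred, true)
        perm = rng.permutation(100)
        assert so.classification_accuracy(pred[perm], true[perm]) == acc

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            so.classification_accuracy([], [])


class TestCrossConditionMatrix:
    def test_static_matrix_is_8x7(self, offline_result):
        m = offline_result.matrices[("static", "B")]
        assert m.values.shape == (8, 7)
        assert m.row_labels[-1] == "ALL"

    def test_dynamic_matrix_is_5x4(self, offline_result):
        m = offline_result.matrices[("dynamic", "B")]
        assert m.values.shape == (5, 4)

    def test_cells_bounded(self, offline_result):
        for m in offline_result.matrices.values():
            assert m.values.min() >= 0.0 and m.values.max() <= 100.0

    def test_no_position_effect_gives_uniform_high_accuracy(self):
        cfg = so.GeneratorConfig(seed=2, position_effect=0.0)
        session = so.generate_session(so.static_protocol(so.Load.LOAD_B), cfg, seed=5)
        split = so.split_repeats(session, seed=1)
        m = so.cross_condition_matrix(
            session, so.Load.LOAD_B, so.Mode.STATIC, split
        )
        assert m.values.min() >= 95.0
        # inter- and intra-position accuracy agree when position has no effect
        assert abs(m.diagonal_mean - m.offdiagonal_mean) < 2.0

    def test_strategy_rows_cover_all_conditions(self):
        static = strategies_for(so.Mode.STATIC)
        dynamic = strategies_for(so.Mode.DYNAMIC)
        assert len(static) == 8 and static[-1].kind == "static_all"
        assert len(dynamic) == 5 and dynamic[-1].kind == "dynamic_all"
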