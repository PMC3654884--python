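"""RaWa model: states, complementary split, weights, fit/predict rules."""

import numpy as np
import pytest

import rawalk
from rawalk import classifier


def literal_prediction(X, labels, class_order, X_test, gamma, alpha, t,
                       lambda_reg, weights=None):
    """Independent transcription of F(x) = Y~ Q^t (K + lambda I)^+ k(X, x).

    Uses numpy's SVD-based pinv (the implementation uses a symmetric
    eigendecomposition route) and explicit loops for the state matrix.
    """
    n = len(labels)
    m = len(class_order)
    Y = np.zeros((m, n))
    for i, lab in enumerate(labels):
        Y[class_order.index(lab), i] = 1.0
    if weights is not None:
        Y = Y * np.asarray(weights)[None, :]
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    K = np.exp(-gamma * sq)
    P = K / K.sum(axis=1)[:, None]
    Q = alpha * np.eye(n) + (1 - alpha) * P
    Qt = np.eye(n)
    for _ in range(t):
        Qt = Qt @ Q
    proj = Y @ Qt @ np.linalg.pinv(K + lambda_reg * np.eye(n))
    sq_test = ((X[:, None, :] - X_test[None, :, :]) ** 2).sum(axis=2)
    return proj @ np.exp(-gamma * sq_test)


class TestOneHotStates:
    def test_definition(self):
        sm = rawalk.one_hot_states(["c1", "c1", "c2"], ["c1", "c2"])
        np.testing.assert_array_equal(sm.Y, [[1, 1, 0], [0, 0, 1]])

    def test_single_sample(self):
        sm = rawalk.one_hot_states(["b"], ["a", "b", "c"])
        np.testing.assert_array_equal(sm.Y, [[0], [1], [0]])

    def test_unknown_label_named(self):
        with pytest.raises(ValueError, match="c9"):
            rawalk.one_hot_states(["c1", "c9"], ["c1", "c2"])

    def test_columns_sum_to_one(self, rng):
        labels = [f"c{i}" for i in rng.integers(0, 4, size=30)]
        order = sorted(set(labels))
        sm = rawalk.one_hot_states(labels, order)
        np.testing.assert_array_equal(sm.Y.sum(axis=0), np.ones(30))


class TestStratifiedHalfSplit:
    def test_two_per_class_forces_one_each_side(self):
        labels = ["a", "a", "b", "b"]
        S, T = rawalk.stratified_half_split(labels, seed=0)
        assert len(S) == len(T) == 2
        assert {labels[i] for i in S} == {"a", "b"}
        assert {labels[i] for i in T} == {"a", "b"}

    def test_partition_properties(self, rng):
        labels = [f"c{i}" for i in rng.integers(0, 3, size=25)]
        S, T = rawalk.stratified_half_split(labels, seed=3)
        assert set(S) | set(T) == set(range(25))
        assert set(S) & set(T) == set()
        # size difference bounded by number of odd-count classes
        odd = sum(labels.count(c) % 2 for c in set(labels))
        assert abs(len(S) - len(T)) <= odd

    def test_singleton_class_lands_one_side(self):
        labels = ["a", "a", "b"]
        S, T = rawalk.stratified_half_split(labels, seed=1)
        assert sorted(list(S) + list(T)) == [0, 1, 2]

    def test_seed_determinism(self):
        labels = ["a", "b"] * 10
        s1 = rawalk.stratified_half_split(labels, seed=5)
        s2 = rawalk.stratified_half_split(labels, seed=5)
        s3 = rawalk.stratified_half_split(labels, seed=6)
        np.testing.assert_array_equal(s1[0], s2[0])
        assert not (
            np.array_equal(s1[0], s3[0]) and np.array_equal(s1[1], s3[1])
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rawalk.stratified_half_split([], seed=0)


class TestCrossPredictionLoss:
    def _setup(self, rng, n=12):
        X = rng.normal(size=(n, 3))
        labels = ["a" if i % 2 == 0 else "b" for i in range(n)]
        Y = rawalk.one_hot_states(labels, ["a", "b"]).Y
        S, T = rawalk.stratified_half_split(labels, seed=0)
        return X, Y, S, T

    def test_swap_symmetry(self, rng):
        X, Y, S, T = self._setup(rng)
        eps_S, eps_T = rawalk.cross_prediction_loss(X, Y, S, T, 0.5, 0.75, 3)
        eps_T2, eps_S2 = rawalk.cross_prediction_loss(X, Y, T, S, 0.5, 0.75, 3)
        assert eps_S == pytest.approx(eps_S2)
        assert eps_T == pytest.approx(eps_T2)

    def test_matches_direct_dense_transcription(self, rng):
        X, Y, S, T = self._setup(rng)
        gamma, alpha, t, lam = 0.8, 0.6, 2, 1e-4
        eps_S, eps_T = rawalk.cross_prediction_loss(X, Y, S, T, gamma, alpha, t, lam)
        labels = ["a" if i % 2 == 0 else "b" for i in range(12)]
        F_S = literal_prediction(
            X[S], [labels[i] for i in S], ["a", "b"], X[T], gamma, alpha, t, lam
        )
        want_S = np.linalg.norm(F_S - Y[:, T], "fro") ** 2
        assert eps_S == pytest.approx(want_S, rel=1e-9)
        assert eps_S >= 0 and eps_T >= 0

    def test_duplicated_points_give_near_minimal_loss(self, rng):
        # T's points sit inside S with matching labels; with a sharp kernel
        # the cross prediction concentrates on the duplicates.
        base = rng.normal(size=(4, 2)) * 3
        X = np.vstack([base, base])
        labels = ["a", "a", "b", "b"] * 2
        Y = rawalk.one_hot_states(labels, ["a", "b"]).Y
        S = np.array([0, 1, 2, 3])
        T = np.array([4, 5, 6, 7])
        eps_sharp, _ = rawalk.cross_prediction_loss(
            X, Y, S, T, gamma=50.0, alpha=0.95, t=1
        )
        eps_blur, _ = rawalk.cross_prediction_loss(
            X, Y, S, T, gamma=0.01, alpha=0.95, t=1
        )
        assert eps_sharp < eps_blur

    def test_empty_half_rejected(self, rng):
        X, Y, S, T = self._setup(rng)
        with pytest.raises(ValueError):
            rawalk.cross_prediction_loss(X, Y, np.array([], dtype=int), T)

    def test_singleton_halves_defined(self, rng):
        X = rng.normal(size=(2, 2))
        Y = rawalk.one_hot_states(["a", "a"], ["a"]).Y
        eps_S, eps_T = rawalk.cross_prediction_loss(
            X, Y, np.array([0]), np.array([1])
        )
        assert np.isfinite(eps_S) and np.isfinite(eps_T)


class TestSplitWeightsAndLoss:
    @pytest.mark.parametrize(
        "eps, want",
        [((1, 1), (0.5, 0.5)), ((1, 3), (0.75, 0.25)), ((0, 0), (0.5, 0.5))],
    )
    def test_weight_formula(self, eps, want):
        assert rawalk.split_weights(*eps) == pytest.approx(want)

    def test_smaller_loss_gets_larger_weight(self, rng):
        for _ in range(20):
            e1, e2 = rng.uniform(0, 10, size=2)
            a_S, a_T = rawalk.split_weights(e1, e2)
            assert a_S + a_T == pytest.approx(1.0)
            if e1 < e2:
                assert a_S > a_T
            elif e2 < e1:
                assert a_T > a_S

    @pytest.mark.parametrize(
        "eps, want", [((1, 1), 0.5), ((0, 5), 0.0), ((2, 3), 1.2), ((0, 0), 0.0)]
    )
    def test_total_loss_formula(self, eps, want):
        assert rawalk.total_loss(*eps) == pytest.approx(want)

    def test_total_loss_below_min(self, rng):
        for _ in range(20):
            e1, e2 = rng.uniform(0.01, 10, size=2)
            assert rawalk.total_loss(e1, e2) <= min(e1, e2) + 1e-12

    def test_negative_losses_rejected(self):
        with pytest.raises(ValueError):
            rawalk.split_weights(-1, 1)
        with pytest.raises(ValueError):
            rawalk.total_loss(1, -1)


class TestFit:
    def test_shapes_and_weight_invariant(self, small_table):
        model = rawalk.fit(small_table, gamma=0.5, seed=0)
        assert model.projection.shape == (2, small_table.n)
        assert model.split.alpha_S + model.split.alpha_T == pytest.approx(1.0)

    def test_same_seed_bit_identical(self, small_table):
        m1 = rawalk.fit(small_table, gamma=0.5, seed=3)
        m2 = rawalk.fit(small_table, gamma=0.5, seed=3)
        np.testing.assert_array_equal(m1.projection, m2.projection)

    def test_alpha_one_is_t_independent(self, small_table):
        m1 = rawalk.fit(small_table, gamma=0.5, alpha=1.0, t=1, seed=0)
        m2 = rawalk.fit(small_table, gamma=0.5, alpha=1.0, t=9, seed=0)
        np.testing.assert_allclose(m1.projection, m2.projection, atol=1e-12)

    def test_single_class_warns_and_predicts_it(self, rng):
        table = rawalk.FeatureTable(
            sample_ids=["s1", "s2", "s3"],
            X=rng.normal(size=(3, 2)),
            labels=["only"] * 3,
        )
        with pytest.warns(UserWarning, match="single-class"):
            model = rawalk.fit(table, gamma=1.0, seed=0)
        labels = rawalk.predict_labels(
            rawalk.predict_scores(model, rng.normal(size=(4, 2)))
        )
        assert labels == ["only"] * 4

    def test_unlabeled_or_tiny_tables_rejected(self, rng):
        t = rawalk.FeatureTable(["a"], np.zeros((1, 2)), labels=["x"])
        with pytest.raises(ValueError):
            rawalk.fit(t)
        t2 = rawalk.FeatureTable(["a", "b"], rng.normal(size=(2, 2)))
        with pytest.raises(ValueError):
            rawalk.fit(t2)

    def test_model_json_round_trip(self, small_table, tmp_path):
        model = rawalk.fit(small_table, gamma=0.5, seed=1)
        path = tmp_path / "model.json"
        model.save(path)
        back = rawalk.WalkModel.load(path)
        np.testing.assert_allclose(back.projection, model.projection)
        assert back.class_order == model.class_order
        assert back.split.eps_S == pytest.approx(model.split.eps_S)


class TestPredict:
    def test_matches_literal_transcription_small_instance(self, rng):
        X = rng.normal(size=(3, 2))
        labels = ["a", "b", "a"]
        table = rawalk.FeatureTable(["s1", "s2", "s3"], X, labels=labels)
        gamma, alpha, t, lam = 0.05, 0.75, 3, 1e-4
        model = rawalk.fit(table, gamma=gamma, alpha=alpha, t=t,
                           lambda_reg=lam, seed=0)
        X_test = rng.normal(size=(4, 2))
        got = rawalk.predict_scores(model, X_test).scores
        weights = np.where(
            np.isin(np.arange(3), model.split.S_indices),
            model.split.alpha_S, model.split.alpha_T,
        )
        want = literal_prediction(X, labels, ["a", "b"], X_test,
                                  gamma, alpha, t, lam, weights=weights)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_sharp_kernel_recovers_projection_column(self, small_table):
        model = rawalk.fit(small_table, gamma=200.0, seed=0)
        got = rawalk.predict_scores(model, small_table.X[[4]]).scores[:, 0]
        # k(X, x) ~ e_4 when the kernel is near-indicator
        want = model.projection @ rawalk.rbf_kernel(
            small_table.X, small_table.X[[4]], 200.0
        )
        np.testing.assert_allclose(got, want[:, 0], atol=1e-12)
        assert rawalk.rbf_kernel(
            small_table.X, small_table.X[[4]], 200.0
        )[4, 0] == pytest.approx(1.0)

    def test_dimension_mismatch(self, small_table, rng):
        model = rawalk.fit(small_table, gamma=0.5, seed=0)
        with pytest.raises(ValueError, match="dimensionality"):
            rawalk.predict_scores(model, rng.normal(size=(2, 5)))

    def test_scale_invariance_of_labels(self, small_table, rng):
        model = rawalk.fit(small_table, gamma=0.5, seed=0)
        X_test = rng.normal(size=(10, small_table.d))
        sm = rawalk.predict_scores(model, X_test)
        base = rawalk.predict_labels(sm)
        scaled = rawalk.ScoreMatrix(scores=7.3 * sm.scores, class_order=sm.class_order)
        assert rawalk.predict_labels(scaled) == base

    def test_equal_loss_reduction_matches_unweighted(self, rng):
        # Duplicated class points make every stratified half identical as a
        # point set, forcing eps_S == eps_T; the weighted state matrix then
        # equals 0.5 * Y and predictions match an unweighted transcription
        # scaled by 0.5.
        X = np.array([[0.0, 0], [0.0, 0], [3.0, 3], [3.0, 3]])
        labels = ["a", "a", "b", "b"]
        table = rawalk.FeatureTable(["1", "2", "3", "4"], X, labels=labels)
        model = rawalk.fit(table, gamma=0.3, seed=0)
        assert model.split.eps_S == pytest.approx(model.split.eps_T)
        X_test = rng.normal(size=(5, 2))
        got = rawalk.predict_scores(model, X_test).scores
        want = 0.5 * literal_prediction(
            X, labels, ["a", "b"], X_test, 0.3, 0.75, 5, 1e-4
        )
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestPredictLabels:
    def test_argmax(self):
        sm = rawalk.ScoreMatrix(np.array([[0.2], [0.8]]), ["c1", "c2"])
        assert rawalk.predict_labels(sm) == ["c2"]

    def test_tie_breaks_to_lowest_index(self):
        sm = rawalk.ScoreMatrix(np.array([[0.5], [0.5]]), ["c1", "c2"])
        assert rawalk.predict_labels(sm) == ["c1"]

    def test_nan_rejected(self):
        sm = rawalk.ScoreMatrix(np.array([[np.nan], [0.5]]), ["c1", "c2"])
        with pytest.raises(ValueError, match="NaN"):
            rawalk.predict_labels(sm)

    def test_empty_rejected(self):
        sm = rawalk.ScoreMatrix(np.zeros((2, 0)), ["c1", "c2"])
        with pytest.raises(ValueError, match="empty"):
            rawalk.predict_labels(sm)
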