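"""Sigmoid scoring, the decision cascade, and IRLS training."""

import json

import numpy as np
import pytest

from fingerbci.classifier import (
    LogisticModel,
    TwoStageModel,
    classify,
    decide,
    logistic_probability,
    stratified_split,
    train_logistic,
    train_two_stage,
)


def model_with_score(z, class1="not_fist", class2="fist"):
    """A network whose linear score is the constant z for any features."""
    B = np.zeros(15)
    B[0] = z
    return LogisticModel(B=B, class1_label=class1, class2_label=class2)


class TestLogisticProbability:
    def test_zero_weights_give_half(self, rng):
        m = model_with_score(0.0)
        assert logistic_probability(m, rng.normal(size=14)) == 0.5

    def test_saturation(self, rng):
        assert logistic_probability(model_with_score(10.0), rng.normal(size=14) * 0) > 0.9999

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            B = rng.normal(size=15)
            f = rng.normal(size=14)
            m = LogisticModel(B=B, class1_label="a", class2_label="b")
            z = B[0] + B[1:] @ f
            expected = np.exp(z) / (np.exp(z) + 1.0)
            assert logistic_probability(m, f) == pytest.approx(expected, abs=1e-12)

    def test_complement_symmetry(self, rng):
        for _ in range(10):
            B = rng.normal(size=15)
            f = rng.normal(size=14)
            p_pos = logistic_probability(LogisticModel(B=B, class1_label="a", class2_label="b"), f)
            p_neg = logistic_probability(LogisticModel(B=-B, class1_label="a", class2_label="b"), f)
            assert p_pos + p_neg == pytest.approx(1.0, abs=1e-12)

    def test_numerically_stable_at_extreme_scores(self):
        f = np.zeros(14)
        assert logistic_probability(model_with_score(700.0), f) == 1.0
        assert logistic_probability(model_with_score(-700.0), f) == pytest.approx(0.0, abs=1e-300)

    def test_rejects_non_finite_features(self):
        f = np.zeros(14)
        f[0] = np.inf
        with pytest.raises(ValueError):
            logistic_probability(model_with_score(0.0), f)


class TestDecide:
    @pytest.mark.parametrize("p, expected", [(0.51, 1), (0.49, 2), (0.5, 2), (1.0, 1), (0.0, 2)])
    def test_threshold(self, p, expected):
        assert decide(p) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            decide(1.2)


class TestClassify:
    def make_cascade(self, z1, z2):
        return TwoStageModel(
            network1=model_with_score(z1, "not_fist", "fist"),
            network2=model_with_score(z2, "thumb", "index"),
        )

    def test_stage1_fist_short_circuits(self, rng):
        pred = classify(self.make_cascade(-2.0, +5.0), rng.normal(size=14))
        assert pred.label == "fist"
        assert pred.p2 is None

    def test_both_class1_gives_thumb(self, rng):
        pred = classify(self.make_cascade(+3.0, +3.0), rng.normal(size=14))
        assert pred.label == "thumb"
        assert pred.p1 > 0.5 and pred.p2 > 0.5

    def test_stage2_class2_gives_index(self, rng):
        pred = classify(self.make_cascade(+3.0, -3.0), rng.normal(size=14))
        assert pred.label == "index"

    def test_scale_consistency(self, rng):
        """Scaling features by c and non-intercept weights by 1/c preserves output."""
        B1, B2 = rng.normal(size=15), rng.normal(size=15)
        model = TwoStageModel(
            network1=LogisticModel(B=B1, class1_label="not_fist", class2_label="fist"),
            network2=LogisticModel(B=B2, class1_label="thumb", class2_label="index"),
        )
        c = 37.5
        scaled = TwoStageModel(
            network1=LogisticModel(B=np.r_[B1[0], B1[1:] / c], class1_label="not_fist",
                                   class2_label="fist"),
            network2=LogisticModel(B=np.r_[B2[0], B2[1:] / c], class1_label="thumb",
                                   class2_label="index"),
        )
        for _ in range(10):
            f = np.abs(rng.normal(size=14))
            assert classify(model, f).label == classify(scaled, c * f).label


class TestTrainLogistic:
    def test_symmetric_data_gives_zero_intercept(self, rng):
        base = rng.normal(size=(50, 14))
        X = np.vstack([base, -base])  # mirror-image pairs
        labels = ["a"] * 50 + ["b"] * 50
        m = train_logistic(X, labels, "a", "b", ridge=1e-2)
        assert abs(m.B[0]) < 1e-6

    def test_separable_toy_set_reaches_perfect_training_accuracy(self, rng):
        X = np.zeros((40, 14))
        X[:20, 0] = rng.normal(3.0, 0.3, 20)
        X[20:, 0] = rng.normal(-3.0, 0.3, 20)
        labels = ["a"] * 20 + ["b"] * 20
        m = train_logistic(X, labels, "a", "b", ridge=1.0)
        preds = [decide(logistic_probability(m, x)) for x in X]
        assert preds == [1] * 20 + [2] * 20

    def test_fit_beats_null_model(self, rng):
        X = rng.normal(size=(60, 14))
        labels = ["a" if x[2] + 0.5 * x[5] > 0 else "b" for x in X]
        if labels.count("a") < 2 or labels.count("b") < 2:
            pytest.skip("degenerate draw")
        ridge = 0.1
        m = train_logistic(X, labels, "a", "b", ridge=ridge)
        y = np.array([1.0 if lab == "a" else 0.0 for lab in labels])
        Xa = np.column_stack([np.ones(len(X)), X])

        def pll(beta):
            z = Xa @ beta
            return np.sum(y * z - np.logaddexp(0, z)) - 0.5 * ridge * beta[1:] @ beta[1:]

        assert pll(m.B) >= pll(np.zeros(15))

    def test_matches_sklearn_at_matching_penalty(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(300, 14))
        beta = rng.normal(size=14)
        p = 1 / (1 + np.exp(-(X @ beta)))
        y = rng.uniform(size=300) < p
        labels = ["a" if yi else "b" for yi in y]
        ridge = 1.0
        mine = train_logistic(X, labels, "a", "b", ridge=ridge)
        ref = sklearn.LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000,
                                         tol=1e-10).fit(X, y.astype(int))
        np.testing.assert_allclose(mine.B[1:], ref.coef_[0], atol=2e-3)
        np.testing.assert_allclose(mine.B[0], ref.intercept_[0], atol=2e-2)

    def test_parameter_recovery(self, rng):
        """Simulated 14-dim logistic data is recovered with RMSE < 0.15 at n=2000."""
        n = 2000
        true_B = np.r_[0.3, rng.normal(0.0, 0.8, 14)]
        X = rng.normal(size=(n, 14))
        p = 1 / (1 + np.exp(-(true_B[0] + X @ true_B[1:])))
        y = rng.uniform(size=n) < p
        labels = ["a" if yi else "b" for yi in y]
        m = train_logistic(X, labels, "a", "b", ridge=1e-8)
        rmse = np.sqrt(np.mean((m.B - true_B) ** 2))
        assert rmse < 0.15

    def test_rejects_single_class(self, rng):
        with pytest.raises(ValueError):
            train_logistic(rng.normal(size=(10, 14)), ["a"] * 10, "a", "b")


class TestTrainTwoStage:
    def separable_features(self, rng, n_per_class=30, spread=0.2):
        f3, fc5 = 2, 3
        X, labels = [], []
        for cls, (g3, g5) in (("thumb", (5, 1)), ("index", (1, 5)), ("fist", (7, 7))):
            block = np.abs(rng.normal(1.0, spread, (n_per_class, 14)))
            block[:, f3] *= g3
            block[:, fc5] *= g5
            X.append(block)
            labels += [cls] * n_per_class
        return np.vstack(X), labels

    def test_missing_class_rejected(self, rng):
        X = rng.normal(size=(20, 14))
        with pytest.raises(ValueError, match="fist"):
            train_two_stage(X, ["thumb"] * 10 + ["index"] * 10)

    def test_separable_classes_decoded_perfectly(self, rng):
        X, labels = self.separable_features(rng)
        train_idx, test_idx = stratified_split(labels, seed=7)
        model = train_two_stage(X[train_idx], [labels[i] for i in train_idx], ridge=1.0)
        preds = [classify(model, X[i]).label for i in test_idx]
        assert preds == [labels[i] for i in test_idx]

    def test_network2_never_sees_fist(self, rng):
        X, labels = self.separable_features(rng, n_per_class=10)
        model = train_two_stage(X, labels, ridge=1.0)
        assert model.network2.n_obs == 20  # thumb + index rows only
        assert model.network1.n_obs == 30


class TestSplitAndSerialization:
    def test_stratified_split_proportions(self):
        labels = ["thumb"] * 40 + ["index"] * 40 + ["fist"] * 40
        train, test = stratified_split(labels, test_fraction=0.25, seed=3)
        assert len(test) == 30 and len(train) == 90
        assert sorted(np.concatenate([train, test]).tolist()) == list(range(120))
        labels_arr = np.array(labels)
        for cls in ("thumb", "index", "fist"):
            assert (labels_arr[test] == cls).sum() == 10

    def test_split_deterministic_in_seed(self):
        labels = ["thumb", "index", "fist"] * 20
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_model_json_round_trip(self, rng):
        model = TwoStageModel(
            network1=LogisticModel(B=rng.normal(size=15), class1_label="not_fist",
                                   class2_label="fist"),
            network2=LogisticModel(B=rng.normal(size=15), class1_label="thumb",
                                   class2_label="index"),
        )
        back = TwoStageModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.network1.B, model.network1.B)
        np.testing.assert_array_equal(back.network2.B, model.network2.B)
        assert json.loads(model.to_json())["network1"]["class2"] == "fist"
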