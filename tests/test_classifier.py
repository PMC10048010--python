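"""Set-aside split, ANN training, cross-validation, importance."""

import numpy as np
import pytest

import crownmorph as cm
from crownmorph.errors import DegenerateTrainingError, InvalidInputError, SchemaError


def _separable(n=200, p=10, seed=42, gap=2.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    y = np.array(["F"] * (n // 2) + ["M"] * (n - n // 2))
    x[: n // 2, :3] += gap
    return x, y


class TestSetAsideSplit:
    def test_study_counts(self):
        labels = {f"F{i}": "F" for i in range(115)} | {f"M{i}": "M" for i in range(115)}
        plan = cm.set_aside_split(labels, {"F": 84, "M": 90}, seed=7)
        assert len(plan.train_ids) == 174
        assert len(plan.test_ids) == 56
        assert plan.train_counts == {"F": 84, "M": 90}
        assert plan.test_counts == {"F": 31, "M": 25}
        assert set(plan.train_ids).isdisjoint(plan.test_ids)
        assert sorted(plan.train_ids + plan.test_ids) == sorted(labels)

    def test_deterministic_under_seed(self):
        labels = {f"s{i}": ("F" if i % 2 else "M") for i in range(40)}
        a = cm.set_aside_split(labels, {"F": 15, "M": 15}, seed=3)
        b = cm.set_aside_split(labels, {"F": 15, "M": 15}, seed=3)
        c = cm.set_aside_split(labels, {"F": 15, "M": 15}, seed=4)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        assert a.train_ids != c.train_ids

    def test_overdraw_rejected(self):
        labels = {f"s{i}": "F" for i in range(10)} | {f"t{i}": "M" for i in range(10)}
        with pytest.raises(InvalidInputError):
            cm.set_aside_split(labels, {"F": 12, "M": 5}, seed=0)


class TestTrainAnn:
    def test_outputs_strictly_in_unit_interval(self):
        x, y = _separable(n=60)
        model = cm.train_ann(x, y, hidden=3, decay=0.1, epochs=50, seed=1)
        proba, _ = cm.predict_sex(model, np.vstack([x, 100 * np.ones((1, x.shape[1]))]))
        assert np.all(proba > 0) and np.all(proba < 1)

    def test_separable_data_learned(self):
        x, y = _separable(n=200, seed=42)
        model = cm.train_ann(x, y, hidden=3, decay=0.1, seed=0)
        assert model.training_accuracy >= 0.98

    def test_bitwise_determinism(self):
        x, y = _separable(n=80, seed=5)
        a = cm.train_ann(x, y, hidden=4, decay=0.05, epochs=60, seed=9)
        b = cm.train_ann(x, y, hidden=4, decay=0.05, epochs=60, seed=9)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.w2, b.w2)
        assert np.array_equal(a.loss_history, b.loss_history)

    def test_loss_history_non_increasing(self):
        x, y = _separable(n=100, seed=6)
        model = cm.train_ann(x, y, hidden=3, decay=0.1, epochs=120, seed=2)
        assert np.all(np.diff(model.loss_history) <= 1e-12)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DegenerateTrainingError):
            cm.train_ann(rng.normal(size=(20, 4)), np.array(["F"] * 20))


class TestPredict:
    def test_half_probability_classifies_positive(self):
        x, y = _separable(n=40, seed=7)
        model = cm.train_ann(x, y, hidden=2, epochs=20, seed=0)
        # zero out everything so the output is exactly sigmoid(0) = 0.5
        model.w1[:] = 0; model.b1[:] = 0; model.w2[:] = 0; model.b2[:] = 0
        proba, labels = cm.predict_sex(model, x)
        assert np.allclose(proba, 0.5)
        assert np.all(labels == "F")

    def test_constant_model_closed_form(self):
        x, y = _separable(n=30, seed=8)
        model = cm.train_ann(x, y, hidden=2, epochs=10, seed=0)
        model.w1[:] = 0; model.w2[:] = 0; model.b1[:] = 0; model.b2[:] = 0.8
        proba, _ = cm.predict_sex(model, x)
        # zero weights: every row collapses to sigmoid(output bias)
        assert np.allclose(proba, 1 / (1 + np.exp(-0.8)))

    def test_training_set_consistency(self):
        x, y = _separable(n=120, seed=9)
        model = cm.train_ann(x, y, hidden=3, decay=0.1, epochs=200, seed=4)
        proba, labels = cm.predict_sex(model, x)
        assert np.mean(labels == y) == pytest.approx(model.training_accuracy)

    def test_column_mismatch_rejected(self):
        import pandas as pd

        x, y = _separable(n=30, p=4, seed=10)
        df = pd.DataFrame(x, columns=list("abcd"))
        model = cm.train_ann(df, y, hidden=2, epochs=10, seed=0)
        with pytest.raises(SchemaError):
            cm.predict_sex(model, df.rename(columns={"d": "z"}))
        with pytest.raises(SchemaError):
            cm.predict_sex(model, x[:, :3])


class TestCrossValidate:
    def test_single_candidate_selected(self):
        x, y = _separable(n=60, seed=11)
        cv = cm.cross_validate(x, y, [(3, 0.1)], k=5, seed=0, epochs=30)
        assert cv.selected == {"hidden": 3, "decay": 0.1}

    def test_selection_attains_maximal_mean_accuracy(self):
        x, y = _separable(n=80, seed=12)
        cv = cm.cross_validate(x, y, [(1, 0.1), (3, 0.1), (3, 1000.0)], k=4, seed=1, epochs=40)
        assert cv.mean_accuracy[cv.selected_index] == cv.mean_accuracy.max()

    def test_k_larger_than_n_rejected(self):
        x, y = _separable(n=8, seed=13)
        with pytest.raises(InvalidInputError):
            cm.cross_validate(x, y, [(2, 0.1)], k=9)

    def test_permuted_labels_give_chance_level(self):
        """With labels shuffled independently of the data, held-out accuracy
        is statistically indistinguishable from 0.5."""
        rng = np.random.default_rng(314)
        x = rng.normal(size=(200, 10))
        y = np.array(["F", "M"] * 100)
        y = y[rng.permutation(200)]
        cv = cm.cross_validate(x, y, [(3, 0.1)], k=10, seed=2, epochs=60)
        mean = cv.mean_accuracy[cv.selected_index]
        se = cv.sd_accuracy[cv.selected_index] / np.sqrt(10)
        assert abs(mean - 0.5) <= 3 * max(se, 0.02)


class TestPredictorImportance:
    def test_hand_computed_two_predictor_net(self):
        x, y = _separable(n=30, p=2, seed=14)
        model = cm.train_ann(x, y, hidden=1, epochs=5, seed=0)
        model.w1[:] = np.array([[0.6], [-0.2]])
        model.w2[:] = np.array([[0.5]])
        imp = cm.predictor_importance(model, names=["a", "b"])
        # |0.6|/0.8 * 0.5 = 0.375 and |0.2|/0.8 * 0.5 = 0.125 -> 100 and 33.33
        assert imp["a"] == pytest.approx(100.0)
        assert imp["b"] == pytest.approx(100.0 / 3, rel=1e-9)

    def test_disconnected_predictor_scores_zero_and_max_is_100(self):
        x, y = _separable(n=60, p=5, seed=15)
        model = cm.train_ann(x, y, hidden=3, epochs=30, seed=3)
        model.w1[4, :] = 0.0
        imp = cm.predictor_importance(model, names=list("abcde"))
        assert imp["e"] == 0.0
        assert imp.max() == pytest.approx(100.0)
        assert (imp >= 0).all()
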