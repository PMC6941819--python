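import numpy as np
import pytest
from sklearn.base import clone

from endofilter.classifier import (
    LogisticNoiseClassifier,
    bias_feature,
    choose_threshold,
    classify,
    fit_model,
    youden_threshold,
)

from helpers import threshold_sweep_oracle


def separable_data(rng, n=100):
    """Artifacts at (x_bias ~ 10, x_clip ~ 0.5); genuine at (~0.2, ~0.05)."""
    Xa = np.column_stack([rng.normal(10, 1, n), rng.normal(0.5, 0.05, n)])
    Xg = np.column_stack([np.abs(rng.normal(0.2, 0.1, n)), np.abs(rng.normal(0.05, 0.02, n))])
    X = np.vstack([Xa, Xg])
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    return X, y


class TestFit:
    def test_separable_clusters_perfectly_classified(self, rng):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning, match="separation"):
            model = LogisticNoiseClassifier().fit(X, y)
        assert model.separable_
        assert model.sensitivity_ == 1.0 and model.specificity_ == 1.0
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            LogisticNoiseClassifier().fit(X, np.ones(20, int))

    def test_shuffled_labels_auroc_near_half(self, rng):
        X, y = separable_data(rng, n=400)
        y_shuf = rng.permutation(y)
        model = LogisticNoiseClassifier().fit(X, y_shuf)
        _, _, auc = model.roc_curve(X, y_shuf)
        assert abs(auc - 0.5) < 0.08

    def test_overlapping_data_gives_mle_with_standard_errors(self, rng):
        n = 500
        X = np.column_stack([rng.normal(0, 2, n), rng.uniform(0, 1, n)])
        z = -0.5 + 0.7 * X[:, 0] + 1.5 * X[:, 1]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-z))).astype(int)
        model = LogisticNoiseClassifier().fit(X, y)
        assert not model.separable_ and model.bse_ is not None
        assert np.isfinite(model.bse_).all()


class TestThreshold:
    def test_sweep_equals_exhaustive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            probs = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            y = rng.integers(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            t, sens, spec = youden_threshold(probs, y)
            j_oracle, t_oracle = threshold_sweep_oracle(probs, y)
            assert t == pytest.approx(t_oracle)
            assert sens + spec == pytest.approx(j_oracle)

    def test_all_probs_equal_degenerate(self):
        t, sens, spec = youden_threshold(np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1]))
        assert sens + spec == pytest.approx(1.0)

    def test_boundary_point_is_noise(self, rng):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning):
            model = LogisticNoiseClassifier().fit(X, y)
        p = model.predict_proba(X)[:, 1]
        at_t = np.argmin(np.abs(p - model.threshold_))
        if p[at_t] == model.threshold_:
            assert model.predict(X[at_t : at_t + 1])[0] == 1

    def test_choose_threshold_updates_model(self, rng):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning):
            model = fit_model(X, y)
        t = choose_threshold(model, X, y)
        assert t == model.threshold_


class TestPredict:
    def test_origin_is_signal_in_separable_fit(self, rng):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning):
            model = LogisticNoiseClassifier().fit(X, y)
        assert model.predict([[0.0, 0.0]])[0] == 0
        assert classify(model, [[0.0, 0.0]])[0] == "signal"

    def test_monotone_in_clip_when_coefficient_positive(self, rng):
        # clip carries the signal here, so b_clip must come out positive
        n = 200
        Xa = np.column_stack([rng.normal(1, 0.5, n), rng.normal(0.5, 0.05, n)])
        Xg = np.column_stack([rng.normal(1, 0.5, n), np.abs(rng.normal(0.05, 0.02, n))])
        X, y = np.vstack([Xa, Xg]), np.r_[np.ones(n, int), np.zeros(n, int)]
        model = LogisticNoiseClassifier().fit(X, y)
        assert model.coef_[1] > 0
        clips = np.linspace(0, 1, 21)
        preds = model.predict(np.column_stack([np.full(21, 1.0), clips]))
        assert (np.diff(preds) >= 0).all()  # never flips noise -> signal

    def test_missing_feature_rejected(self, rng):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning):
            model = LogisticNoiseClassifier().fit(X, y)
        with pytest.raises(ValueError):
            model.predict(np.array([[np.nan, 0.1]]))

    def test_auroc_invariant_under_monotone_transform(self, rng):
        X, y = separable_data(rng, n=50)
        y = rng.permutation(y)
        model = LogisticNoiseClassifier().fit(X, y)
        _, _, auc = model.roc_curve(X, y)
        from sklearn.metrics import roc_auc_score

        p = model.predict_proba(X)[:, 1]
        assert auc == pytest.approx(roc_auc_score(y, np.log(p / (1 - p))))


class TestSerializationAndSklearn:
    def test_json_roundtrip(self, rng, tmp_path):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning):
            model = LogisticNoiseClassifier().fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = LogisticNoiseClassifier.load(path)
        assert loaded.threshold_ == model.threshold_
        assert (loaded.predict(X) == model.predict(X)).all()

    def test_decision_line_is_linear_boundary(self, rng):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning):
            model = LogisticNoiseClassifier().fit(X, y)
        a, b, c = model.decision_line()
        # points on the line have predicted probability exactly threshold
        x_bias = 5.0
        x_clip = -(a + b * x_bias) / c
        p = model.predict_proba([[x_bias, x_clip]])[0, 1]
        assert p == pytest.approx(model.threshold_, rel=1e-9)

    def test_clone_and_get_params(self):
        model = LogisticNoiseClassifier(ridge=1e-5, threshold=0.4)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()

    def test_bias_feature_transform(self):
        assert bias_feature(1.0) == pytest.approx(0.0)
        assert bias_feature(0.0) == pytest.approx(300.0)
        assert bias_feature(1e-10) == pytest.approx(10.0)
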