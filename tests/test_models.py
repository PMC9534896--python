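"""Classifier suite: selection, training, scoring, AUC, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taxaccum import (
    LabeledDataset,
    ModelSpec,
    cross_validate,
    ensemble_predict,
    predict,
    roc_auc,
    select_features_wilcoxon,
    train_model,
)

TINY_SPEC = dict(gbm_n_estimators=30, gbm_max_depth=3, ann_epochs=50, ann_hidden=(16, 8, 4, 2))


def _dataset(X, y):
    idx = [f"s{i}" for i in range(len(y))]
    return LabeledDataset(
        pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(X.shape[1])]),
        pd.Series(y, index=idx),
    )


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(1)
    y = np.repeat([0, 1], 20)
    X = rng.normal(size=(40, 1)) + 10 * y[:, None]
    return _dataset(X, y)


class TestSelection:
    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 15)
        X = np.column_stack([np.ones(30), rng.normal(size=30) + 3 * y])
        kept = select_features_wilcoxon(_dataset(X, y))
        assert 0 not in kept

    def test_disjoint_support_feature_survives_bonferroni(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 10))
        X[:, 4] = y * 10 + rng.uniform(0, 1, size=60)  # fully disjoint class supports
        kept = select_features_wilcoxon(_dataset(X, y))
        assert 4 in kept

    def test_matches_per_feature_ranksum_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=80)
        y[:5], y[-5:] = 0, 1  # both classes guaranteed
        X = rng.normal(size=(80, 25))
        X[:, 3] += 2 * y
        X[:, 17] -= 2 * y
        kept = set(select_features_wilcoxon(_dataset(X, y), alpha=0.05))
        oracle = set()
        for j in range(25):
            p = stats.mannwhitneyu(
                X[y == 1, j], X[y == 0, j], alternative="two-sided", method="asymptotic"
            ).pvalue
            if min(1.0, p * 25) < 0.05:
                oracle.add(j)
        assert kept == oracle

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            select_features_wilcoxon(_dataset(X, np.ones(10)))


class TestTrainPredict:
    @pytest.mark.parametrize("method", ["glm_all", "glm_selected", "gbm", "ann", "ensemble"])
    def test_perfect_separation_reaches_training_auc_one(self, separated, method):
        spec = ModelSpec(method=method, **TINY_SPEC)
        model = train_model(separated, spec, seed=0)
        scores = predict(model, separated.features)
        auc, _ = roc_auc(scores, separated.labels.to_numpy())
        assert auc == 1.0
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_gbm_deterministic_under_seed(self, separated):
        spec = ModelSpec(method="gbm", **TINY_SPEC)
        s1 = predict(train_model(separated, spec, seed=5), separated.features)
        s2 = predict(train_model(separated, spec, seed=5), separated.features)
        assert np.array_equal(s1, s2)

    def test_ann_deterministic_under_seed(self, separated):
        spec = ModelSpec(method="ann", **TINY_SPEC)
        s1 = predict(train_model(separated, spec, seed=5), separated.features)
        s2 = predict(train_model(separated, spec, seed=5), separated.features)
        assert np.array_equal(s1, s2)

    def test_gbm_extrapolation_clipped(self):
        # regression on 0/1 labels can overshoot; scores must stay in [0, 1]
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 25)
        X = (y + rng.normal(0, 0.01, size=50))[:, None]
        spec = ModelSpec(method="gbm", gbm_n_estimators=500, gbm_learning_rate=0.5, gbm_max_depth=2)
        model = train_model(_dataset(X, y), spec, seed=0)
        extreme = pd.DataFrame([[-100.0], [100.0]], columns=["f0"])
        scores = predict(model, extreme)
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_empty_sample_set(self, separated):
        spec = ModelSpec(method="glm_all")
        model = train_model(separated, spec, seed=0)
        assert predict(model, separated.features.iloc[:0]).size == 0

    def test_feature_mismatch_rejected(self, separated):
        model = train_model(separated, ModelSpec(method="glm_all"), seed=0)
        renamed = separated.features.rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="feature names"):
            predict(model, renamed)

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            train_model(_dataset(X, np.zeros(10)), ModelSpec(method="glm_all"), seed=0)


class TestEnsemble:
    def test_mean_and_identity(self):
        assert ensemble_predict([0.4], [0.6])[0] == pytest.approx(0.5)
        x = np.array([0.1, 0.9, 0.5])
        assert np.array_equal(ensemble_predict(x, x), x)

    def test_matches_elementwise_oracle_and_bounds(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(size=50), rng.uniform(size=50)
        out = ensemble_predict(a, b)
        assert np.allclose(out, (a + b) / 2)
        assert (out >= np.minimum(a, b)).all() and (out <= np.maximum(a, b)).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ensemble_predict([0.1, 0.2], [0.3])


class TestAUC:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = 60
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            labels[0], labels[1] = 0, 1
            auc, _ = roc_auc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_equals_trapezoid_under_roc(self):
        rng = np.random.default_rng(10)
        scores = rng.uniform(size=100)
        labels = (scores + rng.normal(0, 0.3, 100) > 0.5).astype(int)
        labels[:2] = [0, 1]
        auc, (fpr, tpr) = roc_auc(scores, labels)
        assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestCrossValidate:
    def test_single_iteration_stats(self, separated):
        spec = ModelSpec(method="glm_all")
        res = cross_validate(separated, spec, n_iter=1, base_seed=3)
        assert len(res.aucs) == 1
        assert res.mean_auc == res.aucs[0]
        assert res.sd_auc == 0.0

    def test_deterministic_under_base_seed(self, separated):
        spec = ModelSpec(method="gbm", **TINY_SPEC)
        r1 = cross_validate(separated, spec, n_iter=3, base_seed=11)
        r2 = cross_validate(separated, spec, n_iter=3, base_seed=11)
        assert r1.aucs == r2.aucs

    def test_null_labels_give_chance_auc(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200, 15))
        y = np.repeat([0, 1], 100)
        rng.shuffle(y)
        data = _dataset(X, y)
        for method in ("glm_all", "gbm"):
            spec = ModelSpec(method=method, **TINY_SPEC)
            res = cross_validate(data, spec, n_iter=5, base_seed=0)
            assert 0.35 <= res.mean_auc <= 0.65

    def test_json_round_trip(self, separated, tmp_path):
        import json

        res = cross_validate(separated, ModelSpec(method="glm_all"), n_iter=2, base_seed=1)
        path = tmp_path / "cv.json"
        res.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["aucs"] == res.aucs
        assert payload["mean_auc"] == pytest.approx(res.mean_auc)
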