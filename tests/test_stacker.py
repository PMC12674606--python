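"""Base registry, out-of-fold stacking, composite features, meta-learner,
full pipeline and the score-ensemble baseline."""

import dataclasses

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

from rpslearner import (
    LabelVector,
    MetaModel,
    RPSConfig,
    RPSLearner,
    build_composite,
    filter_registry,
    fit_meta,
    make_base_registry,
    oof_base_predictions,
    score_ensemble_fit_predict,
)
from rpslearner.stacker import (
    _BASE_SEED_OFFSET,
    _RP_SEED_OFFSET,
    BaseModelSpec,
    BasePredictions,
    CompositeFeatures,
    predict_base_models,
)

EXPECTED_NAMES = ["KNN-D", "KNN-U", "RF-G", "RF-E", "ET-G", "ET-E", "LGBM", "HGB", "XGB", "NN"]


class MemorizingClassifier(BaseEstimator, ClassifierMixin):
    """Pathological learner: returns a sample's own training label if the
    sample was seen during fit, else class 0.  Distinguishes leakage-safe
    out-of-fold stacking (all predictions fall back to class 0) from leaky
    fit-on-all stacking (predictions reproduce y perfectly)."""

    def fit(self, X, y):
        self.memory_ = {tuple(np.round(row, 9)): int(lbl) for row, lbl in zip(X, y)}
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        out = np.zeros((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            lbl = self.memory_.get(tuple(np.round(row, 9)), int(self.classes_[0]))
            out[i, np.searchsorted(self.classes_, lbl)] = 1.0
        return out

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class TestBaseRegistry:
    def test_ten_named_models_in_fixed_order(self):
        specs = make_base_registry(seed=0)
        assert [s.name for s in specs] == EXPECTED_NAMES

    def test_every_model_fits_a_toy_problem(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 1, (20, 10)), rng.normal(2, 1, (20, 10))])
        y = np.array([0] * 20 + [1] * 20)
        for spec in make_base_registry(seed=1):
            est = spec.build()
            est.fit(X, y)
            pred = est.predict(X)
            assert set(np.unique(pred)) <= {0, 1}, spec.name
            proba = est.predict_proba(X)
            np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_top_k_filter_preserves_order(self):
        specs = make_base_registry(seed=0)
        top3 = filter_registry(specs, ["NN", "LGBM", "RF-G"])
        assert [s.name for s in top3] == ["RF-G", "LGBM", "NN"]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown base model"):
            filter_registry(make_base_registry(0), ["SVM"])


@pytest.fixture
def oof_problem():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 6))
    y = LabelVector(labels=list(rng.choice(["a", "b"], size=40)), positive_class="b")
    return X, y


class TestOutOfFoldStacking:
    def test_leakage_detector(self, oof_problem):
        X, y = oof_problem
        spec = BaseModelSpec("MEM", MemorizingClassifier(), 0)
        oof, fitted = oof_base_predictions(X, y, [spec], inner_folds=5, seed=0)
        # out-of-fold: no model ever saw its test rows -> constant fallback
        assert oof.provenance == "out_of_fold"
        assert np.all(oof.hard_labels[:, 0] == 0)
        # refit on all rows: a leaky construction would reproduce y exactly
        leaky = predict_base_models(fitted, X, C=2)
        np.testing.assert_array_equal(leaky.hard_labels[:, 0], y.as_int())

    def test_probability_slices_on_simplex_and_argmax(self, oof_problem):
        X, y = oof_problem
        specs = filter_registry(make_base_registry(0), ["KNN-U", "RF-G"])
        oof, _ = oof_base_predictions(X, y, specs, inner_folds=4, seed=1)
        assert oof.probabilities.shape == (40, 2, 2)
        np.testing.assert_allclose(oof.probabilities.sum(axis=2), 1.0, atol=1e-6)
        np.testing.assert_array_equal(oof.hard_labels, oof.probabilities.argmax(axis=2))

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            y = LabelVector(labels=["a"] * 10, positive_class="a")

    def test_small_class_advises_fewer_folds(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        y = LabelVector(labels=["a"] * 9 + ["b"] * 3, positive_class="b")
        with pytest.raises(ValueError, match="fewer"):
            oof_base_predictions(X, y, [BaseModelSpec("MEM", MemorizingClassifier(), 0)], 5, 0)


class TestBuildComposite:
    def _preds(self, n, N, C, rng):
        probs = rng.dirichlet(np.ones(C), size=(n, N))
        return BasePredictions(
            hard_labels=probs.argmax(axis=2), probabilities=probs, provenance="out_of_fold"
        )

    def test_binary_hard_label_width(self):
        rng = np.random.default_rng(0)
        fused = rng.normal(size=(30, 8000))  # m=20, k=400
        comp = build_composite(fused, self._preds(30, 10, 2, rng), "hard_labels")
        assert comp.values.shape == (30, 8010)
        np.testing.assert_array_equal(comp.values[:, :8000], fused)

    def test_probability_mode_width(self):
        rng = np.random.default_rng(1)
        fused = rng.normal(size=(12, 40))
        comp = build_composite(fused, self._preds(12, 10, 2, rng), "probabilities")
        assert comp.meta_width == 20

    def test_multiclass_hard_labels_one_hot(self):
        rng = np.random.default_rng(2)
        fused = rng.normal(size=(9, 5))
        preds = self._preds(9, 3, 4, rng)
        comp = build_composite(fused, preds, "hard_labels")
        assert comp.meta_width == 12
        meta = comp.values[:, 5:].reshape(9, 3, 4)
        np.testing.assert_array_equal(meta.argmax(axis=2), preds.hard_labels)
        np.testing.assert_allclose(meta.sum(axis=2), 1.0)

    def test_empty_registry_degenerates_to_fused(self):
        fused = np.random.default_rng(3).normal(size=(6, 10))
        comp = build_composite(fused, None, "hard_labels")
        np.testing.assert_array_equal(comp.values, fused)
        assert comp.meta_width == 0

    def test_row_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="row mismatch"):
            build_composite(rng.normal(size=(5, 3)), self._preds(6, 2, 2, rng), "hard_labels")


class TestMetaModel:
    def _blobs(self, n=200, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(0, 1, (n // 2, 10)), rng.normal(sep, 1, (n - n // 2, 10))]
        )
        y = np.array([0] * (n // 2) + [1] * (n - n // 2))
        perm = rng.permutation(n)
        return X[perm], y[perm]

    def test_separable_blobs_learned(self):
        X, y = self._blobs()
        meta = MetaModel(n_classes=2, epochs=300, seed=1)
        meta.fit(X, y)
        assert np.mean(meta.predict(X) == y) >= 0.95

    def test_probabilities_on_simplex(self):
        X, y = self._blobs(n=80)
        meta = MetaModel(n_classes=2, epochs=50, seed=2).fit(X, y)
        np.testing.assert_allclose(meta.predict_proba(X).sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_determinism(self):
        X, y = self._blobs(n=80)
        p1 = MetaModel(n_classes=2, epochs=100, seed=3).fit(X, y).predict_proba(X)
        p2 = MetaModel(n_classes=2, epochs=100, seed=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_non_finite_input_rejected(self):
        X, y = self._blobs(n=40)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            MetaModel(n_classes=2, epochs=10, seed=0).fit(X, y)

    def test_fit_meta_row_mismatch_rejected(self):
        comp = CompositeFeatures(values=np.zeros((5, 4)), fused_width=4, meta_width=0)
        y = LabelVector(labels=["a", "b"] * 3, positive_class="b")
        with pytest.raises(ValueError, match="rows"):
            fit_meta(comp, y, RPSConfig())


FAST_CFG = dict(k=20, m=2, inner_folds=3, epochs=300)


class TestRPSLearnerPipeline:
    def test_fit_predict_consistency(self, small_dataset):
        X, y, _ = small_dataset
        model = RPSLearner(RPSConfig(seed=5, **FAST_CFG)).fit(X, y)
        labels, probs = model.predict(X)
        assert len(labels) == X.n_samples
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        # argmax of probabilities equals returned labels
        assert labels == [model.label_set_[i] for i in probs.argmax(axis=1)]
        # separable training data is learned
        assert np.mean(np.array(labels) == np.array(y.labels)) >= 0.95

    def test_stored_rp_seeds_match_config(self, small_dataset):
        X, y, _ = small_dataset
        cfg = RPSConfig(seed=9, **FAST_CFG)
        model = RPSLearner(cfg).fit(X, y)
        assert model.rp_seeds_ == [cfg.seed + _RP_SEED_OFFSET + i for i in range(cfg.m)]

    def test_deterministic_given_seed(self, small_dataset):
        X, y, _ = small_dataset
        p1 = RPSLearner(RPSConfig(seed=7, **FAST_CFG)).fit(X, y).predict_proba(X)
        p2 = RPSLearner(RPSConfig(seed=7, **FAST_CFG)).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_gene_permutation_invariance(self, small_dataset):
        X, y, _ = small_dataset
        model = RPSLearner(RPSConfig(seed=3, **FAST_CFG)).fit(X, y)
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.n_genes)
        X_perm = dataclasses.replace(
            X,
            values=X.values[:, perm],
            gene_ids=[X.gene_ids[j] for j in perm],
        )
        np.testing.assert_allclose(
            model.predict_proba(X_perm), model.predict_proba(X), atol=1e-10
        )

    def test_missing_genes_rejected(self, small_dataset):
        X, y, _ = small_dataset
        model = RPSLearner(RPSConfig(seed=3, **FAST_CFG)).fit(X, y)
        X_sub = dataclasses.replace(
            X, values=X.values[:, :-5], gene_ids=X.gene_ids[:-5]
        )
        with pytest.raises(ValueError, match="missing"):
            model.predict(X_sub)

    def test_save_load_round_trip(self, small_dataset, tmp_path):
        X, y, _ = small_dataset
        model = RPSLearner(RPSConfig(seed=11, **FAST_CFG)).fit(X, y)
        before = model.predict_proba(X)
        model.save(tmp_path / "model.joblib")
        loaded = RPSLearner.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(loaded.predict_proba(X), before)
        assert loaded.label_set_ == model.label_set_

    def test_too_few_samples_rejected(self, small_dataset):
        X, y, _ = small_dataset
        cfg = RPSConfig(seed=0, k=5, m=1, inner_folds=5)
        Xs = X.subset_rows(np.arange(6))
        ys = LabelVector(labels=y.labels[:6], label_set=y.label_set, positive_class=y.positive_class)
        with pytest.raises(ValueError, match="samples"):
            RPSLearner(cfg).fit(Xs, ys)


class TestScoreEnsemble:
    def test_single_run_degenerate_mean(self, small_dataset):
        X, y, _ = small_dataset
        cfg = RPSConfig(seed=2, k=15, m=1, inner_folds=3)
        probs = score_ensemble_fit_predict(X, y, cfg, X)
        # m=1: identical to one NN trained on the single projection
        from rpslearner.rproject import make_rp_matrix, project

        spec = filter_registry(make_base_registry(cfg.seed + _BASE_SEED_OFFSET), ["NN"])[0]
        R = make_rp_matrix(X.n_genes, cfg.k, cfg.seed + _RP_SEED_OFFSET)
        est = spec.build().fit(project(X.values, R), y.as_int())
        np.testing.assert_allclose(probs, est.predict_proba(project(X.values, R)))

    def test_mean_stays_on_simplex(self, small_dataset):
        X, y, _ = small_dataset
        cfg = RPSConfig(seed=4, k=10, m=3, inner_folds=3)
        probs = score_ensemble_fit_predict(X, y, cfg, X)
        assert probs.shape == (X.n_samples, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
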