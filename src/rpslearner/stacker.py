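"""Stacked-generalization classifier over fused random projections.

The pipeline: fuse m independent Gaussian random projections of the log-scale
expression matrix into an n × (m·k) feature block; fit a heterogeneous
registry of ten base classifiers; append their out-of-fold predictions to the
fused block as a composite feature z(x); train a 4-layer MLP meta-learner
g(·) on z(x); predict ŷ = argmax g(z(x)).

Base predictions used for meta-training are out-of-fold (inner stratified
k-fold), so no base model ever predicts a sample it was trained on — the
standard stacking remedy for meta-learner leakage.  For inference the base
models are refit on the full training set.

A score-ensemble baseline (one classifier per projection, probabilities
averaged) is provided for comparison with feature fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .preprocess import ExpressionMatrix, LabelVector
from .rproject import FusedFeatures, fuse_projections, make_rp_matrix, project

logger = logging.getLogger("rpslearner")

# deterministic seed fan-out offsets (documented in run manifests)
_RP_SEED_OFFSET = 0
_SPLIT_SEED_OFFSET = 101
_BASE_SEED_OFFSET = 211
_META_SEED_OFFSET = 307

BASE_MODEL_NAMES = (
    "KNN-D", "KNN-U", "RF-G", "RF-E", "ET-G", "ET-E", "LGBM", "HGB", "XGB", "NN",
)


@dataclass
class RPSConfig:
    """Operating point of the pipeline.

    Defaults reproduce the published operating point: k=400 projected
    dimensions, m=20 independent projections, all ten base models, hard-label
    meta-features, inner 5-fold out-of-fold stacking, and the meta-learner
    training budget (1000 epochs, batch 64, Adam lr 1e-4, dropout 0.2).
    """

    k: int = 400
    m: int = 20
    base_names: tuple = BASE_MODEL_NAMES
    meta_mode: str = "hard_labels"  # or "probabilities"
    inner_folds: int = 5
    epochs: int = 1000
    batch_size: int = 64
    learning_rate: float = 1e-4
    dropout: float = 0.2
    hidden_layers: tuple = (128, 64, 32, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.meta_mode not in ("hard_labels", "probabilities"):
            raise ValueError(f"unknown meta_mode {self.meta_mode!r}")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_names"] = list(self.base_names)
        d["hidden_layers"] = list(self.hidden_layers)
        return d


# ------------------------------------------------------------ base registry


@dataclass
class BaseModelSpec:
    """A named base classifier: sklearn-style estimator template plus seed."""

    name: str
    estimator: object
    seed: int

    def build(self):
        return clone(self.estimator)


def make_base_registry(seed: int = 0) -> list[BaseModelSpec]:
    """The ten heterogeneous base classifiers, in fixed order.

    KNN with distance / uniform weighting, random forests and extra-trees
    with gini / entropy splits, LightGBM, histogram gradient boosting,
    XGBoost, and a small feed-forward network.  Hyperparameters are library
    defaults pinned here; all randomness is seeded and single-threaded for
    reproducibility.
    """
    import lightgbm
    import xgboost

    specs = [
        BaseModelSpec("KNN-D", KNeighborsClassifier(n_neighbors=5, weights="distance"), seed),
        BaseModelSpec("KNN-U", KNeighborsClassifier(n_neighbors=5, weights="uniform"), seed),
        BaseModelSpec(
            "RF-G",
            RandomForestClassifier(
                n_estimators=100, criterion="gini", random_state=seed, n_jobs=1
            ),
            seed,
        ),
        BaseModelSpec(
            "RF-E",
            RandomForestClassifier(
                n_estimators=100, criterion="entropy", random_state=seed + 1, n_jobs=1
            ),
            seed + 1,
        ),
        BaseModelSpec(
            "ET-G",
            ExtraTreesClassifier(
                n_estimators=100, criterion="gini", random_state=seed + 2, n_jobs=1
            ),
            seed + 2,
        ),
        BaseModelSpec(
            "ET-E",
            ExtraTreesClassifier(
                n_estimators=100, criterion="entropy", random_state=seed + 3, n_jobs=1
            ),
            seed + 3,
        ),
        BaseModelSpec(
            "LGBM",
            lightgbm.LGBMClassifier(
                n_estimators=100, random_state=seed + 4, n_jobs=1, verbose=-1
            ),
            seed + 4,
        ),
        BaseModelSpec(
            "HGB",
            HistGradientBoostingClassifier(random_state=seed + 5),
            seed + 5,
        ),
        BaseModelSpec(
            "XGB",
            xgboost.XGBClassifier(
                n_estimators=100,
                random_state=seed + 6,
                n_jobs=1,
                verbosity=0,
                eval_metric="logloss",
            ),
            seed + 6,
        ),
        BaseModelSpec(
            "NN",
            MLPClassifier(
                hidden_layer_sizes=(64, 32),
                max_iter=300,
                random_state=seed + 7,
            ),
            seed + 7,
        ),
    ]
    return specs


def filter_registry(specs: list[BaseModelSpec], names) -> list[BaseModelSpec]:
    """Subset the registry to the given names, preserving registry order."""
    names = set(names)
    unknown = names - {s.name for s in specs}
    if unknown:
        raise ValueError(f"unknown base model names: {sorted(unknown)}")
    return [s for s in specs if s.name in names]


# ----------------------------------------------------- out-of-fold stacking


@dataclass
class BasePredictions:
    """Per-base-model predictions for every sample.

    ``probabilities`` has shape (n, N, C) with each (sample, model) slice on
    the probability simplex; ``hard_labels`` is the (n, N) argmax as integer
    class codes.  ``provenance`` records whether predictions are out-of-fold
    (leakage-safe, for meta-training) or from models refit on all rows.
    """

    hard_labels: np.ndarray
    probabilities: np.ndarray
    provenance: str
    model_names: list[str] = field(default_factory=list)


def _as_feature_array(features) -> np.ndarray:
    if isinstance(features, FusedFeatures):
        return features.values
    return np.asarray(features, dtype=float)


def oof_base_predictions(
    features,
    labels: LabelVector,
    specs: list[BaseModelSpec],
    inner_folds: int = 5,
    seed: int = 0,
):
    """Leakage-safe base predictions plus refit-on-full models.

    Each sample's prediction comes from base models never trained on that
    sample (inner stratified k-fold).  Returns ``(BasePredictions with
    provenance=out_of_fold, fitted_models)`` where ``fitted_models`` are the
    specs refit on all rows for inference-time use.
    """
    X = _as_feature_array(features)
    y = labels.as_int()
    n, C = len(y), labels.n_classes
    counts = np.bincount(y, minlength=C)
    if np.any(counts == 0) or C < 2:
        raise ValueError("stratification impossible: need every class represented")
    if counts.min() < inner_folds:
        raise ValueError(
            f"class with {counts.min()} members < inner_folds={inner_folds}; "
            "use fewer inner folds"
        )
    N = len(specs)
    probs = np.zeros((n, N, C))
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        for j, spec in enumerate(specs):
            est = spec.build()
            est.fit(X[tr], y[tr])
            probs[te, j, :] = _predict_proba_full(est, X[te], C)
    fitted = []
    for spec in specs:
        est = spec.build()
        est.fit(X, y)
        fitted.append(est)
    hard = probs.argmax(axis=2)
    preds = BasePredictions(
        hard_labels=hard,
        probabilities=probs,
        provenance="out_of_fold",
        model_names=[s.name for s in specs],
    )
    return preds, fitted


def predict_base_models(fitted, features, C: int, names=None) -> BasePredictions:
    """Predictions from already-fitted base models (provenance=refit_full)."""
    X = _as_feature_array(features)
    N = len(fitted)
    probs = np.zeros((X.shape[0], N, C))
    for j, est in enumerate(fitted):
        probs[:, j, :] = _predict_proba_full(est, X, C)
    return BasePredictions(
        hard_labels=probs.argmax(axis=2),
        probabilities=probs,
        provenance="refit_full",
        model_names=list(names) if names else [],
    )


def _predict_proba_full(est, X, C: int) -> np.ndarray:
    """predict_proba padded to all C classes (trained folds always see all
    classes under stratification, but a custom estimator might not)."""
    p = est.predict_proba(X)
    classes = np.asarray(est.classes_, dtype=int)
    out = np.zeros((X.shape[0], C))
    out[:, classes] = p
    return out


# --------------------------------------------------------- composite z(x)


@dataclass
class CompositeFeatures:
    """Fused RP features with base-model meta-features appended: z(x)."""

    values: np.ndarray
    fused_width: int
    meta_width: int


def build_composite(fused, preds: BasePredictions | None, mode: str = "hard_labels") -> CompositeFeatures:
    """Concatenate [fused | meta-features] column-wise.

    ``hard_labels`` mode appends integer class codes for binary problems and
    a one-hot encoding otherwise (keeps the block numeric and order-free);
    ``probabilities`` mode appends the full (N·C) probability block.
    """
    X = _as_feature_array(fused)
    if preds is None or preds.probabilities.shape[1] == 0:
        return CompositeFeatures(values=X, fused_width=X.shape[1], meta_width=0)
    if preds.probabilities.shape[0] != X.shape[0]:
        raise ValueError(
            f"row mismatch: fused has {X.shape[0]} rows, "
            f"predictions have {preds.probabilities.shape[0]}"
        )
    n, N, C = preds.probabilities.shape
    if mode == "probabilities":
        meta = preds.probabilities.reshape(n, N * C)
    elif mode == "hard_labels":
        if C == 2:
            meta = preds.hard_labels.astype(float)
        else:
            meta = np.zeros((n, N * C))
            for j in range(N):
                meta[np.arange(n), j * C + preds.hard_labels[:, j]] = 1.0
    else:
        raise ValueError(f"unknown meta-feature mode {mode!r}")
    return CompositeFeatures(
        values=np.hstack([X, meta]), fused_width=X.shape[1], meta_width=meta.shape[1]
    )


# ------------------------------------------------------- MLP meta-learner


class MetaModel:
    """Fully connected meta-learner g(·): hidden layers 128-64-32-16, ReLU,
    dropout, softmax output over the C classes.

    Trained with cross-entropy, Adam, and class-weighted random sampling
    (each example drawn with probability inversely proportional to its class
    frequency, with replacement, n draws per epoch) so minority classes are
    seen as often as majority ones.  Inputs are z-scored internally; all
    randomness flows from one seed, so training is bit-reproducible.
    """

    def __init__(
        self,
        n_classes: int,
        hidden_layers=(128, 64, 32, 16),
        dropout: float = 0.2,
        learning_rate: float = 1e-4,
        epochs: int = 1000,
        batch_size: int = 64,
        seed: int = 0,
    ):
        self.n_classes = n_classes
        self.hidden_layers = tuple(hidden_layers)
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self._mu = None
        self._sigma = None

    # -- internals

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features, *self.hidden_layers, self.n_classes]
        W, b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization suits the ReLU hidden stack
            W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            b.append(np.zeros(fan_out))
        return W, b

    def _forward(self, X, rng=None):
        """Returns (activations per layer, dropout masks); rng=None → eval mode."""
        acts = [X]
        masks = []
        h = X
        L = len(self.weights_)
        for i in range(L - 1):
            h = np.maximum(h @ self.weights_[i] + self.biases_[i], 0.0)
            if rng is not None and self.dropout > 0:
                keep = 1.0 - self.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        logits = h @ self.weights_[-1] + self.biases_[-1]
        acts.append(logits)
        return acts, masks

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MetaModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in meta-learner input")
        rng = np.random.default_rng(self.seed)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sigma = np.where(sd == 0, 1.0, sd)
        Xs = (X - self._mu) / self._sigma

        n = X.shape[0]
        self.weights_, self.biases_ = self._init_params(X.shape[1], rng)
        params = self.weights_ + self.biases_
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        freq = np.bincount(y, minlength=self.n_classes).astype(float)
        w = 1.0 / freq[y]
        w = w / w.sum()

        for _ in range(self.epochs):
            idx = rng.choice(n, size=n, replace=True, p=w)
            for start in range(0, n, self.batch_size):
                batch = idx[start : start + self.batch_size]
                Xb, yb = Xs[batch], y[batch]
                acts, masks = self._forward(Xb, rng=rng)
                probs = self._softmax(acts[-1])
                # backprop of mean cross-entropy
                grad = probs.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad /= len(yb)
                gW = [None] * len(self.weights_)
                gb = [None] * len(self.biases_)
                for i in range(len(self.weights_) - 1, -1, -1):
                    gW[i] = acts[i].T @ grad
                    gb[i] = grad.sum(axis=0)
                    if i > 0:
                        grad = grad @ self.weights_[i].T
                        if masks[i - 1] is not None:
                            grad = grad * masks[i - 1]
                        grad = grad * (acts[i] > 0)
                t += 1
                grads = gW + gb
                for j, (p, g) in enumerate(zip(params, grads)):
                    m_adam[j] = beta1 * m_adam[j] + (1 - beta1) * g
                    v_adam[j] = beta2 * v_adam[j] + (1 - beta2) * g * g
                    mhat = m_adam[j] / (1 - beta1**t)
                    vhat = v_adam[j] / (1 - beta2**t)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("meta-learner is not fitted")
        X = np.asarray(X, dtype=float)
        Xs = (X - self._mu) / self._sigma
        acts, _ = self._forward(Xs, rng=None)
        return self._softmax(acts[-1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def fit_meta(composite: CompositeFeatures, labels: LabelVector, cfg: RPSConfig) -> MetaModel:
    """Train the MLP meta-learner on composite features."""
    if composite.values.shape[0] != len(labels):
        raise ValueError(
            f"composite has {composite.values.shape[0]} rows but {len(labels)} labels"
        )
    meta = MetaModel(
        n_classes=labels.n_classes,
        hidden_layers=cfg.hidden_layers,
        dropout=cfg.dropout,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed + _META_SEED_OFFSET,
    )
    meta.fit(composite.values, labels.as_int())
    return meta


# ---------------------------------------------------------- full pipeline


class RPSLearner:
    """The full classifier: RP fusion → base stack → MLP meta-learner.

    After :meth:`fit` the model archive holds the RP seeds (projections are
    regenerated from seed at predict time), the refit base models, the meta
    weights, the label set and gene order, and the config.
    """

    def __init__(self, cfg: RPSConfig | None = None):
        self.cfg = cfg or RPSConfig()
        self.gene_ids_: list[str] | None = None
        self.label_set_: list[str] | None = None
        self.positive_class_: str | None = None
        self.rp_seeds_: list[int] | None = None
        self.base_models_: list | None = None
        self.base_names_: list[str] | None = None
        self.meta_: MetaModel | None = None

    # fit --------------------------------------------------------------

    def fit(self, X: ExpressionMatrix, y: LabelVector, specs=None) -> "RPSLearner":
        cfg = self.cfg
        if len(y) != X.n_samples:
            raise ValueError(f"{X.n_samples} samples but {len(y)} labels")
        if X.n_samples < 2 * cfg.inner_folds:
            raise ValueError(
                f"need at least {2 * cfg.inner_folds} samples for inner "
                f"{cfg.inner_folds}-fold stacking, got {X.n_samples}"
            )
        if specs is None:
            specs = filter_registry(
                make_base_registry(cfg.seed + _BASE_SEED_OFFSET), cfg.base_names
            )
        try:
            fused = fuse_projections(X, cfg.k, cfg.m, cfg.seed + _RP_SEED_OFFSET)
        except Exception as e:  # pragma: no cover - defensive relabel
            raise RuntimeError(f"[fuse_projections] {e}") from e
        try:
            oof, fitted = oof_base_predictions(
                fused, y, specs, cfg.inner_folds, cfg.seed + _SPLIT_SEED_OFFSET
            )
        except ValueError as e:
            raise ValueError(f"[oof_base_predictions] {e}") from e
        composite = build_composite(fused, oof, cfg.meta_mode)
        self.meta_ = fit_meta(composite, y, cfg)
        self.gene_ids_ = list(X.gene_ids)
        self.label_set_ = list(y.label_set)
        self.positive_class_ = y.positive_class
        self.rp_seeds_ = list(fused.source_seeds)
        self.base_models_ = fitted
        self.base_names_ = [s.name for s in specs]
        return self

    # predict ----------------------------------------------------------

    def _align(self, Xnew: ExpressionMatrix) -> np.ndarray:
        missing = [g for g in self.gene_ids_ if g not in set(Xnew.gene_ids)]
        if missing:
            raise ValueError(
                f"{len(missing)} training genes missing from input, e.g. {missing[:5]}"
            )
        pos = {g: i for i, g in enumerate(Xnew.gene_ids)}
        order = [pos[g] for g in self.gene_ids_]
        return Xnew.values[:, order]

    def predict_proba(self, Xnew: ExpressionMatrix) -> np.ndarray:
        if self.meta_ is None:
            raise RuntimeError("model is not fitted")
        vals = self._align(Xnew)
        d = vals.shape[1]
        blocks = [
            project(vals, make_rp_matrix(d, self.cfg.k, s)) for s in self.rp_seeds_
        ]
        fused = np.hstack(blocks)
        preds = predict_base_models(
            self.base_models_, fused, len(self.label_set_), self.base_names_
        )
        composite = build_composite(fused, preds, self.cfg.meta_mode)
        return self.meta_.predict_proba(composite.values)

    def predict(self, Xnew: ExpressionMatrix):
        """Returns (labels, per-class probabilities in label_set order)."""
        probs = self.predict_proba(Xnew)
        labels = [self.label_set_[i] for i in probs.argmax(axis=1)]
        return labels, probs

    # archive ----------------------------------------------------------

    def save(self, path) -> None:
        from . import __version__

        joblib.dump(
            {
                "format": "rpslearner-model",
                "version": __version__,
                "cfg": self.cfg.to_dict(),
                "gene_ids": self.gene_ids_,
                "label_set": self.label_set_,
                "positive_class": self.positive_class_,
                "rp_seeds": self.rp_seeds_,
                "base_models": self.base_models_,
                "base_names": self.base_names_,
                "meta": self.meta_,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "RPSLearner":
        blob = joblib.load(path)
        if blob.get("format") != "rpslearner-model":
            raise ValueError(f"{path} is not a model archive")
        cfg_d = dict(blob["cfg"])
        cfg_d["base_names"] = tuple(cfg_d["base_names"])
        cfg_d["hidden_layers"] = tuple(cfg_d["hidden_layers"])
        model = cls(RPSConfig(**cfg_d))
        model.gene_ids_ = blob["gene_ids"]
        model.label_set_ = blob["label_set"]
        model.positive_class_ = blob["positive_class"]
        model.rp_seeds_ = blob["rp_seeds"]
        model.base_models_ = blob["base_models"]
        model.base_names_ = blob["base_names"]
        model.meta_ = blob["meta"]
        return model


# ----------------------------------------------------- score-ensemble baseline


def score_ensemble_fit_predict(
    X: ExpressionMatrix,
    y: LabelVector,
    cfg: RPSConfig,
    Xnew: ExpressionMatrix,
    base_name: str = "NN",
) -> np.ndarray:
    """Comparator strategy: one classifier per projection, probabilities averaged.

    For each of the m RP matrices independently, one ``base_name`` classifier
    is trained on that single k-dimensional projection of the training data;
    the final per-class probability for new samples is the unweighted mean of
    the m runs.  Returns an (n_new, C) array in label_set order.
    """
    spec = filter_registry(make_base_registry(cfg.seed + _BASE_SEED_OFFSET), [base_name])[0]
    y_int = y.as_int()
    C = y.n_classes
    d = X.n_genes
    gene_pos = {g: i for i, g in enumerate(Xnew.gene_ids)}
    missing = [g for g in X.gene_ids if g not in gene_pos]
    if missing:
        raise ValueError(f"genes missing from prediction input: {missing[:5]}")
    new_vals = Xnew.values[:, [gene_pos[g] for g in X.gene_ids]]
    acc = np.zeros((Xnew.n_samples, C))
    for i in range(cfg.m):
        R = make_rp_matrix(d, cfg.k, cfg.seed + _RP_SEED_OFFSET + i)
        est = spec.build()
        est.fit(project(X.values, R), y_int)
        acc += _predict_proba_full(est, project(new_vals, R), C)
    return acc / cfg.m
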