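"""Gradient boosting with a random-forest weak learner (GBBRF).

Classic gradient tree boosting fits one shallow regression tree per round to
the pseudo-residuals of the binary log-loss.  GBBRF replaces the single tree
with a small random forest: each round fits ``trees_per_round`` regression
trees on bootstrap row samples with feature subsampling, replaces every leaf
value by the regularised one-step Newton estimate

    gamma = sum_{i in leaf} (y_i - p_i) / (sum_{i in leaf} p_i (1 - p_i) + lambda)

and adds the forest average, shrunk by the learning rate, to the additive
score.  The model is initialised at the log-odds f0 = ln(n_pos / n_neg) and
predicts logistic(F_M(x)).

Tree structures are grown with scikit-learn regression trees (variance
reduction splits, minimum two samples per leaf); leaf gammas are computed on
all training rows routed to the leaf, which is the exact Newton step for the
current loss and keeps the training log-loss non-increasing at small
learning rates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import expit
from sklearn.tree import DecisionTreeRegressor

from .errors import ClassBalanceError, ShapeError
from .resampling import LabeledDataset

_EPS = 1e-15


@dataclass(frozen=True)
class GBBRFConfig:
    """Boosting hyperparameters.

    Defaults follow the regularisation used for disease-gene prediction:
    learning rate 0.1, lambda 5, individual tree depth 3, 500 rounds.
    ``feature_fraction=None`` means sqrt(p)/p features per split.
    """

    n_rounds: int = 500
    learning_rate: float = 0.1
    lam: float = 5.0
    max_depth: int = 3
    trees_per_round: int = 10
    feature_fraction: Optional[float] = None
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_depth < 1 or self.trees_per_round < 1:
            raise ValueError("max_depth and trees_per_round must be >= 1")
        if self.feature_fraction is not None and not (0.0 < self.feature_fraction <= 1.0):
            raise ValueError("feature_fraction must be in (0, 1]")


@dataclass
class _TreeArrays:
    """Flat array form of one fitted regression tree with Newton leaf values."""

    feature: np.ndarray    # split feature per node; -2 marks a leaf
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray      # gamma at leaves, 0 elsewhere

    def apply(self, x: np.ndarray) -> np.ndarray:
        node = np.zeros(x.shape[0], dtype=np.intp)
        while True:
            feat = self.feature[node]
            interior = feat >= 0
            if not interior.any():
                return node
            idx = np.flatnonzero(interior)
            go_left = x[idx, feat[idx]] <= self.threshold[node[idx]]
            node[idx] = np.where(
                go_left, self.left[node[idx]], self.right[node[idx]]
            )

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.value[self.apply(x)]

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in vars(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "_TreeArrays":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.intp),
            right=np.asarray(d["right"], dtype=np.intp),
            value=np.asarray(d["value"], dtype=float),
        )


@dataclass
class GBBRFModel:
    """Baseline log-odds plus an ordered list of shrunken forest learners."""

    f0: float
    config: GBBRFConfig
    n_features: int
    rounds: List[List[_TreeArrays]] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        x = _check_features(features, self.n_features)
        f = np.full(x.shape[0], self.f0)
        for forest in self.rounds:
            f += self.config.learning_rate * _forest_predict(forest, x)
        return f

    def to_json(self) -> str:
        doc = {
            "f0": self.f0,
            "config": asdict(self.config),
            "n_features": self.n_features,
            "rounds": [[t.to_dict() for t in forest] for forest in self.rounds],
            "train_loss": self.train_loss,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "GBBRFModel":
        doc = json.loads(text)
        return cls(
            f0=doc["f0"],
            config=GBBRFConfig(**doc["config"]),
            n_features=doc["n_features"],
            rounds=[
                [_TreeArrays.from_dict(t) for t in forest]
                for forest in doc["rounds"]
            ],
            train_loss=list(doc["train_loss"]),
        )


def log_loss(labels: Sequence[int], probs: Sequence[float]) -> float:
    """Binary cross-entropy, probabilities clipped to [1e-15, 1 - 1e-15]."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ShapeError(f"labels {y.shape} and probs {p.shape} differ")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _check_features(features, n_features=None) -> np.ndarray:
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("features contain non-finite values")
    if n_features is not None and x.shape[1] != n_features:
        raise ShapeError(
            f"feature width {x.shape[1]} does not match model width {n_features}"
        )
    return x


def _forest_predict(forest: List[_TreeArrays], x: np.ndarray) -> np.ndarray:
    out = np.zeros(x.shape[0])
    for tree in forest:
        out += tree.predict(x)
    return out / len(forest)


def _newton_tree(
    tree: DecisionTreeRegressor, x: np.ndarray, residual: np.ndarray,
    hessian: np.ndarray, lam: float,
) -> _TreeArrays:
    """Export a fitted tree, replacing leaf outputs by the Newton step over
    all training rows routed to each leaf."""
    t = tree.tree_
    leaf_of = tree.apply(x)
    n_nodes = t.node_count
    num = np.bincount(leaf_of, weights=residual, minlength=n_nodes)
    den = np.bincount(leaf_of, weights=hessian, minlength=n_nodes)
    value = np.where(t.children_left == -1, num / (den + lam), 0.0)
    return _TreeArrays(
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        left=t.children_left.copy(),
        right=t.children_right.copy(),
        value=value,
    )


def fit(data: LabeledDataset, cfg: Optional[GBBRFConfig] = None) -> GBBRFModel:
    """Train a GBBRF model on a labelled dataset.

    Each round fits a forest of ``trees_per_round`` regression trees to the
    log-loss pseudo-residuals, replaces leaf values by the regularised
    Newton step, and adds the shrunken forest mean to the score.  The
    training log-loss after each round is recorded in ``model.train_loss``.
    """
    cfg = cfg or GBBRFConfig()
    x = _check_features(data.features)
    y = np.asarray(data.labels, dtype=float)
    n, p = x.shape
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ClassBalanceError("training data must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    if cfg.feature_fraction is None:
        max_features = max(1, round(math.sqrt(p)))
    else:
        max_features = max(1, round(cfg.feature_fraction * p))

    model = GBBRFModel(
        f0=math.log(n_pos / n_neg), config=cfg, n_features=p
    )
    f = np.full(n, model.f0)
    for _m in range(cfg.n_rounds):
        prob = expit(f)
        residual = y - prob
        hessian = prob * (1.0 - prob)
        forest = []
        for _t in range(cfg.trees_per_round):
            idx = rng.integers(0, n, n) if cfg.bootstrap else np.arange(n)
            tree = DecisionTreeRegressor(
                max_depth=cfg.max_depth,
                max_features=max_features,
                min_samples_leaf=2,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(x[idx], residual[idx])
            forest.append(_newton_tree(tree, x, residual, hessian, cfg.lam))
        f += cfg.learning_rate * _forest_predict(forest, x)
        model.rounds.append(forest)
        model.train_loss.append(log_loss(y, expit(f)))
    return model


def predict_proba(model: GBBRFModel, features) -> np.ndarray:
    """Positive-class probability logistic(F_M(x)) per row."""
    return expit(model.decision_function(features))


def predict(model: GBBRFModel, features) -> np.ndarray:
    """Class labels; positive iff probability >= 0.5."""
    return (predict_proba(model, features) >= 0.5).astype(int)


class GBBRFClassifier:
    """Thin scikit-learn-style wrapper around :func:`fit` for use as a base
    learner in stacking."""

    def __init__(self, **config_kwargs):
        self.config_kwargs = config_kwargs
        self.model_: Optional[GBBRFModel] = None
        self.classes_ = np.array([0, 1])

    def get_params(self, deep=True):
        return dict(self.config_kwargs)

    def set_params(self, **params):
        self.config_kwargs.update(params)
        return self

    def fit(self, x, y):
        data = LabeledDataset(features=np.asarray(x), labels=np.asarray(y))
        self.model_ = fit(data, GBBRFConfig(**self.config_kwargs))
        return self

    def predict_proba(self, x):
        p = predict_proba(self.model_, x)
        return np.column_stack([1.0 - p, p])

    def predict(self, x):
        return (predict_proba(self.model_, x) >= 0.5).astype(int)
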