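"""Two-level stacked generalisation.

Level-0 base learners are trained on stratified out-of-fold (OOF) splits of
the training data; each learner contributes one meta-feature column — its
positive-class probability for samples it never saw during that fold's fit.
A level-1 meta-learner is trained on the OOF meta-feature matrix, and the
level-0 learners are refit on the full training data for deployment.

Five named presets combine GBBRF with random forest (RF), support vector
machine (SVM), k-nearest neighbours (KNN), logistic regression (LR) and
Gaussian naive Bayes (NB); ``stacking3`` (RF meta-learner over
GBBRF/NB/SVM/KNN/RF) is the flagship combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ShapeError
from .gbbrf import GBBRFClassifier
from .resampling import LabeledDataset
from .evaluation import stratified_folds


class SVMLearner:
    """SVC with probabilities via a logistic link on decision values."""

    def __init__(self, seed: int = 0, **kwargs):
        kwargs.setdefault("kernel", "rbf")
        self._svc = SVC(random_state=seed, **kwargs)

    @property
    def classes_(self):
        return self._svc.classes_

    def fit(self, x, y):
        self._svc.fit(x, y)
        return self

    def predict_proba(self, x):
        p = expit(self._svc.decision_function(x))
        return np.column_stack([1.0 - p, p])

    def predict(self, x):
        return self._svc.predict(x)


def _make_rf(seed, **kw):
    kw.setdefault("n_estimators", 100)
    return RandomForestClassifier(random_state=seed, **kw)


def _make_knn(seed, **kw):
    kw.setdefault("n_neighbors", 5)
    return KNeighborsClassifier(**kw)


def _make_lr(seed, **kw):
    kw.setdefault("max_iter", 1000)
    return LogisticRegression(random_state=seed, **kw)


#: name -> factory(seed, **params); extend via :func:`register_learner`.
LEARNER_FACTORIES = {
    "RF": _make_rf,
    "SVM": lambda seed, **kw: SVMLearner(seed=seed, **kw),
    "KNN": _make_knn,
    "LR": _make_lr,
    "NB": lambda seed, **kw: GaussianNB(**kw),
    "GBBRF": lambda seed, **kw: GBBRFClassifier(seed=seed, **kw),
}


def register_learner(name: str, factory) -> None:
    """Register an extra base-learner factory ``factory(seed, **params)``."""
    LEARNER_FACTORIES[name] = factory


def make_learner(name: str, seed: int, params: Optional[Mapping] = None):
    if name not in LEARNER_FACTORIES:
        raise ValueError(f"unknown learner {name!r}; known: {sorted(LEARNER_FACTORIES)}")
    return LEARNER_FACTORIES[name](seed, **dict(params or {}))


def positive_proba(estimator, x) -> np.ndarray:
    """Positive-class (label 1) probability column from any learner."""
    proba = np.asarray(estimator.predict_proba(x))
    classes = list(np.asarray(estimator.classes_).tolist())
    return proba[:, classes.index(1)]


@dataclass(frozen=True)
class StackingSpec:
    """Configuration of a two-level stack.

    ``meta_features`` selects whether level-0 learners feed probabilities
    (default) or hard labels to the meta-learner.
    """

    level0: Tuple[str, ...]
    level1: str
    oof_folds: int = 5
    seed: int = 0
    meta_features: str = "proba"
    learner_params: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self):
        if not self.level0:
            raise ValueError("level0 must be non-empty")
        if len(set(self.level0)) != len(self.level0):
            raise ValueError("level0 learner names must be unique")
        if self.meta_features not in ("proba", "label"):
            raise ValueError("meta_features must be 'proba' or 'label'")


#: The five published level-0/level-1 combinations.
PRESETS: Dict[str, StackingSpec] = {
    "stacking1": StackingSpec(level0=("NB", "SVM", "KNN", "RF"), level1="RF"),
    "stacking2": StackingSpec(level0=("RF", "KNN", "SVM", "LR", "GBBRF"), level1="GBBRF"),
    "stacking3": StackingSpec(level0=("GBBRF", "NB", "SVM", "KNN", "RF"), level1="RF"),
    "stacking4": StackingSpec(level0=("GBBRF", "LR", "SVM", "KNN", "RF"), level1="RF"),
    "stacking5": StackingSpec(level0=("GBBRF", "LR", "SVM", "KNN", "RF"), level1="KNN"),
}


def preset(name: str, **overrides) -> StackingSpec:
    """A named preset, optionally with ``seed``/``oof_folds``/... overridden."""
    base = PRESETS[name]
    from dataclasses import replace

    return replace(base, **overrides)


@dataclass
class StackedModel:
    """Fitted two-level stack; level-0 order fixes meta-feature columns."""

    spec: StackingSpec
    level0_models: List
    level1_model: object

    @property
    def level0_names(self) -> Tuple[str, ...]:
        return self.spec.level0


def oof_meta_features(data: LabeledDataset, spec: StackingSpec) -> np.ndarray:
    """n x L matrix of out-of-fold positive-class predictions.

    Column ℓ holds, for every sample, the prediction of learner ℓ trained on
    the stratified folds that exclude that sample's fold, so no learner ever
    sees the label of a sample it scores.
    """
    folds = stratified_folds(data.labels, spec.oof_folds, spec.seed)
    n = data.n
    meta = np.empty((n, len(spec.level0)))
    for col, name in enumerate(spec.level0):
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            est = make_learner(name, spec.seed, spec.learner_params.get(name))
            est.fit(data.features[train_idx], data.labels[train_idx])
            p = positive_proba(est, data.features[test_idx])
            if spec.meta_features == "label":
                p = (p >= 0.5).astype(float)
            meta[test_idx, col] = p
    return meta


def fit_stacked(data: LabeledDataset, spec: StackingSpec) -> StackedModel:
    """Fit the meta-learner on OOF meta-features, then refit every level-0
    learner on the full training data for deployment."""
    meta = oof_meta_features(data, spec)
    level1 = make_learner(spec.level1, spec.seed, spec.learner_params.get(spec.level1))
    level1.fit(meta, data.labels)
    level0_models = []
    for name in spec.level0:
        est = make_learner(name, spec.seed, spec.learner_params.get(name))
        est.fit(data.features, data.labels)
        level0_models.append(est)
    return StackedModel(spec=spec, level0_models=level0_models, level1_model=level1)


def predict_stacked(model: StackedModel, features) -> Tuple[np.ndarray, np.ndarray]:
    """(positive-class probabilities, hard 0/1 classes) for new samples."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    cols = []
    for est in model.level0_models:
        p = positive_proba(est, x)
        if model.spec.meta_features == "label":
            p = (p >= 0.5).astype(float)
        cols.append(p)
    meta = np.column_stack(cols)
    if meta.shape[1] != len(model.spec.level0):
        raise ShapeError("meta-feature width mismatch")
    if len(np.asarray(model.level1_model.classes_)) == 1:
        # degenerate meta input (e.g. constant columns): predict the only class
        only = int(np.asarray(model.level1_model.classes_)[0])
        proba = np.full(x.shape[0], float(only))
        return proba, np.full(x.shape[0], only)
    proba = positive_proba(model.level1_model, meta)
    return proba, (proba >= 0.5).astype(int)
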