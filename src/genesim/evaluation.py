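"""Stratified cross-validation and binary classification metrics.

Metrics follow the standard confusion-matrix definitions — accuracy,
positive-class precision and recall, their harmonic mean (F-measure) — plus
AUC-ROC.  :func:`cross_validate` orchestrates resampling and model fitting
in two pipeline orders:

``safe`` (default)
    Split first, resample only the training folds, evaluate on untouched
    original samples.  No synthetic row can ever reach a test fold.
``paper``
    Resample the whole dataset, shuffle, then split — the order some
    published pipelines use.  Synthetic neighbours of test points leak into
    training, which typically inflates scores; reports are labelled with
    the mode so the two are never confused.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ClassBalanceError, StratificationError
from .resampling import LabeledDataset, ResampleSpec, resample

logger = logging.getLogger(__name__)


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> List[np.ndarray]:
    """k disjoint test-index sets with per-fold class proportions within one
    sample of the global proportions; deterministic given *seed*."""
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("labels contain a single class")
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} member(s), fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _train, test in skf.split(np.zeros(len(y)), y)]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true).astype(int)
        p = np.asarray(y_pred).astype(int)
        if t.shape != p.shape:
            raise ValueError("label/prediction length mismatch")
        return cls(
            tp=int(np.sum((t == 1) & (p == 1))),
            tn=int(np.sum((t == 0) & (p == 0))),
            fp=int(np.sum((t == 0) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == 0))),
        )


def compute_metrics(cm: ConfusionMatrix) -> Dict[str, float]:
    """Accuracy, positive-class precision/recall and F-measure.

    Degenerate denominators yield 0.0 with a logged warning rather than an
    error.
    """

    def _ratio(num, den, name):
        if den == 0:
            logger.warning("undefined %s (zero denominator); reporting 0", name)
            return 0.0
        return num / den

    accuracy = _ratio(cm.tp + cm.tn, cm.total, "accuracy")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    f_measure = _ratio(2 * precision * recall, precision + recall, "f_measure")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
    }


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve: the probability that a random positive
    outranks a random negative, ties counted one half."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ClassBalanceError("AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics for one cross-validated pipeline."""

    per_fold: Dict[str, List[float]]
    mean: Dict[str, float]
    k: int
    seed: int
    mode: str
    model: str
    resample_method: str
    pooling: str = "mean"
    n_synthetic_in_test: int = 0
    fold_sizes: List[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "model": self.model,
            "resample": self.resample_method,
            "k": self.k,
            "seed": self.seed,
            "pooling": self.pooling,
            "per_fold": self.per_fold,
            "mean": self.mean,
            "fold_sizes": self.fold_sizes,
            "n_synthetic_in_test": self.n_synthetic_in_test,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _fit_predict(train: LabeledDataset, test_x: np.ndarray, model_spec, seed: int):
    """Fit the requested model on *train* and score *test_x*.

    *model_spec* is a :class:`~genesim.stacking.StackingSpec`, a preset name
    (``stacking1``..``stacking5``), a base-learner name (``GBBRF``, ``RF``,
    ...), or a ``(name, params)`` pair.  Returns positive-class
    probabilities.
    """
    from . import stacking

    if isinstance(model_spec, str) and model_spec in stacking.PRESETS:
        model_spec = stacking.preset(model_spec, seed=seed)
    if isinstance(model_spec, stacking.StackingSpec):
        spec = replace(model_spec, seed=seed)
        model = stacking.fit_stacked(train, spec)
        proba, _cls = stacking.predict_stacked(model, test_x)
        return proba
    params = None
    if isinstance(model_spec, tuple):
        model_spec, params = model_spec
    est = stacking.make_learner(model_spec, seed, params)
    est.fit(train.features, train.labels)
    return stacking.positive_proba(est, test_x)


def cross_validate(
    data: LabeledDataset,
    model_spec,
    resample_spec: Optional[ResampleSpec] = None,
    k: int = 5,
    mode: str = "safe",
    seed: int = 0,
    pooling: str = "mean",
) -> MetricsReport:
    """Stratified k-fold cross-validation of a resampling + model pipeline.

    ``mode="safe"`` resamples the training folds only and evaluates on
    untouched originals; ``mode="paper"`` resamples the whole dataset,
    shuffles, then splits.  ``pooling`` selects how confusion-based metrics
    aggregate: unweighted mean over folds (default) or a pooled confusion
    matrix (``"pooled"``); AUC is always averaged over folds.
    """
    if mode not in ("safe", "paper"):
        raise ValueError("mode must be 'safe' or 'paper'")
    if pooling not in ("mean", "pooled"):
        raise ValueError("pooling must be 'mean' or 'pooled'")

    if mode == "paper":
        pool = resample(data, resample_spec)
        order = np.random.default_rng(seed).permutation(pool.n)
        work = pool.subset(order)
    else:
        work = data

    folds = stratified_folds(work.labels, k, seed)
    per_fold: Dict[str, List[float]] = {
        m: [] for m in ("accuracy", "precision", "recall", "f_measure", "auc_roc")
    }
    cms: List[ConfusionMatrix] = []
    fold_sizes: List[int] = []
    n_synth_in_test = 0
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(work.n), test_idx)
        train = work.subset(train_idx)
        test = work.subset(test_idx)
        if mode == "safe" and resample_spec is not None:
            fold_spec = replace(
                resample_spec, seed=resample_spec.seed + 7919 * fold_id
            )
            train = resample(train, fold_spec)
        n_synth_in_test += int(test.synthetic.sum())
        proba = _fit_predict(train, test.features, model_spec, seed)
        pred = (proba >= 0.5).astype(int)
        cm = ConfusionMatrix.from_predictions(test.labels, pred)
        cms.append(cm)
        fold_sizes.append(test.n)
        for name, value in compute_metrics(cm).items():
            per_fold[name].append(value)
        per_fold["auc_roc"].append(roc_auc(test.labels, proba))

    if pooling == "pooled":
        pooled_cm = ConfusionMatrix(
            tp=sum(c.tp for c in cms), tn=sum(c.tn for c in cms),
            fp=sum(c.fp for c in cms), fn=sum(c.fn for c in cms),
        )
        mean = dict(compute_metrics(pooled_cm))
        mean["auc_roc"] = float(np.mean(per_fold["auc_roc"]))
    else:
        mean = {name: float(np.mean(vals)) for name, vals in per_fold.items()}

    return MetricsReport(
        per_fold=per_fold,
        mean=mean,
        k=k,
        seed=seed,
        mode=mode,
        model=str(model_spec),
        resample_method="none" if resample_spec is None else resample_spec.method,
        pooling=pooling,
        n_synthetic_in_test=n_synth_in_test,
        fold_sizes=fold_sizes,
    )
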