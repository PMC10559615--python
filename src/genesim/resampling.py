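"""Class-imbalance resamplers: SMOTE, random undersampling, and the hybrid.

Disease-gene cohorts are heavily imbalanced (few known disease genes versus
many background genes).  SMOTE synthesises new minority samples by linear
interpolation between a minority sample and one of its k nearest minority
neighbours under Euclidean distance; RUS discards majority samples uniformly
at random; SMOTE-RUS meets in the middle, oversampling the minority to an
intermediate ratio and then trimming the majority.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ClassBalanceError

logger = logging.getLogger(__name__)

POSITIVE = 1  # disease / "ASD" class
NEGATIVE = 0


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels, the unit flowing through resampling,
    boosting, stacking and cross-validation.

    ``labels`` take values in {0, 1}; 1 is the positive (disease) class.
    ``synthetic`` flags rows created by an oversampler (False for originals).
    """

    features: np.ndarray
    labels: np.ndarray
    sample_ids: Sequence[str] = None
    synthetic: np.ndarray = None

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels and feature rows are not aligned")
        if not set(np.unique(self.labels)) <= {NEGATIVE, POSITIVE}:
            raise ValueError("labels must be binary 0/1")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids and feature rows are not aligned")
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def class_counts(self):
        """(n_negative, n_positive)."""
        return int(np.sum(self.labels == NEGATIVE)), int(np.sum(self.labels == POSITIVE))

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            synthetic=self.synthetic[idx],
        )


@dataclass(frozen=True)
class ResampleSpec:
    """How to rebalance a dataset.

    ``target_ratio`` is the desired minority/majority count ratio after
    resampling (1.0 = full balance).  ``k`` is the SMOTE neighbour count.
    ``intermediate_ratio`` (SMOTE-RUS only) is the ratio SMOTE raises the
    minority to before RUS trims the majority; by default the geometric
    midpoint between the initial and target ratios.
    """

    method: str = "smote"
    k: int = 5
    target_ratio: float = 1.0
    seed: int = 0
    intermediate_ratio: Optional[float] = None

    def __post_init__(self):
        if self.method not in ("smote", "rus", "smote-rus", "none"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in (0, 1]")


def _split_classes(data: LabeledDataset):
    pos = np.flatnonzero(data.labels == POSITIVE)
    neg = np.flatnonzero(data.labels == NEGATIVE)
    if len(pos) == 0 or len(neg) == 0:
        raise ClassBalanceError("dataset must contain both classes")
    # minority = smaller class; ties resolve to the positive class
    if len(pos) <= len(neg):
        return pos, neg
    return neg, pos


def _minority_neighbors(x_min: np.ndarray, k: int):
    """k nearest minority neighbours of each minority row (self excluded),
    Euclidean distance, ties broken by lower original index."""
    dist = cdist(x_min, x_min)
    order = np.argsort(dist, axis=1, kind="stable")
    nn = np.empty((x_min.shape[0], k), dtype=int)
    for i in range(x_min.shape[0]):
        row = order[i][order[i] != i]
        nn[i] = row[:k]
    return nn


def smote(
    data: LabeledDataset, spec: ResampleSpec, rng: Optional[np.random.Generator] = None
) -> LabeledDataset:
    """Oversample the minority class by linear interpolation.

    New rows ``x_s = x_i + u * (x'_i - x_i)`` with ``u ~ Uniform(0, 1)`` and
    ``x'_i`` drawn uniformly from the k nearest minority neighbours of
    ``x_i``, appended until minority/majority >= ``spec.target_ratio``.
    Base points cycle through the minority in order; the remainder is drawn
    uniformly without replacement.  Originals are never touched.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    min_idx, maj_idx = _split_classes(data)
    n_min, n_maj = len(min_idx), len(maj_idx)
    if n_min < 2:
        raise ClassBalanceError(
            "SMOTE needs at least 2 minority samples to interpolate"
        )
    k = spec.k
    if k > n_min - 1:
        logger.warning("reducing k from %d to %d (minority size %d)", k, n_min - 1, n_min)
        k = n_min - 1

    target_min = math.ceil(spec.target_ratio * n_maj)
    n_new = max(0, target_min - n_min)
    if n_new == 0:
        return data.subset(np.arange(data.n))

    x_min = data.features[min_idx]
    nn = _minority_neighbors(x_min, k)

    n_cycles, remainder = divmod(n_new, n_min)
    bases = np.concatenate(
        [np.tile(np.arange(n_min), n_cycles),
         np.sort(rng.choice(n_min, size=remainder, replace=False))]
    ).astype(int)

    new_rows = np.empty((n_new, data.features.shape[1]))
    for s, b in enumerate(bases):
        neighbor = nn[b, rng.integers(k)]
        u = rng.uniform()
        seg = x_min[neighbor] - x_min[b]
        if not seg.any():
            logger.debug("zero-length segment at base %d; duplicating point", b)
        new_rows[s] = x_min[b] + u * seg

    minority_label = int(data.labels[min_idx[0]])
    return LabeledDataset(
        features=np.vstack([data.features, new_rows]),
        labels=np.concatenate([data.labels, np.full(n_new, minority_label)]),
        sample_ids=list(data.sample_ids)
        + [f"{data.sample_ids[min_idx[b]]}~syn{s}" for s, b in enumerate(bases)],
        synthetic=np.concatenate([data.synthetic, np.ones(n_new, dtype=bool)]),
    )


def rus(
    data: LabeledDataset, spec: ResampleSpec, rng: Optional[np.random.Generator] = None
) -> LabeledDataset:
    """Randomly undersample the majority class (uniform, without
    replacement) until minority/majority >= ``spec.target_ratio``.  All
    retained rows are originals, in their original order."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    min_idx, maj_idx = _split_classes(data)
    n_keep = min(len(maj_idx), math.floor(len(min_idx) / spec.target_ratio))
    kept_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([min_idx, kept_maj]))
    return data.subset(keep)


def smote_rus(
    data: LabeledDataset, spec: ResampleSpec, rng: Optional[np.random.Generator] = None
) -> LabeledDataset:
    """Hybrid: SMOTE the minority up to an intermediate ratio, then RUS the
    majority down to ``spec.target_ratio``."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    min_idx, maj_idx = _split_classes(data)
    r0 = len(min_idx) / len(maj_idx)
    r1 = spec.intermediate_ratio
    if r1 is None:
        r1 = math.sqrt(r0 * spec.target_ratio)
    r1 = min(max(r1, r0), spec.target_ratio)
    stage1 = smote(data, replace(spec, target_ratio=r1), rng=rng) if r1 > r0 else data
    return rus(stage1, spec, rng=rng)


_METHODS = {"smote": smote, "rus": rus, "smote-rus": smote_rus}


def resample(data: LabeledDataset, spec: Optional[ResampleSpec]) -> LabeledDataset:
    """Dispatch on ``spec.method``; ``None`` or method ``"none"`` is a no-op."""
    if spec is None or spec.method == "none":
        return data
    return _METHODS[spec.method](data, spec)
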