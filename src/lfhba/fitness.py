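"""Wrapper fitness for binary feature masks.

A candidate feature subset is scored by training a classifier on the
selected columns and combining its validation loss ``gamma`` with the
selected-feature fraction:

    Fit = lambda * gamma + (1 - lambda) * |mask| / dim

Lower is better; ``lambda`` close to 1 makes the subset-size term a
tie-breaker.  The default evaluator trains a linear support-vector machine
on one fixed stratified train/hold-out split per run, so every candidate in
a run is scored against the same data and fitness is deterministic given
the split seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

__all__ = [
    "FitnessConfig",
    "FitnessResult",
    "SvmEvaluator",
    "validation_loss",
    "evaluate_fitness",
]

# An evaluator maps (features, labels, mask, rng) -> gamma in [0, 1].
Evaluator = Callable[[np.ndarray, np.ndarray, np.ndarray, np.random.Generator], float]


@dataclass(frozen=True)
class FitnessConfig:
    """Configuration of the wrapper fitness.

    lambda_weight
        Weight of the classifier loss vs the subset-size penalty, in [0, 1].
    kernel, regularization
        SVM kernel ("linear" or "rbf") and its C parameter.
    holdout_fraction, split_seed
        Size and seed of the stratified hold-out split used for gamma.
    """

    lambda_weight: float = 0.99
    kernel: str = "linear"
    regularization: float = 1.0
    holdout_fraction: float = 0.2
    split_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.lambda_weight <= 1:
            raise ValueError("lambda_weight must be in [0, 1]")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


@dataclass(frozen=True)
class FitnessResult:
    """Score of one mask: validation loss, feature ratio, combined fitness."""

    gamma: float
    ratio: float
    fit: float


def _stratified_split(features, labels, config: FitnessConfig):
    """One stratified split; re-seeds up to 5 times if a class drops out."""
    n_classes = np.unique(labels).size
    for attempt in range(5):
        xtr, xte, ytr, yte = train_test_split(
            features,
            labels,
            test_size=config.holdout_fraction,
            stratify=labels,
            random_state=(config.split_seed + attempt) % 2**31,
        )
        if np.unique(ytr).size == n_classes:
            return xtr, xte, ytr, yte
    raise RuntimeError("could not produce a split containing every class")


class SvmEvaluator:
    """Hold-out SVM loss, memoized on the mask bit pattern.

    The split is drawn once at construction from ``split_seed``; gamma is
    ``1 - accuracy`` on the hold-out.  Multi-class data uses scikit-learn's
    one-vs-rest SVC, so gamma stays 1 minus overall accuracy.
    """

    def __init__(self, features, labels, config: FitnessConfig | None = None):
        self.config = config or FitnessConfig()
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels)
        if np.unique(labels).size < 2:
            raise ValueError("need at least 2 classes")
        self.x_train, self.x_test, self.y_train, self.y_test = _stratified_split(
            features, labels, self.config
        )
        self._cache: dict[bytes, float] = {}

    def __call__(self, features, labels, mask, rng) -> float:
        return self.gamma(mask)

    def gamma(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 1:
            raise ValueError("mask selects no features")
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        clf = SVC(kernel=self.config.kernel, C=self.config.regularization)
        clf.fit(self.x_train[:, mask], self.y_train)
        acc = float(np.mean(clf.predict(self.x_test[:, mask]) == self.y_test))
        g = 1.0 - acc
        self._cache[key] = g
        return g


def validation_loss(
    features: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    config: FitnessConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Hold-out loss ``gamma`` of the SVM trained on the masked features."""
    return SvmEvaluator(features, labels, config).gamma(np.asarray(mask))


def evaluate_fitness(
    features: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    config: FitnessConfig | None = None,
    rng: np.random.Generator | None = None,
    evaluator: Evaluator | None = None,
) -> FitnessResult:
    """Combined fitness of one mask (loss plus subset-size penalty)."""
    config = config or FitnessConfig()
    mask = np.asarray(mask, dtype=bool)
    dim = mask.size
    if evaluator is None:
        gamma = validation_loss(features, labels, mask, config, rng)
    else:
        gamma = float(evaluator(features, labels, mask, rng))
    ratio = float(mask.sum()) / dim
    lam = config.lambda_weight
    return FitnessResult(gamma=gamma, ratio=ratio, fit=lam * gamma + (1 - lam) * ratio)
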