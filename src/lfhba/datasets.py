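"""Synthetic data, dataset manifests, benchmark functions and score fixtures.

The feature generator emulates the setting the selector is built for:
fixed-width deep-feature vectors (128 per sample by default) for an
imbalanced 2-class chest X-ray-like task or a 4-class retinal-OCT-like
task, with a small planted subset of class-informative columns and pure
Gaussian noise elsewhere.  The planted indices are returned so recovery can
be measured.  Also packaged: the published dataset manifests (class
train/test counts), the published per-optimizer score tables used by the
aggregation and ranking utilities, the concatenated-backbone feature-width
contract, and standard continuous benchmark functions for optimizer sanity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "DatasetManifest",
    "BenchmarkFunction",
    "make_features",
    "table1_manifest",
    "ensemble_feature_width",
    "benchmark_function",
    "published_score_fixture",
    "score_table",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted-feature classification matrix.

    n_samples_per_class
        One entry per class (>= 2 classes).  The default 200/540 keeps the
        ~1:2.7 imbalance of the public chest X-ray split at desk scale.
    n_features, n_informative
        Total columns (default 128, the deep-feature width fed to
        selection) and how many carry class signal.
    effect_size
        Separation of adjacent class means on informative columns, in
        noise-SD units.
    """

    n_samples_per_class: tuple = (200, 540)
    n_features: int = 128
    n_informative: int = 8
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "n_samples_per_class", tuple(int(n) for n in self.n_samples_per_class)
        )
        if len(self.n_samples_per_class) < 2:
            raise ValueError("need at least 2 classes")
        if any(n < 1 for n in self.n_samples_per_class):
            raise ValueError("class sizes must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def make_features(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``(features, labels, informative_indices)`` from a spec.

    Informative columns receive class-dependent Gaussian means, equally
    spaced ``effect_size * noise_sd`` apart across classes; every other
    column is N(0, noise_sd^2) regardless of class.  Deterministic given
    the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.n_samples_per_class)
    n_total = sum(spec.n_samples_per_class)

    features = rng.normal(0.0, spec.noise_sd, size=(n_total, spec.n_features))
    labels = np.repeat(np.arange(n_classes), spec.n_samples_per_class)
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )

    # centred, equally spaced class means on the planted columns
    offsets = (np.arange(n_classes) - (n_classes - 1) / 2.0) * spec.effect_size
    shift = offsets[labels] * spec.noise_sd
    features[:, informative] += shift[:, None]
    return features, labels, informative


@dataclass(frozen=True)
class DatasetManifest:
    """Per-class train/test counts of a published dataset split."""

    dataset: str
    class_names: tuple
    train_counts: tuple
    test_counts: tuple

    @property
    def train_total(self) -> int:
        return sum(self.train_counts)

    @property
    def test_total(self) -> int:
        return sum(self.test_counts)

    @property
    def total(self) -> int:
        return self.train_total + self.test_total

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "classes": {
                name: {"train": tr, "test": te, "total": tr + te}
                for name, tr, te in zip(
                    self.class_names, self.train_counts, self.test_counts
                )
            },
            "train_total": self.train_total,
            "test_total": self.test_total,
            "total": self.total,
        }


_MANIFESTS = {
    "CXR": DatasetManifest(
        dataset="CXR",
        class_names=("Normal", "Pneumonia"),
        train_counts=(1349, 3883),
        test_counts=(234, 390),
    ),
    "OCT": DatasetManifest(
        dataset="OCT",
        class_names=("CNV", "DME", "Drusen", "Normal"),
        train_counts=(37213, 11356, 8624, 26323),
        test_counts=(242, 242, 242, 242),
    ),
}


def table1_manifest(dataset: str) -> DatasetManifest:
    """Published class counts of the CXR (2-class) or OCT (4-class) split."""
    try:
        return _MANIFESTS[dataset.upper()]
    except KeyError:
        raise ValueError(f"unknown dataset {dataset!r}; expected 'CXR' or 'OCT'")


def ensemble_feature_width(backbone_widths: Sequence[int]) -> int:
    """Width of the concatenated backbone representation (sum of widths)."""
    widths = list(backbone_widths)
    if not widths:
        raise ValueError("backbone_widths must be non-empty")
    if any(w <= 0 for w in widths):
        raise ValueError("all widths must be positive")
    return int(sum(widths))


@dataclass(frozen=True)
class BenchmarkFunction:
    """A continuous test function with its known global minimum."""

    name: str
    fn: Callable[[np.ndarray], float]
    optimum_position: np.ndarray
    optimum_value: float
    suggested_bounds: tuple


def _sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def _rastrigin(x):
    x = np.asarray(x)
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


def _rosenbrock(x):
    x = np.asarray(x)
    return float(np.sum(100 * (x[1:] - x[:-1] ** 2) ** 2 + (1 - x[:-1]) ** 2))


def benchmark_function(name: str, dim: int) -> BenchmarkFunction:
    """Standard optimizer sanity-check functions: sphere, rastrigin, rosenbrock."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if name == "sphere":
        return BenchmarkFunction(name, _sphere, np.zeros(dim), 0.0, (-5.12, 5.12))
    if name == "rastrigin":
        return BenchmarkFunction(name, _rastrigin, np.zeros(dim), 0.0, (-5.12, 5.12))
    if name == "rosenbrock":
        return BenchmarkFunction(name, _rosenbrock, np.ones(dim), 0.0, (-5.0, 10.0))
    raise ValueError(f"unknown benchmark function {name!r}")


# ---------------------------------------------------------------------------
# Published per-optimizer score tables (percent), rows are
# (optimizer, model) and columns the five reported metrics.  The OCT table
# carries one extra optimizer (MFO) not present in the CXR table.

_METRICS = ("accuracy", "balanced_accuracy", "f1", "recall", "precision")

_CXR_SCORES = {
    ("GWO", "DenseNet"): (82.69, 77.86, 81.60, 82.69, 84.48),
    ("GWO", "MobileNet"): (85.74, 81.24, 84.89, 85.74, 87.89),
    ("GWO", "Ensemble"): (86.06, 81.58, 85.23, 86.06, 88.27),
    ("WOA", "DenseNet"): (81.25, 75.85, 79.84, 81.25, 83.53),
    ("WOA", "MobileNet"): (84.78, 79.96, 83.77, 84.78, 87.22),
    ("WOA", "Ensemble"): (85.10, 80.47, 84.17, 85.10, 87.28),
    ("FFA", "DenseNet"): (81.57, 76.28, 80.22, 81.57, 83.77),
    ("FFA", "MobileNet"): (85.26, 80.60, 84.33, 85.26, 87.55),
    ("FFA", "Ensemble"): (84.94, 80.17, 83.96, 84.94, 87.33),
    ("HGS", "DenseNet"): (82.85, 77.99, 81.76, 82.85, 84.74),
    ("HGS", "MobileNet"): (85.58, 80.94, 84.67, 85.58, 87.94),
    ("HGS", "Ensemble"): (86.22, 81.79, 85.41, 86.22, 88.38),
    ("AOA", "DenseNet"): (82.21, 77.14, 80.99, 82.21, 84.25),
    ("AOA", "MobileNet"): (85.90, 81.37, 85.04, 85.90, 88.16),
    ("AOA", "Ensemble"): (84.94, 80.26, 83.99, 84.94, 87.17),
    ("AO", "DenseNet"): (82.21, 76.97, 80.91, 82.21, 84.57),
    ("AO", "MobileNet"): (84.62, 79.91, 83.65, 84.62, 86.78),
    ("AO", "Ensemble"): (86.22, 81.97, 85.47, 86.22, 88.09),
    ("HBA", "DenseNet"): (83.01, 78.03, 81.87, 83.01, 85.16),
    ("HBA", "MobileNet"): (86.06, 81.75, 85.28, 86.06, 87.97),
    ("HBA", "Ensemble"): (86.06, 81.75, 85.28, 86.06, 87.97),
    ("LFHBA", "DenseNet"): (83.65, 78.97, 82.66, 83.65, 85.49),
    ("LFHBA", "MobileNet"): (86.54, 82.22, 85.78, 86.54, 88.61),
    ("LFHBA", "Ensemble"): (87.10, 82.82, 86.19, 87.10, 88.56),
}

_OCT_SCORES = {
    ("GWO", "DenseNet"): (85.85, 85.85, 85.35, 85.85, 89.05),
    ("GWO", "MobileNet"): (88.12, 88.12, 87.78, 88.12, 90.74),
    ("GWO", "Ensemble"): (93.49, 93.49, 93.45, 93.49, 94.28),
    ("MFO", "DenseNet"): (86.67, 86.67, 86.38, 86.67, 89.45),
    ("MFO", "MobileNet"): (88.53, 88.53, 88.25, 88.53, 91.00),
    ("MFO", "Ensemble"): (93.80, 93.80, 93.78, 93.80, 94.55),
    ("WOA", "DenseNet"): (87.19, 87.19, 86.86, 87.19, 89.84),
    ("WOA", "MobileNet"): (88.43, 88.43, 88.15, 88.43, 90.79),
    ("WOA", "Ensemble"): (93.39, 93.39, 93.35, 93.39, 94.26),
    ("FFA", "DenseNet"): (86.26, 86.26, 85.88, 86.26, 89.46),
    ("FFA", "MobileNet"): (88.33, 88.33, 87.99, 88.33, 90.57),
    ("FFA", "Ensemble"): (87.19, 87.19, 86.87, 87.19, 89.78),
    ("HGS", "DenseNet"): (87.19, 87.19, 86.87, 87.19, 89.78),
    ("HGS", "MobileNet"): (88.33, 88.33, 88.02, 88.33, 90.87),
    ("HGS", "Ensemble"): (93.29, 93.29, 93.26, 93.29, 94.19),
    ("AOA", "DenseNet"): (86.98, 86.98, 86.65, 86.98, 89.66),
    ("AOA", "MobileNet"): (88.74, 88.74, 88.49, 88.74, 91.08),
    ("AOA", "Ensemble"): (93.70, 93.70, 93.68, 93.70, 94.48),
    ("AO", "DenseNet"): (87.40, 87.40, 87.03, 87.40, 89.95),
    ("AO", "MobileNet"): (88.43, 88.43, 88.13, 88.43, 90.98),
    ("AO", "Ensemble"): (93.80, 93.80, 93.78, 93.80, 94.55),
    ("HBA", "DenseNet"): (87.50, 87.50, 87.17, 87.50, 90.01),
    ("HBA", "MobileNet"): (88.43, 88.43, 88.18, 88.43, 90.85),
    ("HBA", "Ensemble"): (93.80, 93.80, 93.78, 93.80, 94.55),
    ("LFHBA", "DenseNet"): (87.71, 87.71, 87.44, 87.71, 90.30),
    ("LFHBA", "MobileNet"): (88.95, 88.95, 88.66, 88.95, 91.19),
    ("LFHBA", "Ensemble"): (94.32, 94.32, 94.30, 94.32, 94.93),
}


def published_score_fixture() -> pd.DataFrame:
    """Published per-optimizer scores as a tidy DataFrame.

    Columns: optimizer, dataset, model, metric, score (percent).
    """
    rows = []
    for dataset, scores in (("CXR", _CXR_SCORES), ("OCT", _OCT_SCORES)):
        for (optimizer, model), values in scores.items():
            for metric, score in zip(_METRICS, values):
                rows.append(
                    {
                        "optimizer": optimizer,
                        "dataset": dataset,
                        "model": model,
                        "metric": metric,
                        "score": score,
                    }
                )
    return pd.DataFrame(rows)


def score_table(
    metric: str = "accuracy",
    dataset: str | None = None,
    optimizers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Wide score table: rows = optimizers, columns = dataset/model blocks.

    Suitable for :func:`lfhba.metrics.friedman_mean_ranks` and
    :func:`lfhba.metrics.aggregate_table`.  Restricting ``dataset`` keeps
    one table's blocks; ``optimizers`` selects and orders the rows.
    """
    tidy = published_score_fixture()
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    tidy = tidy[tidy["metric"] == metric]
    if dataset is not None:
        tidy = tidy[tidy["dataset"] == dataset.upper()]
    tidy = tidy.assign(block=tidy["dataset"] + "/" + tidy["model"])
    wide = tidy.pivot(index="optimizer", columns="block", values="score")
    if optimizers is not None:
        wide = wide.loc[list(optimizers)]
    else:
        wide = wide.dropna()  # drop optimizers absent from one dataset
    return wide
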