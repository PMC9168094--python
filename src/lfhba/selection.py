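"""Binary wrapper feature selection with the Levy-flight honey badger algorithm.

LFHBA searches the continuous unit cube ``[0, 1]^dim``; a position is
decoded into a feature subset by strict thresholding at 0.5.  Each
iteration, every candidate is updated by either the honey badger digging
move (exploitation around the incumbent best) or the Levy-flight move
(heavy-tailed jumps), chosen per candidate by a uniform probability draw
against 0.5.  Candidates are scored by the wrapper fitness
``lambda * gamma + (1 - lambda) * |mask|/dim`` and accepted greedily.

The user-facing surface follows the model/results idiom:
``LfhbaFeatureSelector(features, labels).fit()`` returns a
``SelectionResult`` carrying the best mask, its fitness decomposition and
the convergence history, with a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from enum import Enum
from typing import Callable

import numpy as np
import pandas as pd

from .hba import (
    Bounds,
    HbaConfig,
    density_factor,
    digging_update,
    direction_flag,
    honey_update,
    intensity,
)
from .levy import LevyParams, levy_update
from .fitness import Evaluator, FitnessConfig, FitnessResult, SvmEvaluator

__all__ = [
    "LfhbaConfig",
    "BinaryMask",
    "SelectionResult",
    "Operator",
    "LfhbaFeatureSelector",
    "init_solutions",
    "binarize",
    "operator_switch",
    "select_features",
]


class Operator(Enum):
    """Which move updates a candidate this iteration."""

    HBA_DIG = "hba_dig"
    LEVY = "levy"


@dataclass(frozen=True)
class LfhbaConfig:
    """Configuration of an LFHBA feature-selection run.

    pop_size, max_iters
        Population size N (default 50) and iteration budget (default 1000).
    density_constant, ability
        Honey badger parameters (see :class:`~lfhba.hba.HbaConfig`).
    levy
        Levy-flight operator parameters.
    fitness_lambda
        Weight of classifier loss vs subset size in the fitness, in [0, 1].
    repair_policy
        What to do with an empty mask: "flip_one_on" turns one uniformly
        chosen bit on (the classifier needs at least one feature);
        "penalize" assigns fitness 1.0.
    hba_phase
        "digging" applies only the digging move on the HBA branch (the
        literal operator-switch rule); "full" tosses a second coin between
        digging and honey moves, recovering the complete HBA arm.
    """

    pop_size: int = 50
    max_iters: int = 1000
    density_constant: float = 2.0
    ability: float = 6.0
    levy: LevyParams = field(default_factory=LevyParams)
    fitness_lambda: float = 0.99
    seed: int = 0
    repair_policy: str = "flip_one_on"
    hba_phase: str = "digging"

    def __post_init__(self):
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if not 0 <= self.fitness_lambda <= 1:
            raise ValueError("fitness_lambda must be in [0, 1]")
        if self.repair_policy not in ("flip_one_on", "penalize"):
            raise ValueError(f"unknown repair_policy {self.repair_policy!r}")
        if self.hba_phase not in ("digging", "full"):
            raise ValueError(f"unknown hba_phase {self.hba_phase!r}")


@dataclass(frozen=True)
class BinaryMask:
    """A 0/1 feature-subset encoding of length dim."""

    bits: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "bits", np.asarray(self.bits, dtype=np.int8).copy()
        )

    @property
    def cardinality(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def init_solutions(
    dim: int,
    config: LfhbaConfig,
    rng: np.random.Generator,
    lower: float = 0.0,
    upper: float = 1.0,
) -> np.ndarray:
    """Initial N x dim positions uniform over [lower, upper] (default [0, 1])."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    return rng.uniform(size=(config.pop_size, dim)) * (upper - lower) + lower


def binarize(position: np.ndarray) -> BinaryMask:
    """Threshold a continuous position at 0.5 (strict: 0.5 itself maps to 0)."""
    return BinaryMask(np.asarray(position) > 0.5)


def operator_switch(p: float) -> Operator:
    """Digging branch iff p < 0.5; Levy branch otherwise (0.5 included)."""
    return Operator.HBA_DIG if p < 0.5 else Operator.LEVY


@dataclass
class SelectionResult:
    """Outcome of one LFHBA run.

    Attributes
    ----------
    best_mask : BinaryMask
        The best feature subset found.
    best_fitness, best_gamma, best_ratio : float
        Its combined fitness, validation loss, and selected-feature ratio.
    history : ndarray
        Best fitness after initialization and after each iteration
        (length ``max_iters + 1``, non-increasing).
    n_evaluations : int
        Distinct mask evaluations performed (memoized repeats not counted).
    """

    best_mask: BinaryMask
    best_fitness: float
    best_gamma: float
    best_ratio: float
    history: np.ndarray
    seed: int
    config: LfhbaConfig
    dim: int
    n_evaluations: int = 0

    @property
    def selected_indices(self) -> np.ndarray:
        return self.best_mask.indices

    @property
    def n_selected(self) -> int:
        return self.best_mask.cardinality

    def summary(self) -> str:
        c = self.config
        lines = [
            "LFHBA Feature Selection Results",
            "=" * 46,
            f"{'Features (dim)':<28}{self.dim:>18}",
            f"{'Selected features':<28}{self.n_selected:>18}",
            f"{'Selected ratio':<28}{self.best_ratio:>18.4f}",
            f"{'Best fitness':<28}{self.best_fitness:>18.6f}",
            f"{'Validation loss (gamma)':<28}{self.best_gamma:>18.6f}",
            f"{'Validation accuracy':<28}{1 - self.best_gamma:>18.6f}",
            "-" * 46,
            f"{'Population size':<28}{c.pop_size:>18}",
            f"{'Iterations':<28}{c.max_iters:>18}",
            f"{'Fitness lambda':<28}{c.fitness_lambda:>18.4f}",
            f"{'Seed':<28}{self.seed:>18}",
            f"{'Distinct mask evaluations':<28}{self.n_evaluations:>18}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        cfg = asdict(replace(self.config, levy=self.config.levy))
        cfg["levy"] = asdict(self.config.levy)
        return {
            "mask": self.best_mask.bits.astype(int).tolist(),
            "selected_indices": self.selected_indices.tolist(),
            "n_selected": self.n_selected,
            "best_fitness": self.best_fitness,
            "best_gamma": self.best_gamma,
            "best_ratio": self.best_ratio,
            "history": np.asarray(self.history, dtype=float).tolist(),
            "seed": self.seed,
            "dim": self.dim,
            "n_evaluations": self.n_evaluations,
            "config": cfg,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def plot_convergence(self, ax=None):
        """Best-fitness trace vs iteration (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(len(self.history)), self.history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best fitness")
        ax.set_title("LFHBA convergence")
        return ax


class LfhbaFeatureSelector:
    """Wrapper feature-selection model over a labelled feature matrix.

    Parameters
    ----------
    features : (n_samples, dim) array
        Real-valued feature matrix (rows = samples).
    labels : (n_samples,) array
        Integer class labels; at least two classes must be present.
    config : LfhbaConfig, optional
    fitness_config : FitnessConfig, optional
        SVM and split settings for the default evaluator.  Its
        ``lambda_weight`` is overridden by ``config.fitness_lambda``.
    evaluator : callable, optional
        Custom ``(features, labels, mask, rng) -> gamma`` in [0, 1],
        replacing the SVM (used e.g. by brute-force oracle tests).

    Examples
    --------
    >>> sel = LfhbaFeatureSelector(X, y, LfhbaConfig(pop_size=20, max_iters=100))
    >>> res = sel.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        features,
        labels,
        config: LfhbaConfig | None = None,
        fitness_config: FitnessConfig | None = None,
        evaluator: Evaluator | None = None,
    ):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if np.unique(self.labels).size < 2:
            raise ValueError("need at least 2 classes in labels")
        if self.features.shape[1] < 2:
            raise ValueError("need at least 2 feature columns")
        self.config = config or LfhbaConfig()
        fc = fitness_config or FitnessConfig()
        self.fitness_config = replace(fc, lambda_weight=self.config.fitness_lambda)
        if evaluator is None:
            evaluator = SvmEvaluator(self.features, self.labels, self.fitness_config)
        self.evaluator = evaluator
        self.dim = self.features.shape[1]
        self.bounds = Bounds(0.0, 1.0, self.dim)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "label",
        **kwargs,
    ) -> "LfhbaFeatureSelector":
        """Build a selector from a DataFrame with one label column."""
        if label_column not in df.columns:
            raise KeyError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy()
        features = df.drop(columns=[label_column]).to_numpy(dtype=float)
        return cls(features, labels, **kwargs)

    # -- fitness plumbing ---------------------------------------------------

    def _repair(self, position, mask: BinaryMask, rng) -> BinaryMask:
        """Enforce cardinality >= 1 under the flip_one_on policy.

        The continuous coordinate is lifted above the threshold too, so the
        stored position still decodes to the repaired mask.
        """
        j = int(rng.integers(self.dim))
        bits = mask.bits.copy()
        bits[j] = 1
        position[j] = 0.75
        return BinaryMask(bits)

    def _score(self, mask: BinaryMask, rng, cache: dict) -> FitnessResult:
        key = np.packbits(mask.bits > 0).tobytes()
        hit = cache.get(key)
        if hit is not None:
            return hit
        lam = self.config.fitness_lambda
        gamma = float(self.evaluator(self.features, self.labels, mask.bits > 0, rng))
        ratio = mask.cardinality / self.dim
        res = FitnessResult(gamma=gamma, ratio=ratio, fit=lam * gamma + (1 - lam) * ratio)
        cache[key] = res
        return res

    def _evaluate(self, position, rng, cache) -> tuple[BinaryMask, FitnessResult]:
        mask = binarize(position)
        if mask.cardinality == 0:
            if self.config.repair_policy == "penalize":
                return mask, FitnessResult(gamma=1.0, ratio=0.0, fit=1.0)
            mask = self._repair(position, mask, rng)
        return mask, self._score(mask, rng, cache)

    # -- main loop ----------------------------------------------------------

    def fit(self) -> SelectionResult:
        """Run the LFHBA search and return the best subset found."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        cache: dict = {}

        positions = init_solutions(self.dim, cfg, rng)
        masks: list[BinaryMask] = []
        fits = np.empty(cfg.pop_size)
        gammas = np.empty(cfg.pop_size)
        for i in range(cfg.pop_size):
            try:
                m, r = self._evaluate(positions[i], rng, cache)
            except Exception as exc:
                raise RuntimeError(f"fitness evaluation failed at iteration 0: {exc}")
            masks.append(m)
            fits[i] = r.fit
            gammas[i] = r.gamma

        best = int(np.argmin(fits))
        prey = positions[best].copy()
        best_mask = masks[best]
        best_fit = float(fits[best])
        best_gamma = float(gammas[best])
        history = [best_fit]

        for t in range(1, cfg.max_iters + 1):
            alpha = density_factor(t, cfg.max_iters, cfg.density_constant)
            intens = intensity(positions, prey, rng)
            for i in range(cfg.pop_size):
                op = operator_switch(rng.uniform())
                if op is Operator.HBA_DIG:
                    flag = direction_flag(rng)
                    if cfg.hba_phase == "full" and rng.uniform() >= 0.5:
                        cand = honey_update(positions[i], prey, alpha, flag, rng)
                    else:
                        cand = digging_update(
                            positions[i], prey, intens[i], alpha, flag,
                            cfg.ability, rng,
                        )
                else:
                    cand = levy_update(prey, positions, cfg.levy, rng)
                cand = self.bounds.clamp(cand)
                try:
                    m, r = self._evaluate(cand, rng, cache)
                except Exception as exc:
                    raise RuntimeError(
                        f"fitness evaluation failed at iteration {t}: {exc}"
                    )
                if r.fit < fits[i]:
                    positions[i] = cand
                    fits[i] = r.fit
                    gammas[i] = r.gamma
                    masks[i] = m
                    if r.fit < best_fit:
                        best_fit = float(r.fit)
                        best_gamma = float(r.gamma)
                        best_mask = m
                        prey = cand.copy()
            history.append(best_fit)

        return SelectionResult(
            best_mask=best_mask,
            best_fitness=best_fit,
            best_gamma=best_gamma,
            best_ratio=best_mask.cardinality / self.dim,
            history=np.asarray(history),
            seed=cfg.seed,
            config=cfg,
            dim=self.dim,
            n_evaluations=len(cache),
        )


def select_features(
    features,
    labels,
    config: LfhbaConfig | None = None,
    fitness_config: FitnessConfig | None = None,
    evaluator: Evaluator | None = None,
) -> SelectionResult:
    """Functional entry point: build the selector and fit in one call."""
    return LfhbaFeatureSelector(
        features, labels, config=config,
        fitness_config=fitness_config, evaluator=evaluator,
    ).fit()
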