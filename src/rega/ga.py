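"""Genetic algorithm over K-subset individuals with F1-on-validation fitness.

An individual is a (K, Sfs) integer array: K ordered feature subsets of
Sfs indices into the fused feature matrix (duplicates permitted). Each
generation, parents are paired at random, every pair is crossed at a
subset-granularity single point, children are mutated per-position with
probability P_M, children are evaluated (train a rotation-boost ensemble
on the training split, F1 of the positive class on the validation
split), and the best M of the 2M parents+children survive. Elitism plus
fitness caching make the best-validation-F1 series non-decreasing.

Randomness is organized as named streams spawned from one master seed
(population init; per-generation genetic operators; one stream per
fitness evaluation), so evaluation order cannot change results.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .ensemble import RotationBoostClassifier
from .rotation import DegenerateSubsetError

logger = logging.getLogger(__name__)

_STREAM_INIT, _STREAM_GENOPS, _STREAM_EVAL = 0, 1, 2


@dataclass
class GAConfig:
    """Evolution settings; defaults follow the reference experiment protocol."""

    generations: int = 50          # T
    population_size: int = 50      # M, must be even
    mutation_prob: float = 0.1     # P_M, per-position
    n_subsets: int = 10            # K
    subset_size: int = 300         # Sfs
    n_features: int = 0            # Sf, set from the data
    base_estimator: object = None  # default: RandomForestClassifier(50)
    max_retries: int = 5
    seed: int = 0

    def validate(self) -> None:
        if min(self.generations, self.population_size, self.n_subsets,
               self.subset_size) < 0 or self.n_features <= 0:
            raise ValueError("GA sizes must be positive (Sf > 0)")
        if self.population_size % 2:
            raise ValueError("population_size must be even")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------

def init_population(config: GAConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """M random individuals of shape (K, Sfs), indices uniform in [0, Sf)."""
    config.validate()
    return [rng.integers(0, config.n_features,
                         size=(config.n_subsets, config.subset_size))
            for _ in range(config.population_size)]


def crossover_pair(parent_a: np.ndarray, parent_b: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover at subset granularity, point uniform in {0..K}."""
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must share (K, Sfs)")
    k = parent_a.shape[0]
    cp = int(rng.integers(0, k + 1))
    child_a = np.vstack([parent_a[:cp], parent_b[cp:]])
    child_b = np.vstack([parent_b[:cp], parent_a[cp:]])
    return child_a, child_b


def mutate(individual: np.ndarray, mutation_prob: float, n_features: int,
           rng: np.random.Generator) -> np.ndarray:
    """Independently resample each position with probability P_M."""
    out = individual.copy()
    mask = rng.random(out.shape) < mutation_prob
    out[mask] = rng.integers(0, n_features, size=int(mask.sum()))
    return out


def evaluate_fitness(individual: np.ndarray, X_train, y_train, X_val, y_val,
                     config: GAConfig, rng: np.random.Generator) -> float:
    """Validation-set F1 of the individual's trained ensemble (0 on failure)."""
    try:
        model = RotationBoostClassifier(
            subsets=individual, column_kinds=config_column_kinds(config),
            base_estimator=config.base_estimator,
            max_retries=config.max_retries, random_state=rng,
        ).fit(X_train, y_train)
    except DegenerateSubsetError as exc:
        logger.warning("fitness 0 for degenerate individual: %s", exc)
        return 0.0
    return float(f1_score(y_val, model.predict(X_val), zero_division=0))


def config_column_kinds(config: GAConfig):
    kinds = getattr(config, "column_kinds", None)
    if kinds is None:
        raise ValueError("config.column_kinds must be set before evaluation")
    return kinds


def select_survivors(individuals: Sequence[np.ndarray],
                     fitnesses: Sequence[float],
                     m: int) -> tuple[list[np.ndarray], list[float]]:
    """Keep the top m by fitness; ties broken by stable original order."""
    order = np.argsort(-np.asarray(fitnesses), kind="stable")[:m]
    return ([individuals[i] for i in order], [fitnesses[i] for i in order])


# ---------------------------------------------------------------------------
# the evolutionary loop
# ---------------------------------------------------------------------------

@dataclass
class EvolutionResult:
    population: list[np.ndarray]
    fitnesses: list[float]
    curve: pd.DataFrame            # generation, best_val_f1[, test_f1]
    best_individual: np.ndarray = field(init=False)
    best_fitness: float = field(init=False)

    def __post_init__(self) -> None:
        best = int(np.argmax(self.fitnesses))
        self.best_individual = self.population[best]
        self.best_fitness = float(self.fitnesses[best])


def evolve(config: GAConfig, X_train, y_train, X_val, y_val,
           X_test=None, y_test=None,
           column_kinds: Sequence[str] | None = None) -> EvolutionResult:
    """Run the full GA loop; optional test split is tracked for the curve only."""
    if column_kinds is not None:
        config.column_kinds = list(column_kinds)
    config.validate()
    eval_counter = 0

    def eval_individual(ind: np.ndarray) -> float:
        nonlocal eval_counter
        rng = _stream(config.seed, _STREAM_EVAL, eval_counter)
        eval_counter += 1
        return evaluate_fitness(ind, X_train, y_train, X_val, y_val, config, rng)

    def test_f1(ind: np.ndarray, tag: int) -> float:
        model = RotationBoostClassifier(
            subsets=ind, column_kinds=config.column_kinds,
            base_estimator=config.base_estimator, max_retries=config.max_retries,
            random_state=_stream(config.seed, 3, tag),
        ).fit(X_train, y_train)
        return float(f1_score(y_test, model.predict(X_test), zero_division=0))

    population = init_population(config, _stream(config.seed, _STREAM_INIT))
    fitnesses = [eval_individual(ind) for ind in population]

    records = []

    def record(gen: int) -> None:
        row = {"generation": gen, "best_val_f1": max(fitnesses)}
        if X_test is not None:
            row["test_f1"] = test_f1(population[int(np.argmax(fitnesses))], gen)
        records.append(row)

    record(0)
    for gen in range(1, config.generations + 1):
        rng = _stream(config.seed, _STREAM_GENOPS, gen)
        order = rng.permutation(config.population_size)
        children = []
        for i in range(0, config.population_size, 2):
            a, b = population[order[i]], population[order[i + 1]]
            child_a, child_b = crossover_pair(a, b, rng)
            children.append(mutate(child_a, config.mutation_prob,
                                   config.n_features, rng))
            children.append(mutate(child_b, config.mutation_prob,
                                   config.n_features, rng))
        child_fit = [eval_individual(c) for c in children]
        population, fitnesses = select_survivors(
            population + children, fitnesses + child_fit, config.population_size)
        record(gen)

    return EvolutionResult(population, fitnesses, pd.DataFrame(records))


# ---------------------------------------------------------------------------
# sklearn-style front door
# ---------------------------------------------------------------------------

class REGAClassifier(ClassifierMixin, BaseEstimator):
    """Rotation-Ensemble-GA classifier.

    Evolves K-subset individuals by validation F1 and exposes the best
    individual's retrained rotation-boost ensemble as a standard
    fit/predict classifier. The validation split used as the GA's fitness
    signal is carved from the training data unless an explicit
    ``validation`` pair is passed to :meth:`fit`.

    Parameters mirror :class:`GAConfig`; ``column_kinds`` declares every
    input column binary or continuous (default: all continuous).
    """

    def __init__(self, generations: int = 50, population_size: int = 50,
                 mutation_prob: float = 0.1, n_subsets: int = 10,
                 subset_size: int = 300, base_estimator=None,
                 max_retries: int = 5, validation_fraction: float = 0.25,
                 column_kinds=None, track_test: bool = False,
                 random_state: int = 0):
        self.generations = generations
        self.population_size = population_size
        self.mutation_prob = mutation_prob
        self.n_subsets = n_subsets
        self.subset_size = subset_size
        self.base_estimator = base_estimator
        self.max_retries = max_retries
        self.validation_fraction = validation_fraction
        self.column_kinds = column_kinds
        self.track_test = track_test
        self.random_state = random_state

    def _config(self, n_features: int) -> GAConfig:
        cfg = GAConfig(
            generations=self.generations, population_size=self.population_size,
            mutation_prob=self.mutation_prob, n_subsets=self.n_subsets,
            subset_size=self.subset_size, n_features=n_features,
            base_estimator=self.base_estimator, max_retries=self.max_retries,
            seed=self.random_state,
        )
        cfg.column_kinds = (list(self.column_kinds) if self.column_kinds is not None
                            else ["continuous"] * n_features)
        return cfg

    def fit(self, X, y, validation: tuple | None = None,
            test: tuple | None = None) -> "REGAClassifier":
        X, y = check_X_y(X, y)
        if validation is None:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, test_size=self.validation_fraction, stratify=y,
                random_state=self.random_state)
        else:
            X_tr, y_tr = X, y
            X_val, y_val = validation
        cfg = self._config(X.shape[1])
        X_test, y_test = test if test is not None else (None, None)
        result = evolve(cfg, X_tr, y_tr, X_val, y_val,
                        X_test=X_test, y_test=y_test)
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.population_ = result.population
        self.fitnesses_ = result.fitnesses
        self.curve_ = result.curve
        self.best_individual_ = result.best_individual
        self.best_fitness_ = result.best_fitness
        self.best_ensemble_ = RotationBoostClassifier(
            subsets=self.best_individual_, column_kinds=cfg.column_kinds,
            base_estimator=self.base_estimator, max_retries=self.max_retries,
            random_state=_stream(self.random_state, 4),
        ).fit(X_tr, y_tr)
        return self

    def predict(self, X):
        check_is_fitted(self, "best_ensemble_")
        return self.best_ensemble_.predict(check_array(X))

    def decision_function(self, X):
        check_is_fitted(self, "best_ensemble_")
        return self.best_ensemble_.decision_function(check_array(X))
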