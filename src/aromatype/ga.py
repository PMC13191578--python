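"""Genetic algorithm over mixed integer/real/boolean chromosomes.

A generational GA (tournament selection of size 3, uniform crossover,
per-gene mutation, elitism) maximizing an arbitrary scalar fitness over a
bounded search space.  All genes are held as reals in one chromosome vector;
integer genes are rounded and booleans thresholded at decode time.  The main
client is random-forest hyperparameter tuning with 5-fold CV macro-F1 as the
fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data_io import FeatureTable
from .modeling import ModelSpec, cross_validate

INT, REAL, BOOL = "int", "real", "bool"


@dataclass(frozen=True)
class Gene:
    name: str
    type: str
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in (INT, REAL, BOOL):
            raise ValueError(f"unknown gene type {self.type!r}")
        if self.low > self.high:
            raise ValueError(f"gene {self.name!r}: low > high")

    def decode(self, x: float):
        if self.type == BOOL:
            return bool(x >= 0.5)
        if self.type == INT:
            return int(np.clip(round(x), self.low, self.high))
        return float(np.clip(x, self.low, self.high))


@dataclass
class SearchSpace:
    genes: list[Gene]

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([0.0 if g.type == BOOL else g.low for g in self.genes])
        hi = np.array([1.0 if g.type == BOOL else g.high for g in self.genes])
        return lo, hi

    def decode(self, chrom: np.ndarray) -> dict:
        return {g.name: g.decode(x) for g, x in zip(self.genes, chrom)}


def default_rf_space() -> SearchSpace:
    """The six tuned random-forest hyperparameters and their ranges."""
    return SearchSpace(
        [
            Gene("n_estimators", INT, 50, 200),
            Gene("max_depth", INT, 3, 20),
            Gene("min_samples_split", INT, 2, 20),
            Gene("min_samples_leaf", INT, 1, 10),
            Gene("max_features", REAL, 0.1, 1.0),
            Gene("bootstrap", BOOL),
        ]
    )


@dataclass
class GAConfig:
    """GA control parameters: population 100, 50 iterations, precision 1e-6.

    The error precision acts as a stall rule: the run stops early when the
    best fitness improves by less than ``tolerance`` for
    ``stall_generations`` consecutive generations.
    """

    population_size: int = 100
    max_generations: int = 50
    tolerance: float = 1e-6
    stall_generations: int = 5
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1
    elitism_count: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")


def ga_optimize(
    fitness: Callable[[Mapping], float],
    space: SearchSpace,
    config: GAConfig | None = None,
) -> tuple[dict, float, list[float]]:
    """Maximize ``fitness(decoded chromosome)`` over the search space.

    Returns the best decoded chromosome, its fitness, and the per-generation
    best-fitness history (non-decreasing, by elitism).  Fitness values are
    cached on the decoded genotype, so re-evaluations of identical decoded
    chromosomes are free.
    """
    cfg = config or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = space.bounds
    n_genes = len(space.genes)
    pop = rng.uniform(lo, hi, size=(cfg.population_size, n_genes))

    cache: dict[tuple, float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        decoded = space.decode(chrom)
        key = tuple(decoded.values())
        if key not in cache:
            value = float(fitness(decoded))
            if not np.isfinite(value):
                raise ValueError(f"fitness returned non-finite value for {decoded}")
            cache[key] = value
        return cache[key]

    scores = np.array([evaluate(c) for c in pop])
    history: list[float] = []
    best_idx = int(np.argmax(scores))
    best_chrom, best_score = pop[best_idx].copy(), float(scores[best_idx])
    history.append(best_score)
    stall = 0

    for _ in range(1, cfg.max_generations):
        order = np.argsort(-scores)
        elite = pop[order[: cfg.elitism_count]].copy()
        children = []
        while len(children) < cfg.population_size - cfg.elitism_count:
            pa = _tournament(pop, scores, rng)
            pb = _tournament(pop, scores, rng)
            ca, cb = pa.copy(), pb.copy()
            if rng.random() < cfg.crossover_prob:
                mask = rng.random(n_genes) < 0.5
                ca[mask], cb[mask] = pb[mask], pa[mask]
            for child in (ca, cb):
                _mutate(child, space, cfg.mutation_prob, rng)
                children.append(child)
        pop = np.vstack([elite, np.array(children[: cfg.population_size - cfg.elitism_count])])
        pop = np.clip(pop, lo, hi)
        scores = np.array([evaluate(c) for c in pop])
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            improvement = float(scores[gen_best]) - best_score
            best_chrom, best_score = pop[gen_best].copy(), float(scores[gen_best])
        else:
            improvement = 0.0
        history.append(best_score)
        stall = stall + 1 if improvement < cfg.tolerance else 0
        if stall >= cfg.stall_generations:
            break

    return space.decode(best_chrom), best_score, history


def _tournament(pop, scores, rng, size: int = 3) -> np.ndarray:
    idx = rng.integers(0, len(pop), size=size)
    return pop[idx[np.argmax(scores[idx])]]


def _mutate(chrom: np.ndarray, space: SearchSpace, prob: float, rng) -> None:
    for j, g in enumerate(space.genes):
        if rng.random() >= prob:
            continue
        if g.type == BOOL:
            chrom[j] = 1.0 - (chrom[j] >= 0.5)
        elif g.type == INT:
            chrom[j] = rng.uniform(g.low, g.high)
        else:
            span = g.high - g.low
            chrom[j] = np.clip(chrom[j] + rng.normal(0, 0.1 * span), g.low, g.high)


def build_rf(params: Mapping, seed: int = 42) -> RandomForestClassifier:
    """A random forest from decoded GA hyperparameters."""
    return RandomForestClassifier(
        n_estimators=int(params["n_estimators"]),
        max_depth=int(params["max_depth"]),
        min_samples_split=int(params["min_samples_split"]),
        min_samples_leaf=int(params["min_samples_leaf"]),
        max_features=float(params["max_features"]),
        bootstrap=bool(params["bootstrap"]),
        random_state=seed,
        n_jobs=1,
    )


def tune_rf(
    train: FeatureTable,
    space: SearchSpace | None = None,
    config: GAConfig | None = None,
    cv_folds: int = 5,
    rf_seed: int = 42,
):
    """GA-tune a random forest on the training split.

    Fitness is the mean ``cv_folds``-fold stratified CV macro-F1 of the
    candidate forest on the (preprocessed-per-fold) training data; the
    held-out test split is never touched.  Returns the best hyperparameters,
    a forest with those hyperparameters refitted on the full training data,
    and the GA history.
    """
    if train.labels is None:
        raise ValueError("tune_rf requires labels")
    space = space or default_rf_space()
    cfg = config or GAConfig()

    def fitness(params: Mapping) -> float:
        spec = ModelSpec("candidate", lambda: build_rf(params, rf_seed))
        return cross_validate(spec, train, cv_folds, cfg.seed).macro_f1

    best_params, best_fitness, history = ga_optimize(fitness, space, cfg)
    forest = build_rf(best_params, rf_seed)
    forest.fit(train.values, train.labels)
    return best_params, forest, best_fitness, history
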