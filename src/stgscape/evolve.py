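"""Seedable genetic algorithm over the conductance search box.

A standard real-coded GA: uniform random initialization inside per-gene
bounds, linear rank-based parent selection with adjustable pressure
("elitism": the breeding weight of the best rank relative to the
population mean, 1.0 meaning uniform), uniform per-gene crossover,
per-gene mutation by resampling inside the bounds, and elitist (mu+lambda)
survivor selection: parents and offspring compete and the best individuals
form the next generation, so the best-ever individual is always preserved.
Fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

__all__ = ["SEARCH_BOUNDS", "GAConfig", "GAResult", "ga_minimize"]

#: the 9-gene search box: 8 maximal conductances (uS) and tau_Ca (ms)
SEARCH_BOUNDS = np.array([
    [0.0, 2.0e3],   # g_Na
    [0.0, 2.0e2],   # g_CaT
    [0.0, 2.0e2],   # g_CaS
    [0.0, 2.0e2],   # g_A
    [0.0, 2.0e3],   # g_KCa
    [0.0, 2.0e2],   # g_Kd
    [0.0, 2.0e2],   # g_H
    [0.0, 2.0e1],   # g_leak
    [0.0, 1.0e3],   # tau_Ca
])


@dataclass
class GAConfig:
    population: int = 1000
    generations: int = 100
    mutation_rate: float = 0.05
    elitism: float = 1.2        # best rank's breeding weight / mean weight
    bounds: np.ndarray = field(default_factory=lambda: SEARCH_BOUNDS.copy())
    seed: int = 0
    workers: int = 1

    def __post_init__(self):
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.ndim != 2 or self.bounds.shape[1] != 2 or len(self.bounds) == 0:
            raise ValueError("bounds must be a (n_genes, 2) array")
        if np.any(self.bounds[:, 1] < self.bounds[:, 0]):
            raise ValueError("each bound must satisfy lo <= hi")
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be a fraction")
        if not (1.0 <= self.elitism <= 2.0):
            raise ValueError("elitism must lie in [1, 2] for linear ranking")


@dataclass
class GAResult:
    best: np.ndarray
    best_score: float
    history: List[float]            # best-so-far score per generation
    population: np.ndarray          # final population
    scores: np.ndarray              # final population scores


def _rank_weights(n: int, elitism: float) -> np.ndarray:
    """Linear ranking selection probabilities, worst to best.

    With mean weight normalized to 1, the best rank receives ``elitism``
    (1.0 -> uniform breeding probability).
    """
    ranks = np.arange(n, dtype=float)           # 0 = worst
    if n == 1:
        return np.ones(1)
    slope = 2.0 * (elitism - 1.0) / (n - 1)
    w = (2.0 - elitism) + slope * ranks
    return w / w.sum()


def _evaluate(objective, pop, cache, workers):
    """Scores for a population, memoized by candidate bytes.

    Results are independent of ``workers`` (scores are attached by
    candidate identity; evaluation is pure).
    """
    keys = [p.tobytes() for p in pop]
    todo = [i for i, k in enumerate(keys) if k not in cache]
    if todo:
        if workers > 1:
            from joblib import Parallel, delayed

            vals = Parallel(n_jobs=workers)(
                delayed(objective)(pop[i]) for i in todo
            )
        else:
            vals = [objective(pop[i]) for i in todo]
        for i, v in zip(todo, vals):
            cache[keys[i]] = float(v)
    return np.array([cache[k] for k in keys])


def ga_minimize(objective: Callable[[np.ndarray], float], config: GAConfig,
                target_score: Optional[float] = None,
                callback: Optional[Callable[[int, float], None]] = None) -> GAResult:
    """Minimize ``objective`` over the box; reproducible from ``config.seed``.

    ``objective`` must be total on the box (return finite scores, mapping
    failures to penalties).  ``target_score`` stops the run early once the
    best-ever score falls below it.  Survivor selection keeps the best of
    parents and offspring, so the best-so-far history is non-increasing.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = len(config.bounds)
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    pop = rng.uniform(lo, hi, size=(config.population, n_genes))
    cache: dict = {}
    scores = _evaluate(objective, pop, cache, config.workers)

    best_idx = int(np.argmin(scores))
    best = pop[best_idx].copy()
    best_score = float(scores[best_idx])
    history = [best_score]
    if callback is not None:
        callback(0, best_score)

    for gen in range(1, config.generations + 1):
        if target_score is not None and best_score < target_score:
            break
        order = np.argsort(scores, kind="stable")[::-1]     # worst to best
        probs = _rank_weights(config.population, config.elitism)
        # breed one offspring per slot
        parents_a = order[rng.choice(config.population, size=config.population, p=probs)]
        parents_b = order[rng.choice(config.population, size=config.population, p=probs)]
        mask = rng.random((config.population, n_genes)) < 0.5
        children = np.where(mask, pop[parents_a], pop[parents_b])
        mut = rng.random((config.population, n_genes)) < config.mutation_rate
        resampled = rng.uniform(lo, hi, size=(config.population, n_genes))
        children = np.where(mut, resampled, children)
        child_scores = _evaluate(objective, children, cache, config.workers)
        # (mu+lambda) survivor selection: parents and offspring compete
        combined = np.vstack([pop, children])
        combined_scores = np.concatenate([scores, child_scores])
        keep = np.argsort(combined_scores, kind="stable")[:config.population]
        pop = combined[keep]
        scores = combined_scores[keep]
        if scores[0] < best_score:
            best_score = float(scores[0])
            best = pop[0].copy()
        history.append(best_score)
        if callback is not None:
            callback(gen, best_score)

    return GAResult(best=best, best_score=best_score, history=history,
                    population=pop, scores=scores)
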