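"""NSGA-II over binary feature masks.

Bi-objective wrapper feature selection: each individual is a 512-bit mask
over the feature-matrix columns, and the algorithm simultaneously
minimizes

* O1 — the number of selected features (popcount of the mask), and
* O2 — the mean cross-validated error rate (percent) of the GRNN trained
  on the masked columns.

The loop is the canonical elitist NSGA-II: fast non-dominated sorting
assigns Pareto ranks, crowding distance preserves spread along each
front, parents are chosen by binary tournament under the crowded
comparison operator, offspring arise from uniform crossover and per-bit
mutation, and environmental selection fills the next generation front by
front from the combined parent+offspring pool, truncating the split
front by descending crowding distance.

Because the cross-validation splits are fixed for the whole run, the
objective is a deterministic function of the mask; evaluations are
memoized by mask bytes and the best error on the first front can never
worsen across generations (elitism).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ictalemo import evaluation
from ictalemo.feature_extraction import FeatureMatrix
from ictalemo import grnn

logger = logging.getLogger(__name__)


@dataclass
class Individual:
    """A candidate feature subset: boolean mask plus objectives, rank and crowding."""

    mask: np.ndarray
    o1: int | None = None  # selected-feature count
    o2: float | None = None  # mean CV error rate, percent
    rank: int | None = None
    crowding: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def evaluated(self) -> bool:
        return self.o1 is not None and self.o2 is not None

    @property
    def objectives(self) -> tuple[float, float]:
        assert self.o1 is not None and self.o2 is not None
        return (float(self.o1), float(self.o2))

    def copy(self) -> "Individual":
        return Individual(mask=self.mask.copy(), o1=self.o1, o2=self.o2)


@dataclass
class EAConfig:
    """Evolutionary-loop settings.

    pop_size must be even (pairwise crossover); mutation defaults to one
    expected bit flip per offspring (1/512). ``crowding_metric`` selects
    the canonical normalized-gap crowding distance ('cuboid') or the raw
    Euclidean nearest-neighbor variant ('euclidean').
    """

    pop_size: int = 10
    n_generations: int = 500
    crossover_prob: float = 0.9
    mutation_prob_per_bit: float = 1.0 / 512.0
    tournament_size: int = 2
    seed: int = 0
    cv_iterations: int = 10
    sigma: float = grnn.DEFAULT_SIGMA
    crossover: str = "uniform"  # or "single_point"
    crowding_metric: str = "cuboid"  # or "euclidean"
    early_stop_patience: int | None = None  # generations with unchanged front

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 4")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0 <= self.crossover_prob <= 1 or not 0 <= self.mutation_prob_per_bit <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class ParetoArchive:
    """Result of a run: final population, rank-1 front, and the selected solution."""

    individuals: list[Individual]
    config: EAConfig
    history: list[dict] = field(default_factory=list)
    selected: Individual | None = None

    @property
    def front(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.rank == 1]

    def front_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for ind in self.front:
            rec = {f"bit{j:03d}": int(b) for j, b in enumerate(ind.mask)}
            rec.update(o1=ind.o1, o2=ind.o2, crowding=ind.crowding)
            rows.append(rec)
        pd.DataFrame(rows).to_csv(path, index=False)

    def plot_front(self, path: str | Path) -> None:
        """Objective-space scatter of the rank-1 front (O1 vs O2)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        o1 = [ind.o1 for ind in self.front]
        o2 = [ind.o2 for ind in self.front]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(o1, o2, c="tab:blue", label="rank-1 front")
        if self.selected is not None:
            ax.scatter([self.selected.o1], [self.selected.o2], c="tab:red", marker="*", s=160, label="selected")
        ax.set_xlabel("O1: number of features")
        ax.set_ylabel("O2: mean CV error rate (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """An all-false mask gets one uniformly chosen bit set; others pass through."""
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def init_population(n: int, length: int, rng: np.random.Generator) -> list[Individual]:
    """Random masks, each bit included with probability 0.5; empty masks repaired."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    return [Individual(mask=_repair(rng.random(length) < 0.5, rng)) for _ in range(n)]


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance for minimization: a <= b everywhere, < somewhere."""
    a0, a1 = a
    b0, b1 = b
    return a0 <= b0 and a1 <= b1 and (a0 < b0 or a1 < b1)


def fast_non_dominated_sort(objectives: Sequence[Sequence[float]]) -> list[list[int]]:
    """Partition indices into Pareto fronts (front 0 = non-dominated set)."""
    n = len(objectives)
    if n == 0:
        raise ValueError("empty population")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominators = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objectives[i], objectives[j]):
                dominated_by[i].append(j)
                n_dominators[j] += 1
            elif dominates(objectives[j], objectives[i]):
                dominated_by[j].append(i)
                n_dominators[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominators[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                n_dominators[j] -= 1
                if n_dominators[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(front_objectives: Sequence[Sequence[float]], metric: str = "cuboid") -> np.ndarray:
    """Density estimate along one front; boundary members get infinity.

    'cuboid' (default) is the canonical normalized neighbor-gap sum: for
    each objective the front is sorted, the extremes get infinite
    distance, and interior members accumulate
    (next - previous) / (max - min). 'euclidean' instead assigns each
    interior member its raw Euclidean distance to the nearest other
    front member (extremes still infinite), kept for comparison.
    """
    objs = np.asarray(front_objectives, dtype=np.float64)
    n = objs.shape[0]
    if n == 0:
        raise ValueError("empty front")
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    if metric == "euclidean":
        from scipy.spatial.distance import cdist as _cdist

        d = _cdist(objs, objs)
        np.fill_diagonal(d, np.inf)
        dist = d.min(axis=1)
        for m in range(objs.shape[1]):
            order = np.argsort(objs[:, m], kind="stable")
            dist[order[0]] = np.inf
            dist[order[-1]] = np.inf
        return dist
    if metric != "cuboid":
        raise ValueError(f"unknown crowding metric {metric!r}")
    for m in range(objs.shape[1]):
        order = np.argsort(objs[:, m], kind="stable")
        lo, hi = objs[order[0], m], objs[order[-1], m]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if hi > lo:
            gaps = (objs[order[2:], m] - objs[order[:-2], m]) / (hi - lo)
            dist[order[1:-1]] += gaps
    return dist


def crowded_compare(a: Individual, b: Individual, rng: np.random.Generator) -> Individual:
    """Crowded comparison: lower rank wins, then larger crowding, then coin flip."""
    if a.rank is None or b.rank is None or a.crowding is None or b.crowding is None:
        raise RuntimeError("individuals must be ranked before crowded comparison")
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a if rng.random() < 0.5 else b


def _assign_rank_and_crowding(pop: list[Individual], metric: str = "cuboid") -> list[list[int]]:
    fronts = fast_non_dominated_sort([ind.objectives for ind in pop])
    for r, front in enumerate(fronts, start=1):
        dists = crowding_distance([pop[i].objectives for i in front], metric=metric)
        for i, d in zip(front, dists):
            pop[i].rank = r
            pop[i].crowding = float(d)
    return fronts


def make_offspring(parents: list[Individual], cfg: EAConfig, rng: np.random.Generator) -> list[Individual]:
    """Binary-tournament selection, crossover, per-bit mutation, empty-mask repair."""
    length = parents[0].mask.size
    offspring: list[Individual] = []
    while len(offspring) < cfg.pop_size:
        p1 = crowded_compare(parents[rng.integers(len(parents))], parents[rng.integers(len(parents))], rng)
        p2 = crowded_compare(parents[rng.integers(len(parents))], parents[rng.integers(len(parents))], rng)
        c1, c2 = p1.mask.copy(), p2.mask.copy()
        if rng.random() < cfg.crossover_prob:
            if cfg.crossover == "uniform":
                swap = rng.random(length) < 0.5
            elif cfg.crossover == "single_point":
                point = rng.integers(1, length)
                swap = np.arange(length) >= point
            else:
                raise ValueError(f"unknown crossover {cfg.crossover!r}")
            c1[swap], c2[swap] = p2.mask[swap], p1.mask[swap]
        for child in (c1, c2):
            flips = rng.random(length) < cfg.mutation_prob_per_bit
            child ^= flips
            offspring.append(Individual(mask=_repair(child, rng)))
    return offspring[: cfg.pop_size]


class ObjectiveEvaluator:
    """Memoized (O1, O2) evaluation of a mask against a feature matrix.

    O2 is the mean error of randomized sub-sampling CV; the CV seed is
    fixed at construction so every mask in a run is scored on identical
    splits, making the objective deterministic and cacheable.
    """

    def __init__(self, fm: FeatureMatrix, cfg: EAConfig, cv_seed: int):
        self.fm = fm
        self.cfg = cfg
        self.cv_seed = cv_seed
        self._cache: dict[bytes, float] = {}
        self.n_cv_calls = 0

    def __call__(self, ind: Individual) -> Individual:
        key = np.packbits(ind.mask).tobytes()
        if key not in self._cache:
            self.n_cv_calls += 1
            self._cache[key] = evaluation.random_subsample_cv(
                self.fm,
                mask=ind.mask,
                n_iter=self.cfg.cv_iterations,
                sigma=self.cfg.sigma,
                seed=self.cv_seed,
            )
        ind.o1 = int(ind.mask.sum())
        ind.o2 = self._cache[key]
        return ind


def evaluate_objectives(ind: Individual, fm: FeatureMatrix, cfg: EAConfig, cv_seed: int = 0) -> Individual:
    """Convenience single-mask evaluation (no cross-run memoization)."""
    return ObjectiveEvaluator(fm, cfg, cv_seed)(ind)


def _environmental_selection(pool: list[Individual], cfg: EAConfig) -> list[Individual]:
    """Fill the next generation front by front; truncate the split front by crowding."""
    fronts = _assign_rank_and_crowding(pool, metric=cfg.crowding_metric)
    nxt: list[Individual] = []
    for front in fronts:
        members = [pool[i] for i in front]
        if len(nxt) + len(members) <= cfg.pop_size:
            nxt.extend(members)
        else:
            # stable sort by descending crowding; index order breaks ties
            members.sort(key=lambda ind: -ind.crowding)  # type: ignore[operator]
            nxt.extend(members[: cfg.pop_size - len(nxt)])
            break
    return nxt


def run_nsga2(
    fm: FeatureMatrix,
    cfg: EAConfig,
    cv_seed: int | None = None,
    progress: Callable[[dict], None] | None = None,
) -> ParetoArchive:
    """Run the elitist NSGA-II loop for cfg.n_generations generations.

    Per generation: make offspring from the ranked parents, evaluate,
    combine parents and offspring (2N pool), and select the next
    generation front by front. Optional early stop when the rank-1
    objective set is unchanged for ``cfg.early_stop_patience``
    generations. Fully deterministic under (fm, cfg, cv_seed).
    """
    rng = np.random.default_rng(cfg.seed)
    if cv_seed is None:
        cv_seed = cfg.seed
    evaluate = ObjectiveEvaluator(fm, cfg, cv_seed)
    pop = [evaluate(ind) for ind in init_population(cfg.pop_size, fm.n_features, rng)]
    _assign_rank_and_crowding(pop, metric=cfg.crowding_metric)
    history: list[dict] = []
    stagnant = 0
    prev_front_key: frozenset | None = None
    for gen in range(cfg.n_generations):
        offspring = [evaluate(ind) for ind in make_offspring(pop, cfg, rng)]
        pop = _environmental_selection(pop + offspring, cfg)
        front = [ind for ind in pop if ind.rank == 1]
        record = {
            "generation": gen + 1,
            "front_size": len(front),
            "best_o2": min(ind.o2 for ind in front),
            "min_o1": min(ind.o1 for ind in front),
            "cv_calls": evaluate.n_cv_calls,
        }
        history.append(record)
        logger.info(
            "gen %d: front size %d, best Er %.2f%%, min features %d",
            record["generation"], record["front_size"], record["best_o2"], record["min_o1"],
        )
        if progress is not None:
            progress(record)
        front_key = frozenset(ind.objectives for ind in front)
        if cfg.early_stop_patience is not None:
            stagnant = stagnant + 1 if front_key == prev_front_key else 0
            if stagnant >= cfg.early_stop_patience:
                break
        prev_front_key = front_key
    archive = ParetoArchive(individuals=pop, config=cfg, history=history)
    archive.selected = select_solution(archive, np.random.default_rng(cfg.seed + 1))
    return archive


def select_solution(archive: ParetoArchive, rng: np.random.Generator) -> Individual:
    """Knockout binary tournament among rank-1 members down to a single winner.

    Each round pairs the shuffled survivors and keeps the crowded-compare
    winner of every pair; with an odd count the unpaired member advances.
    The result is stored on the archive.
    """
    front = archive.front
    if not front:
        raise RuntimeError("archive has no rank-1 front")
    contenders = list(front)
    order = rng.permutation(len(contenders))
    contenders = [contenders[i] for i in order]
    while len(contenders) > 1:
        nxt = []
        for i in range(0, len(contenders) - 1, 2):
            nxt.append(crowded_compare(contenders[i], contenders[i + 1], rng))
        if len(contenders) % 2:
            nxt.append(contenders[-1])
        contenders = nxt
    archive.selected = contenders[0]
    return contenders[0]
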