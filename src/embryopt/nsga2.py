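"""Elitist bi-objective NSGA-II with ideal-point selection on the final front.

Both objectives are maximized.  The ideal-point rule picks the front member
closest (Euclidean) to the pair of maxima observed in the training data,
written (m, n_ref).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class Individual:
    """Decision vector with its objectives and NSGA-II bookkeeping."""

    x: np.ndarray
    objectives: tuple[float, float]
    rank: int = -1
    crowding: float = 0.0


@dataclass
class NsgaConfig:
    pop_size: int = 100
    n_generations: int = 200
    eta_c: float = 15.0  # SBX distribution index
    p_c: float = 0.9  # crossover probability
    eta_m: float = 20.0  # polynomial-mutation distribution index
    p_m: float | None = None  # per-gene mutation probability, default 1/d
    seed: int = 0
    bounds: np.ndarray | None = None  # d x 2 (min, max) per feature

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 4")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)


@dataclass
class IdealPointResult:
    m: float
    n_ref: float
    selected: Individual
    distance: float


def dominates(a: Individual, b: Individual) -> bool:
    """True iff a is at least as good in both objectives and better in one."""
    a1, a2 = a.objectives
    b1, b2 = b.objectives
    return (a1 >= b1 and a2 >= b2) and (a1 > b1 or a2 > b2)


def fast_nondominated_sort(population: list[Individual]) -> list[list[Individual]]:
    """Partition a population into non-dominated fronts (Deb's algorithm).

    Assigns ``rank`` on every individual; front 0 holds exactly the
    non-dominated members.
    """
    if not population:
        raise ValueError("population must be nonempty")
    n = len(population)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(population[i], population[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(population[j], population[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
    for i in range(n):
        if domination_count[i] == 0:
            population[i].rank = 0
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt: list[int] = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    population[j].rank = k + 1
                    nxt.append(j)
        k += 1
        fronts.append(nxt)
    return [[population[i] for i in f] for f in fronts[:-1]]


def crowding_distance(front: list[Individual]) -> None:
    """Assign crowding distances within one front (in place).

    Boundary individuals per objective get +inf; interior individuals sum
    the normalized gap between their two neighbors over both objectives.  A
    constant objective contributes nothing.
    """
    if not front:
        raise ValueError("front must be nonempty")
    for ind in front:
        ind.crowding = 0.0
    n = len(front)
    if n <= 2:
        for ind in front:
            ind.crowding = math.inf
        return
    for obj in range(2):
        order = sorted(front, key=lambda ind: ind.objectives[obj])
        fmin = order[0].objectives[obj]
        fmax = order[-1].objectives[obj]
        order[0].crowding = math.inf
        order[-1].crowding = math.inf
        if fmax == fmin:
            continue
        for i in range(1, n - 1):
            gap = order[i + 1].objectives[obj] - order[i - 1].objectives[obj]
            order[i].crowding += gap / (fmax - fmin)


def tournament_winner(a: Individual, b: Individual, rng: np.random.Generator) -> Individual:
    """Pairwise comparison: lower rank wins, then larger crowding, then coin flip."""
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a if rng.random() < 0.5 else b


def tournament_select(population: list[Individual], rng: np.random.Generator) -> Individual:
    """Binary tournament between two uniformly drawn candidates."""
    i, j = rng.integers(len(population), size=2)
    return tournament_winner(population[int(i)], population[int(j)], rng)


def sbx_crossover(
    p1: np.ndarray, p2: np.ndarray, config: NsgaConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover; children clipped to bounds."""
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() <= config.p_c:
        eta = config.eta_c
        for k in range(p1.size):
            if rng.random() > 0.5 or p1[k] == p2[k]:
                continue
            x1, x2 = (p1[k], p2[k]) if p1[k] < p2[k] else (p2[k], p1[k])
            u = rng.random()
            # bounds-aware SBX (Deb & Agrawal): the spread factor is chosen
            # so children cannot leave [lo, hi]
            for child, sign in ((0, -1.0), (1, +1.0)):
                if sign < 0:
                    beta = 1.0 + 2.0 * (x1 - lo[k]) / (x2 - x1)
                else:
                    beta = 1.0 + 2.0 * (hi[k] - x2) / (x2 - x1)
                alpha = 2.0 - beta ** -(eta + 1.0)
                if u <= 1.0 / alpha:
                    betaq = (u * alpha) ** (1.0 / (eta + 1.0))
                else:
                    betaq = (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta + 1.0))
                val = 0.5 * ((x1 + x2) + sign * betaq * (x2 - x1))
                if child == 0:
                    c1[k] = min(max(val, lo[k]), hi[k])
                else:
                    c2[k] = min(max(val, lo[k]), hi[k])
    return c1, c2


def polynomial_mutation(
    x: np.ndarray, config: NsgaConfig, rng: np.random.Generator
) -> np.ndarray:
    """Polynomial mutation; result clipped to bounds."""
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    p_m = config.p_m if config.p_m is not None else 1.0 / x.size
    eta = config.eta_m
    y = x.copy()
    for k in range(x.size):
        if rng.random() > p_m or hi[k] == lo[k]:
            continue
        u = rng.random()
        span = hi[k] - lo[k]
        # bounds-aware polynomial mutation: the perturbation shrinks as the
        # gene approaches a bound, so no clipping is needed
        d1 = (x[k] - lo[k]) / span
        d2 = (hi[k] - x[k]) / span
        if u < 0.5:
            delta = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)) ** (
                1.0 / (eta + 1.0)
            ) - 1.0
        else:
            delta = 1.0 - (
                2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)
            ) ** (1.0 / (eta + 1.0))
        y[k] = min(max(x[k] + delta * span, lo[k]), hi[k])
    return y


def _evaluate(objective_fn, x: np.ndarray) -> tuple[float, float]:
    f1, f2 = objective_fn(x)
    if not (math.isfinite(f1) and math.isfinite(f2)):
        raise FloatingPointError(f"non-finite objective at x = {x.tolist()}")
    return float(f1), float(f2)


def _assign_ranks_and_crowding(population: list[Individual]) -> list[list[Individual]]:
    fronts = fast_nondominated_sort(population)
    for front in fronts:
        crowding_distance(front)
    return fronts


def evolve(objective_fn, config: NsgaConfig, on_generation=None) -> list[Individual]:
    """Run the NSGA-II main loop; returns front 0 of the final population.

    Per generation: binary-tournament parents, SBX crossover, polynomial
    mutation, merge of parents and offspring, non-dominated sort, and
    elitist truncation by rank then descending crowding.  Fully reproducible
    for a fixed seed.  ``on_generation(gen, front)`` is invoked with the
    current first front after each generation, e.g. for hypervolume logging.
    """
    if config.bounds is None:
        raise ValueError("config.bounds must be set")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    d = lo.size

    pop = [
        Individual(x=x, objectives=_evaluate(objective_fn, x))
        for x in rng.uniform(lo, hi, size=(config.pop_size, d))
    ]
    _assign_ranks_and_crowding(pop)

    for gen in range(config.n_generations):
        offspring: list[Individual] = []
        while len(offspring) < config.pop_size:
            p1 = tournament_select(pop, rng)
            p2 = tournament_select(pop, rng)
            c1, c2 = sbx_crossover(p1.x, p2.x, config, rng)
            for c in (c1, c2):
                c = polynomial_mutation(c, config, rng)
                offspring.append(Individual(x=c, objectives=_evaluate(objective_fn, c)))
        merged = pop + offspring[: config.pop_size]
        fronts = _assign_ranks_and_crowding(merged)
        nxt: list[Individual] = []
        for front in fronts:
            if len(nxt) + len(front) <= config.pop_size:
                nxt.extend(front)
            else:
                front.sort(key=lambda ind: -ind.crowding)
                nxt.extend(front[: config.pop_size - len(nxt)])
                break
        pop = nxt
        _assign_ranks_and_crowding(pop)
        if on_generation is not None:
            on_generation(gen, [ind for ind in pop if ind.rank == 0])

    return [ind for ind in pop if ind.rank == 0]


def select_ideal_point(
    front: list[Individual], m: float, n_ref: float
) -> IdealPointResult:
    """Pick the front member closest to the observed maxima (m, n_ref).

    Distance is Euclidean in objective space; ties break toward higher
    first objective, then lexicographically smaller decision vector.
    """
    if not front:
        raise ValueError("front must be nonempty")

    def key(ind: Individual):
        f1, f2 = ind.objectives
        dist = math.hypot(f1 - m, f2 - n_ref)
        return (dist, -f1, tuple(ind.x))

    best = min(front, key=key)
    f1, f2 = best.objectives
    return IdealPointResult(
        m=m, n_ref=n_ref, selected=best, distance=math.hypot(f1 - m, f2 - n_ref)
    )
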