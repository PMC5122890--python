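"""Multiobjective evolutionary engine for per-node sparse network recovery.

Each candidate solution is a nonnegative weight vector w over the N-1
possible neighbors of a focal node, scored on two conflicting objectives

    f1(w) = ||Y - A w||_2        (measurement error)
    f2(w) = ||w||_1              (structural sparsity)

so the parameter-free alternative to a penalized fit is to evolve the whole
Pareto front of (f1, f2) tradeoffs and pick one solution afterwards.  The
engine is an elitist dominance-based EA in the NSGA-II mold — fast
nondominated sorting, crowding distance, binary-tournament mating,
simulated binary crossover and polynomial mutation — augmented with a
soft-thresholding operator that shrinks offspring toward sparse vectors.
The population is seeded either from a nonnegative-lasso path over a grid
of penalties (IPL) or uniformly at random (IPR).

All heavy per-generation work is vectorized over the population; the public
dataclasses exist at the API boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .linear_system import LocalSystem
from .sparse_solvers import lasso_path, null_threshold

__all__ = [
    "CandidateSolution",
    "Population",
    "ParetoFront",
    "MOEAConfig",
    "evaluate",
    "evaluate_batch",
    "dominates",
    "nondominated_sort",
    "crowding_distance",
    "soft_threshold",
    "init_population",
    "variation",
    "run_moeanet",
    "hypervolume_2d",
]

logger = logging.getLogger(__name__)


@dataclass
class CandidateSolution:
    """One putative neighbor-weight vector with its two objective values."""

    weights: np.ndarray
    f1: float
    f2: float
    rank: int | None = None
    crowding: float | None = None

    @property
    def objectives(self) -> tuple[float, float]:
        return (self.f1, self.f2)


@dataclass
class Population:
    members: list[CandidateSolution]
    generation: int = 0


@dataclass
class ParetoFront:
    """Mutually nondominated solutions, sorted by ascending f1."""

    solutions: list[CandidateSolution]

    def __len__(self) -> int:
        return len(self.solutions)

    @property
    def objectives(self) -> np.ndarray:
        return np.array([[s.f1, s.f2] for s in self.solutions])

    @property
    def weight_matrix(self) -> np.ndarray:
        return np.array([s.weights for s in self.solutions])

    def dump(self, path) -> None:
        """Delimited text: f1, f2, then the weight vector, one row per solution."""
        rows = np.column_stack([self.objectives, self.weight_matrix])
        np.savetxt(path, rows, delimiter="\t")


@dataclass
class MOEAConfig:
    pop_size: int = 100
    generations: int = 200
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1/n_candidates
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    soft_threshold_prob: float = 0.25
    init: str = "IPL"
    lambda_grid: np.ndarray | None = None
    include_lambdas: tuple[float, ...] = (0.001,)
    weight_upper: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("crossover_prob", "soft_threshold_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.mutation_prob is not None and not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.init not in ("IPL", "IPR"):
            raise ValueError(f"init must be 'IPL' or 'IPR'; got {self.init!r}")
        if self.lambda_grid is not None and len(self.lambda_grid) != self.pop_size:
            raise ValueError("lambda_grid length must equal pop_size")


# ---------------------------------------------------------------------------
# objectives and dominance


def evaluate(weights: np.ndarray, system: LocalSystem) -> tuple[float, float]:
    """(f1, f2) = (Euclidean measurement error, L1 sparsity) of one vector."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (system.n_candidates,):
        raise ValueError(
            f"weights have shape {weights.shape}, expected ({system.n_candidates},)"
        )
    f1 = float(np.linalg.norm(system.Y - system.A @ weights))
    f2 = float(np.sum(np.abs(weights)))
    return f1, f2


def evaluate_batch(W: np.ndarray, system: LocalSystem) -> np.ndarray:
    """Objective matrix (rows: candidates, columns: f1, f2) for a population."""
    resid = system.Y[:, None] - system.A @ W.T
    f1 = np.linalg.norm(resid, axis=0)
    f2 = np.abs(W).sum(axis=1)
    return np.column_stack([f1, f2])


def _objs(x) -> tuple[float, float]:
    if isinstance(x, CandidateSolution):
        return x.objectives
    a = tuple(float(v) for v in x)
    return a  # type: ignore[return-value]


def dominates(a, b) -> bool:
    """Pareto dominance for minimization: a <= b in both objectives, < in one."""
    fa, fb = _objs(a), _objs(b)
    return fa[0] <= fb[0] and fa[1] <= fb[1] and (fa[0] < fb[0] or fa[1] < fb[1])


def _front_matrix(pop) -> np.ndarray:
    if isinstance(pop, Population):
        return np.array([[s.f1, s.f2] for s in pop.members])
    return np.asarray(pop, dtype=float)


def _peel_first_front_2d(F: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One sweep peel of the nondominated subset of F[idx] (2 objectives).

    ``idx`` must be presorted by (f1 asc, f2 asc).  Returns (front, rest),
    both preserving the sorted order.  Duplicate objective vectors are
    mutually nondominated and stay together.
    """
    f1 = F[idx, 0]
    f2 = F[idx, 1]
    # group by equal f1; within a group the first (f2-sorted) entry is minimal
    first = np.concatenate([[True], f1[1:] != f1[:-1]])
    group_id = np.cumsum(first) - 1
    group_min = f2[first][group_id]
    # min f2 among groups with strictly smaller f1 (exclusive prefix minimum)
    acc = np.minimum.accumulate(f2[first])
    prev_best = np.concatenate([[np.inf], acc[:-1]])[group_id]
    keep = (f2 == group_min) & (f2 < prev_best)
    return idx[keep], idx[~keep]


def nondominated_sort(pop) -> list[np.ndarray]:
    """Fast nondominated sorting of a Population or an (n, 2) objective array.

    Returns index arrays, one per front, rank 0 first.  Implemented as
    repeated sorted-sweep peeling (O(n log n) per front for 2 objectives).
    """
    F = _front_matrix(pop)
    order = np.lexsort((F[:, 1], F[:, 0]))
    fronts: list[np.ndarray] = []
    rest = order
    while rest.size:
        front, rest = _peel_first_front_2d(F, rest)
        fronts.append(np.sort(front))
    if isinstance(pop, Population):
        for rank, idx in enumerate(fronts):
            for i in idx:
                pop.members[i].rank = rank
    return fronts


def crowding_distance(front) -> np.ndarray:
    """NSGA-II crowding distance; boundary members get infinite crowding."""
    F = _front_matrix(front)
    n = F.shape[0]
    d = np.zeros(n)
    if n <= 2:
        d[:] = np.inf
        return d
    for k in range(F.shape[1]):
        order = np.argsort(F[:, k], kind="stable")
        vals = F[order, k]
        span = vals[-1] - vals[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (vals[2:] - vals[:-2]) / span
    return d


# ---------------------------------------------------------------------------
# initialization


def soft_threshold(weights: np.ndarray, theta: float) -> np.ndarray:
    """Nonnegative shrinkage max(w - theta, 0); the sparsifying operator."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0; got {theta}")
    return np.maximum(np.asarray(weights, dtype=float) - theta, 0.0)


def _initial_weights(system: LocalSystem, config: MOEAConfig,
                     rng: np.random.Generator) -> np.ndarray:
    n = system.n_candidates
    if config.init == "IPR":
        return rng.uniform(0.0, 3.0, size=(config.pop_size, n))
    # IPL: one lasso seed per penalty on a log grid up to the null threshold,
    # so the largest penalty contributes the all-zero vector and the smallest
    # a dense, low-error vector.
    if config.lambda_grid is not None:
        lams = np.asarray(config.lambda_grid, dtype=float)
    else:
        lam_max = max(null_threshold(system), 1e-12)
        extra = [lam for lam in config.include_lambdas if lam >= 0]
        n_grid = max(config.pop_size - len(extra), 2)
        lams = lam_max * np.geomspace(1e-4, 1.0, n_grid)
        # always seed the practitioner's baseline penalties too, so the
        # evolved front weakly dominates every single-lambda lasso fit
        lams = np.concatenate([lams, extra])[: config.pop_size]
    W = np.zeros((config.pop_size, n))
    try:
        sols = lasso_path(system, lams)
    except Exception:
        logger.warning("lasso initialization failed entirely; falling back to zero seeds",
                       exc_info=True)
        return W
    for k, sol in enumerate(sols):
        W[k] = sol.weights
    return W


def init_population(system: LocalSystem, config: MOEAConfig) -> Population:
    """Seed and evaluate the generation-0 population (IPL or IPR)."""
    rng = np.random.default_rng(config.seed)
    W = _initial_weights(system, config, rng)
    F = evaluate_batch(W, system)
    members = [CandidateSolution(W[k].copy(), float(F[k, 0]), float(F[k, 1]))
               for k in range(W.shape[0])]
    return Population(members=members, generation=0)


# ---------------------------------------------------------------------------
# variation operators (vectorized over the offspring batch)


def _sbx(p1: np.ndarray, p2: np.ndarray, eta: float, cx_prob: float,
         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover; identical parents yield identical children."""
    shape = p1.shape
    u = rng.random(shape)
    beta = np.where(u <= 0.5,
                    (2.0 * u) ** (1.0 / (eta + 1.0)),
                    (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
    # gene-level exchange mask and pair-level crossover mask
    gene = rng.random(shape) < 0.5
    pair = (rng.random((shape[0], 1)) < cx_prob)
    beta = np.where(gene & pair, beta, 1.0)
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return c1, c2


def _polynomial_mutation(W: np.ndarray, eta: float, prob: float, upper: float,
                         rng: np.random.Generator) -> np.ndarray:
    x = np.clip(W, 0.0, upper)
    mask = rng.random(x.shape) < prob
    u = rng.random(x.shape)
    d1 = x / upper
    d2 = 1.0 - d1
    exp = 1.0 / (eta + 1.0)
    lo = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)) ** exp - 1.0
    hi = 1.0 - (2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)) ** exp
    delta = np.where(u <= 0.5, lo, hi)
    return np.where(mask, np.clip(x + delta * upper, 0.0, upper), x)


def _tournament(rank: np.ndarray, crowd: np.ndarray, k: int,
                rng: np.random.Generator) -> np.ndarray:
    a = rng.integers(0, rank.size, size=k)
    b = rng.integers(0, rank.size, size=k)
    better_b = (rank[b] < rank[a]) | ((rank[b] == rank[a]) & (crowd[b] > crowd[a]))
    return np.where(better_b, b, a)


def variation(W_parents: np.ndarray, config: MOEAConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Produce an offspring batch: SBX + polynomial mutation + occasional
    soft-thresholding, everything clipped to the feasible region w >= 0."""
    n_par, n = W_parents.shape
    half = n_par // 2
    p1 = W_parents[:half]
    p2 = W_parents[half:2 * half]
    c1, c2 = _sbx(p1, p2, config.eta_crossover, config.crossover_prob, rng)
    children = np.vstack([c1, c2])
    if n_par % 2:  # odd leftover parent passes through
        children = np.vstack([children, W_parents[-1:]])
    pm = config.mutation_prob if config.mutation_prob is not None else 1.0 / n
    children = _polynomial_mutation(children, config.eta_mutation, pm,
                                    config.weight_upper, rng)
    # sparsify a random subset of offspring
    st_mask = rng.random(children.shape[0]) < config.soft_threshold_prob
    if st_mask.any():
        pos_mean = np.array([
            children[k][children[k] > 0].mean() if (children[k] > 0).any() else 0.0
            for k in np.flatnonzero(st_mask)
        ])
        thetas = rng.uniform(0.0, 0.5 * pos_mean + 1e-12)
        for theta, k in zip(thetas, np.flatnonzero(st_mask)):
            children[k] = soft_threshold(children[k], theta)
    return np.clip(children, 0.0, config.weight_upper)


# ---------------------------------------------------------------------------
# main loop


def _environmental_selection(F: np.ndarray, pop_size: int) -> np.ndarray:
    """Elitist mu+lambda truncation by nondomination rank, then crowding."""
    fronts = nondominated_sort(F)
    keep: list[np.ndarray] = []
    total = 0
    for idx in fronts:
        if total + idx.size <= pop_size:
            keep.append(idx)
            total += idx.size
        else:
            room = pop_size - total
            crowd = crowding_distance(F[idx])
            order = np.argsort(-crowd, kind="stable")
            keep.append(idx[order[:room]])
            total = pop_size
        if total >= pop_size:
            break
    return np.concatenate(keep)


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = nondominated_sort(F)
    rank = np.empty(F.shape[0], dtype=int)
    crowd = np.empty(F.shape[0])
    for r, idx in enumerate(fronts):
        rank[idx] = r
        crowd[idx] = crowding_distance(F[idx])
    return rank, crowd


def _dedup_front(W: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse duplicate objective vectors, keeping the smallest index."""
    _, first = np.unique(F, axis=0, return_index=True)
    keep = np.sort(first)
    return W[keep], F[keep]


def run_moeanet(system: LocalSystem, config: MOEAConfig) -> ParetoFront:
    """Evolve the population and return the final nondominated front.

    Generation loop: mating selection (binary tournament on rank then
    crowding) -> variation -> merge parents and offspring -> elitist
    truncation back to ``pop_size``.  An external archive keeps every
    nondominated solution encountered (capped at 4x pop_size by crowding),
    so good lasso seeds cannot be lost to diversity pressure; the archive
    is the returned front, deduplicated in objective space and sorted by
    ascending f1 (ties by f2).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    W = _initial_weights(system, config, rng)
    F = evaluate_batch(W, system)
    # external elitist archive: every nondominated solution ever encountered
    # survives here even if crowding truncation drops it from the population
    arc_idx = nondominated_sort(F)[0]
    W_arc, F_arc = _dedup_front(W[arc_idx], F[arc_idx])
    cap = 4 * config.pop_size
    for _ in range(config.generations):
        rank, crowd = _rank_and_crowd(F)
        parents = _tournament(rank, crowd, config.pop_size, rng)
        children = variation(W[parents], config, rng)
        Fc = evaluate_batch(children, system)
        W_all = np.vstack([W, children])
        F_all = np.vstack([F, Fc])
        keep = _environmental_selection(F_all, config.pop_size)
        W, F = W_all[keep], F_all[keep]
        W_pool = np.vstack([W_arc, children])
        F_pool = np.vstack([F_arc, Fc])
        first = nondominated_sort(F_pool)[0]
        W_arc, F_arc = _dedup_front(W_pool[first], F_pool[first])
        if F_arc.shape[0] > cap:
            crowd_arc = crowding_distance(F_arc)
            keep_arc = np.sort(np.argsort(-crowd_arc, kind="stable")[:cap])
            W_arc, F_arc = W_arc[keep_arc], F_arc[keep_arc]
    Wf, Ff = W_arc, F_arc
    order = np.lexsort((Ff[:, 1], Ff[:, 0]))
    solutions = [
        CandidateSolution(Wf[k].copy(), float(Ff[k, 0]), float(Ff[k, 1]), rank=0)
        for k in order
    ]
    return ParetoFront(solutions=solutions)


def hypervolume_2d(front_objectives: np.ndarray, reference: np.ndarray) -> float:
    """Hypervolume (area dominated up to ``reference``) of a 2-D minimization front."""
    F = np.asarray(front_objectives, dtype=float)
    ref = np.asarray(reference, dtype=float)
    F = F[(F[:, 0] <= ref[0]) & (F[:, 1] <= ref[1])]
    if F.size == 0:
        return 0.0
    order = np.lexsort((F[:, 1], F[:, 0]))
    F = F[order]
    hv = 0.0
    prev_f2 = ref[1]
    for f1, f2 in F:
        if f2 < prev_f2:
            hv += (ref[0] - f1) * (prev_f2 - f2)
            prev_f2 = f2
    return float(hv)
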