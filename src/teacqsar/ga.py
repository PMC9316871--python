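"""Genetic-algorithm descriptor-subset selection with QUIK filtering.

The K multivariate correlation index (eigenvalue-dispersion form) measures
how much total correlation a block of variables carries.  The QUIK rule
keeps a candidate subset only when adding the response raises that index
by at least a threshold (delta K = Kxy - Kxx), which discards both
redundant-descriptor models and models uncorrelated with the response.
On top of it sits a fixed-subset-size GA: tournament selection, uniform
crossover with repair, single-member swap mutation and elitism, with the
fitness of every evaluated subset cached so reappearing candidates cost
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import validation
from .mlr import MLRModel, fit_mlr, fit_statistics

__all__ = [
    "GAConfig",
    "KResult",
    "CandidateModel",
    "k_index",
    "quik_filter",
    "cross_correlation_screen",
    "ga_select",
    "build_model_ladder",
]


@dataclass
class GAConfig:
    """GA controls; the defaults match a 200-model population evolved for
    2000 generations with 20% mutation probability."""

    model_size: int
    population_size: int = 200
    generations: int = 2000
    mutation_probability: float = 0.20
    fitness_metric: str = "q2_loo"
    elitism: int = 2
    quik_delta: float = 0.05
    cross_r_limit: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_probability <= 1:
            raise ValueError("mutation_probability must lie in [0, 1]")
        if self.population_size < 2 or self.model_size < 1:
            raise ValueError("population_size >= 2 and model_size >= 1 required")
        if self.fitness_metric not in ("q2_loo", "r2"):
            raise ValueError("fitness_metric must be 'q2_loo' or 'r2'")


@dataclass
class KResult:
    """K of the descriptor block (Kxx), of block + response (Kxy), and
    their difference delta K."""

    kxx: float
    kxy: float

    @property
    def delta_k(self) -> float:
        return self.kxy - self.kxx


@dataclass
class CandidateModel:
    """A GA survivor: descriptor subset, fitness, fitted model, K result."""

    descriptor_names: tuple[str, ...]
    fitness: float
    fitted: MLRModel | None = None
    k: KResult | None = None
    stats: dict = field(default_factory=dict)


def k_index(block) -> float:
    """K multivariate correlation index of a column block.

    With eigenvalues l_j of the block's correlation matrix and
    l'_j = l_j / sum(l), K = sum|l'_j - 1/p| / (2(p-1)/p): 0 for mutually
    orthogonal columns, 1 for perfect collinearity.  A single column
    returns 0 by convention.
    """
    values = block.to_numpy(dtype=float) if isinstance(block, pd.DataFrame) \
        else np.asarray(block, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    p = values.shape[1]
    if p == 1:
        if values.std() == 0:
            raise ValueError("constant column: correlation undefined")
        return 0.0
    if np.any(values.std(axis=0) == 0):
        raise ValueError("constant column: correlation undefined")
    corr = np.corrcoef(values, rowvar=False)
    eigvals = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    frac = eigvals / eigvals.sum()
    return float(np.abs(frac - 1.0 / p).sum() / (2.0 * (p - 1) / p))


def quik_filter(X_subset, y, delta_threshold: float = 0.05) -> tuple[KResult, bool]:
    """QUIK rule: pass iff K(descriptors + response) - K(descriptors)
    reaches ``delta_threshold``."""
    values = X_subset.to_numpy(dtype=float) if isinstance(X_subset, pd.DataFrame) \
        else np.asarray(X_subset, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    y = np.asarray(y, dtype=float).ravel()
    kxx = k_index(values)
    kxy = k_index(np.column_stack([values, y]))
    result = KResult(kxx=kxx, kxy=kxy)
    return result, result.delta_k >= delta_threshold


def cross_correlation_screen(X_subset, r_limit: float = 0.7
                             ) -> tuple[bool, list[tuple[str, str, float]]]:
    """Flag descriptor pairs whose |Pearson r| exceeds ``r_limit``.

    Returns (flagged, offending pairs); a flagged model carries redundant
    descriptors and is rejected from the ladder.
    """
    if isinstance(X_subset, pd.DataFrame):
        names = list(X_subset.columns)
        values = X_subset.to_numpy(dtype=float)
    else:
        values = np.asarray(X_subset, dtype=float)
        names = [f"x{i + 1}" for i in range(values.shape[1])]
    if values.shape[1] < 2:
        return False, []
    corr = np.corrcoef(values, rowvar=False)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > r_limit:
                pairs.append((names[i], names[j], float(corr[i, j])))
    return bool(pairs), pairs


class _FitnessCache:
    """Evaluates and memoizes subset fitness; rejected subsets get -inf."""

    def __init__(self, X: pd.DataFrame, y, config: GAConfig):
        self.X = X
        self.values = X.to_numpy(dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.config = config
        self.names = list(X.columns)
        self.corr = np.corrcoef(self.values, rowvar=False) \
            if self.values.shape[1] > 1 else np.ones((1, 1))
        self.cache: dict[frozenset, float] = {}
        self.k_results: dict[frozenset, KResult] = {}

    def __call__(self, subset: frozenset) -> float:
        hit = self.cache.get(subset)
        if hit is not None:
            return hit
        fitness = self._evaluate(subset)
        self.cache[subset] = fitness
        return fitness

    def _evaluate(self, subset: frozenset) -> float:
        idx = sorted(subset)
        cols = self.values[:, idx]
        if len(idx) > 1:
            sub_corr = np.abs(self.corr[np.ix_(idx, idx)])
            np.fill_diagonal(sub_corr, 0.0)
            if sub_corr.max() > self.config.cross_r_limit:
                return -np.inf
        try:
            k, passed = quik_filter(cols, self.y, self.config.quik_delta)
        except ValueError:
            return -np.inf
        self.k_results[subset] = k
        if not passed:
            return -np.inf
        try:
            if self.config.fitness_metric == "q2_loo":
                return validation.loo_cv(cols, self.y).q2_loo
            model = fit_mlr(cols, self.y)
            return fit_statistics(model, cols, self.y).r2
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf


def _ranked_candidates(cache: _FitnessCache, top_k: int) -> list[CandidateModel]:
    def sort_key(item):
        subset, fitness = item
        return (-fitness, tuple(sorted(cache.names[i] for i in subset)))

    survivors = [(s, f) for s, f in cache.cache.items() if np.isfinite(f)]
    survivors.sort(key=sort_key)
    out = []
    for subset, fitness in survivors[:top_k]:
        idx = sorted(subset)
        names = [cache.names[i] for i in idx]
        fitted = fit_mlr(cache.X.iloc[:, idx], cache.y)
        out.append(CandidateModel(
            descriptor_names=tuple(names),
            fitness=fitness,
            fitted=fitted,
            k=cache.k_results.get(subset),
        ))
    return out


def ga_select(X: pd.DataFrame, y, config: GAConfig, top_k: int = 100
              ) -> list[CandidateModel]:
    """Evolve fixed-size descriptor subsets and return the best survivors.

    Selection is by tournament of two, crossover keeps members shared by
    both parents and fills the rest from their symmetric difference,
    mutation swaps one member for an outside descriptor with the configured
    probability, and the elite are copied through unchanged.  Candidates
    failing the QUIK rule or the cross-correlation screen are excluded
    (fitness -inf).  The returned list is deduplicated over every subset
    evaluated during the run and ranked by fitness; the run is fully
    deterministic under ``config.seed``.
    """
    m = X.shape[1]
    p = config.model_size
    if m < p:
        raise ValueError(f"only {m} descriptors for model size {p}")
    if p >= len(X) / 3:
        raise ValueError("model_size must stay below n/3")
    rng = np.random.default_rng(config.seed)
    cache = _FitnessCache(X, y, config)

    population = []
    seen = set()
    while len(population) < config.population_size:
        subset = frozenset(rng.choice(m, size=p, replace=False).tolist())
        if subset not in seen or len(seen) >= _n_subsets(m, p):
            seen.add(subset)
            population.append(subset)

    for _ in range(config.generations):
        fitness = np.array([cache(s) for s in population])
        order = np.argsort(-fitness, kind="stable")
        elite = [population[i] for i in order[:config.elitism]]
        children = list(elite)
        while len(children) < config.population_size:
            parents = [_tournament(population, fitness, rng) for _ in range(2)]
            child = _crossover(parents[0], parents[1], p, rng)
            if rng.random() < config.mutation_probability:
                child = _mutate(child, m, rng)
            children.append(child)
        population = children

    for s in population:  # make sure the final generation is evaluated
        cache(s)
    return _ranked_candidates(cache, top_k)


def _n_subsets(m: int, p: int) -> int:
    from math import comb
    return comb(m, p)


def _tournament(population, fitness, rng) -> frozenset:
    i, j = rng.integers(len(population)), rng.integers(len(population))
    return population[i] if fitness[i] >= fitness[j] else population[j]


def _crossover(a: frozenset, b: frozenset, p: int, rng) -> frozenset:
    shared = a & b
    pool = list(a ^ b)
    need = p - len(shared)
    if need > 0:
        rng.shuffle(pool)
        return frozenset(shared | set(pool[:need]))
    return frozenset(a)


def _mutate(subset: frozenset, m: int, rng) -> frozenset:
    members = list(subset)
    out = members[rng.integers(len(members))]
    candidates = np.setdiff1d(np.arange(m), members)
    new = candidates[rng.integers(len(candidates))]
    return frozenset((set(members) - {out}) | {int(new)})


def build_model_ladder(X: pd.DataFrame, y, sizes: Iterable[int],
                       config: GAConfig) -> tuple[dict[int, CandidateModel], pd.DataFrame]:
    """Best model per subset size plus a statistics table.

    Runs the GA once per size (seed offset by the size for independent
    streams), always also considering the greedy one-descriptor extension
    of the previous size's winner so the training fit never degrades as the
    ladder grows.  The statistics table has one column per size and the
    conventional row labels (R2, R2_adj, s, F, Kxx, DK, RMSE_tr, ...).
    """
    y_arr = np.asarray(y, dtype=float).ravel()
    ladder: dict[int, CandidateModel] = {}
    columns = {}
    prev: CandidateModel | None = None
    name_to_idx = {n: i for i, n in enumerate(X.columns)}
    cfg = config
    for size in sizes:
        run_cfg = GAConfig(**{**cfg.__dict__, "model_size": size,
                              "seed": cfg.seed + size})
        cache = _FitnessCache(X, y_arr, run_cfg)
        ranked = ga_select(X, y_arr, run_cfg, top_k=5)
        best = ranked[0] if ranked else None
        if prev is not None:
            grown = _greedy_extend(prev, X, y_arr, cache, name_to_idx)
            if grown is not None and (best is None or grown.fitness > best.fitness):
                best = grown
        if best is None:
            raise RuntimeError(f"no admissible model of size {size}")
        if prev is not None and best.fitted is not None:
            prev_r2 = fit_statistics(prev.fitted, X[list(prev.descriptor_names)], y_arr).r2
            best_r2 = fit_statistics(best.fitted, X[list(best.descriptor_names)], y_arr).r2
            if best_r2 < prev_r2 - 1e-9:
                grown = _greedy_extend(prev, X, y_arr, cache, name_to_idx)
                if grown is not None:
                    best = grown
        ladder[size] = best
        cols = X[list(best.descriptor_names)]
        fit = fit_statistics(best.fitted, cols, y_arr)
        internal = validation.loo_cv(cols, y_arr)
        columns[size] = validation.validation_report(
            fit, internal,
            kxx=best.k.kxx if best.k else None,
            delta_k=best.k.delta_k if best.k else None,
        )
        prev = best
    table = pd.DataFrame(columns)
    table.columns.name = "model_size"
    return ladder, table


def _greedy_extend(prev: CandidateModel, X, y, cache: _FitnessCache,
                   name_to_idx) -> CandidateModel | None:
    base = frozenset(name_to_idx[n] for n in prev.descriptor_names)
    best_subset, best_fit = None, -np.inf
    for j in range(X.shape[1]):
        if j in base:
            continue
        subset = base | {j}
        fitness = cache(subset)
        if fitness > best_fit:
            best_fit, best_subset = fitness, subset
    if best_subset is None or not np.isfinite(best_fit):
        return None
    names = tuple(sorted((cache.names[i] for i in best_subset),
                         key=lambda n: name_to_idx[n]))
    fitted = fit_mlr(X[list(names)], y)
    return CandidateModel(descriptor_names=names, fitness=best_fit,
                          fitted=fitted, k=cache.k_results.get(best_subset))
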