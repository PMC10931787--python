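"""Genetic-programming symbolic regression over descriptor tables.

A from-scratch tree-based GP engine used to search for closed-form
models that map conceptual-DFT descriptors to log relative rate
constants.  The function set is {add, sub, mul, div, sqrt, log, inv}
with the usual protected semantics (division and inversion return 1
near a zero denominator, log is log10 of the absolute value with
log(0) = 0, sqrt acts on the absolute value), so tree evaluation is
total on finite inputs.

Fitness is the squared Pearson correlation (coefficient of
determination of the best affine rescaling) between a tree's output and
the response, penalized by a parsimony term proportional to the node
count.  Selection is by tournament on the penalized fitness; offspring
are produced by subtree crossover (p = 0.7), subtree mutation
(p = 0.1) and reproduction (remaining mass).  Each generation fitness
is evaluated on a fresh subsample of ``max_samples`` of the rows, and
one elite (the best individual so far on the full data) survives
unconditionally, which makes the best-so-far fitness trace monotone.

Everything is driven by a single seeded ``numpy.random.Generator``, so
runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ExpressionTree",
    "GPConfig",
    "RegressionDataset",
    "EvolutionResult",
    "FUNCTIONS",
    "evaluate_tree",
    "fitness",
    "random_tree",
    "subtree_crossover",
    "subtree_mutation",
    "evolve",
]

#: Threshold under which a denominator counts as zero for protected ops.
PROTECTED_EPS = 1e-6


def _protected_div(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    small = np.abs(b) < PROTECTED_EPS
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.where(small, 1.0, a / np.where(small, 1.0, b))
    return out


def _protected_log(a: np.ndarray) -> np.ndarray:
    zero = a == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, 0.0, np.log10(np.abs(np.where(zero, 1.0, a))))
    return out


def _protected_sqrt(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.abs(a))


def _protected_inv(a: np.ndarray) -> np.ndarray:
    small = np.abs(a) < PROTECTED_EPS
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(small, 1.0, 1.0 / np.where(small, 1.0, a))
    return out


def _mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        return a * b


#: name -> (arity, vectorized implementation)
FUNCTIONS: dict[str, tuple[int, Callable[..., np.ndarray]]] = {
    "add": (2, np.add),
    "sub": (2, np.subtract),
    "mul": (2, _mul),
    "div": (2, _protected_div),
    "sqrt": (1, _protected_sqrt),
    "log": (1, _protected_log),
    "inv": (1, _protected_inv),
}

# Node encodings: ("x", feature_name) | ("c", value) | (fname, child, ...)


def _depth(node: tuple) -> int:
    if node[0] in ("x", "c"):
        return 1
    return 1 + max(_depth(child) for child in node[1:])


def _length(node: tuple) -> int:
    if node[0] in ("x", "c"):
        return 1
    return 1 + sum(_length(child) for child in node[1:])


def _to_infix(node: tuple) -> str:
    kind = node[0]
    if kind == "x":
        return str(node[1])
    if kind == "c":
        return f"{node[1]:.6g}"
    args = [_to_infix(c) for c in node[1:]]
    if kind == "add":
        return f"({args[0]} + {args[1]})"
    if kind == "sub":
        return f"({args[0]} - {args[1]})"
    if kind == "mul":
        return f"({args[0]} * {args[1]})"
    if kind == "div":
        return f"({args[0]} / {args[1]})"
    return f"{kind}({', '.join(args)})"


def _to_prefix(node: tuple) -> str:
    kind = node[0]
    if kind == "x":
        return str(node[1])
    if kind == "c":
        return f"{node[1]:.6g}"
    return f"{kind}({', '.join(_to_prefix(c) for c in node[1:])})"


@dataclass
class ExpressionTree:
    """A GP individual: an expression tree plus its last fitness values."""

    root: tuple
    fitness_raw: float | None = None
    fitness_penalized: float | None = None

    @property
    def depth(self) -> int:
        return _depth(self.root)

    @property
    def length(self) -> int:
        return _length(self.root)

    def to_infix(self) -> str:
        return _to_infix(self.root)

    def to_prefix(self) -> str:
        return _to_prefix(self.root)

    def copy(self) -> "ExpressionTree":
        # roots are immutable tuples, sharing is safe
        return ExpressionTree(self.root, self.fitness_raw, self.fitness_penalized)


@dataclass(frozen=True)
class GPConfig:
    """Hyperparameters of one evolutionary run.

    Defaults follow the production-scale configuration (population 5000,
    10000 generations); desk-scale experiments should pass much smaller
    values.  ``seed`` is mandatory: there is no unseeded mode.
    """

    seed: int
    population_size: int = 5000
    generations: int = 10000
    p_crossover: float = 0.7
    p_subtree_mutation: float = 0.1
    max_samples: float = 0.9
    parsimony_coefficient: float = 0.01
    tournament_size: int = 20
    max_depth: int = 10
    init_depth: tuple[int, int] = (2, 4)
    mutation_depth: int = 3
    const_range: tuple[float, float] = (-1.0, 1.0)
    p_feature_terminal: float = 0.8
    elitism: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.p_crossover <= 1 or not 0 <= self.p_subtree_mutation <= 1:
            raise ValidationError("operator probabilities must lie in [0, 1]")
        if self.p_crossover + self.p_subtree_mutation > 1:
            raise ValidationError("p_crossover + p_subtree_mutation must be <= 1")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if not 0 < self.max_samples <= 1:
            raise ValidationError("max_samples must lie in (0, 1]")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if self.tournament_size < 1:
            raise ValidationError("tournament_size must be >= 1")
        if self.max_depth < 2:
            raise ValidationError("max_depth must be >= 2")


@dataclass(frozen=True)
class RegressionDataset:
    """A descriptor table (rows = species) and its response vector."""

    features: pd.DataFrame
    response: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", y)
        X = self.features
        if len(X) != len(y):
            raise ValidationError("feature and response row counts differ")
        if len(y) < 2:
            raise ValidationError("need at least 2 rows")
        if not np.all(np.isfinite(X.to_numpy(dtype=float))) or not np.all(
            np.isfinite(y)
        ):
            raise ValidationError("dataset contains missing/non-finite values")
        if np.ptp(y) == 0:
            raise ValidationError("response is constant; nothing to regress")

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.features.columns]

    @property
    def n_rows(self) -> int:
        return len(self.response)


@dataclass
class EvolutionResult:
    """Outcome of :func:`evolve`."""

    best: ExpressionTree
    history: list[float] = field(default_factory=list)  # best-so-far raw R^2


# ---------------------------------------------------------------------------
# Evaluation and fitness
# ---------------------------------------------------------------------------


def _eval_node(node: tuple, columns: dict[str, np.ndarray], n: int) -> np.ndarray:
    kind = node[0]
    if kind == "x":
        try:
            return columns[node[1]]
        except KeyError:
            raise ValidationError(f"unknown feature name {node[1]!r}") from None
    if kind == "c":
        return np.full(n, float(node[1]))
    arity, fn = FUNCTIONS[kind]
    args = [_eval_node(child, columns, n) for child in node[1:]]
    return fn(*args)


def evaluate_tree(
    tree: ExpressionTree | tuple,
    dataset: RegressionDataset,
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized evaluation of a tree on (a row subset of) a dataset.

    Protected operators make this total on finite inputs; overflow may
    still produce infinities, which the fitness function treats as a
    zero-fitness individual.
    """
    root = tree.root if isinstance(tree, ExpressionTree) else tree
    X = dataset.features
    if rows is not None:
        X = X.iloc[rows]
    columns = {str(c): X[c].to_numpy(dtype=float) for c in X.columns}
    return _eval_node(root, columns, len(X))


def _raw_r2(pred: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 for constant or non-finite output."""
    if not np.all(np.isfinite(pred)):
        return 0.0
    pc = pred - pred.mean()
    yc = y - y.mean()
    spp = float(pc @ pc)
    syy = float(yc @ yc)
    if spp <= 0.0 or syy <= 0.0:
        return 0.0
    r = float(pc @ yc) / math.sqrt(spp * syy)
    if not math.isfinite(r):
        return 0.0
    return min(r * r, 1.0)


def fitness(
    tree: ExpressionTree,
    dataset: RegressionDataset,
    config: GPConfig,
    rows: np.ndarray | None = None,
) -> tuple[float, float]:
    """(raw R^2, parsimony-penalized fitness) on the given row subset.

    Raw fitness is the squared Pearson correlation between the tree's
    output and the response (0 for a constant or non-finite output);
    penalized = raw - parsimony_coefficient * node_count, to be
    maximized.
    """
    pred = evaluate_tree(tree, dataset, rows)
    y = dataset.response if rows is None else dataset.response[rows]
    raw = _raw_r2(pred, y)
    penalized = raw - config.parsimony_coefficient * tree.length
    tree.fitness_raw = raw
    tree.fitness_penalized = penalized
    return raw, penalized


# ---------------------------------------------------------------------------
# Random trees and variation operators
# ---------------------------------------------------------------------------

_FUNC_NAMES = tuple(FUNCTIONS)


def _random_terminal(
    rng: np.random.Generator, feature_names: Sequence[str], config: GPConfig
) -> tuple:
    if rng.random() < config.p_feature_terminal:
        return ("x", feature_names[int(rng.integers(len(feature_names)))])
    lo, hi = config.const_range
    return ("c", float(rng.uniform(lo, hi)))


def _grow(
    rng: np.random.Generator,
    feature_names: Sequence[str],
    config: GPConfig,
    depth: int,
    full: bool,
) -> tuple:
    if depth <= 1 or (not full and rng.random() < 0.3):
        return _random_terminal(rng, feature_names, config)
    name = _FUNC_NAMES[int(rng.integers(len(_FUNC_NAMES)))]
    arity = FUNCTIONS[name][0]
    return (name,) + tuple(
        _grow(rng, feature_names, config, depth - 1, full) for _ in range(arity)
    )


def random_tree(
    rng: np.random.Generator,
    feature_names: Sequence[str],
    config: GPConfig,
    depth: int | None = None,
    full: bool | None = None,
) -> ExpressionTree:
    """Grow a random tree (ramped half-and-half when depth/full unset)."""
    if depth is None:
        lo, hi = config.init_depth
        depth = int(rng.integers(lo, hi + 1))
    if full is None:
        full = bool(rng.random() < 0.5)
    return ExpressionTree(_grow(rng, feature_names, config, depth, full))


def _all_paths(node: tuple, prefix: tuple = ()) -> list[tuple]:
    paths = [prefix]
    if node[0] not in ("x", "c"):
        for i, child in enumerate(node[1:]):
            paths.extend(_all_paths(child, prefix + (i,)))
    return paths


def _get_subtree(node: tuple, path: tuple) -> tuple:
    for i in path:
        node = node[i + 1]
    return node


def _replace_subtree(node: tuple, path: tuple, new: tuple) -> tuple:
    if not path:
        return new
    i = path[0]
    children = list(node[1:])
    children[i] = _replace_subtree(children[i], path[1:], new)
    return (node[0],) + tuple(children)


_MAX_RETRIES = 10


def subtree_crossover(
    parent_a: ExpressionTree,
    parent_b: ExpressionTree,
    rng: np.random.Generator,
    config: GPConfig,
) -> ExpressionTree:
    """Replace a uniformly chosen subtree of ``parent_a`` with a
    uniformly chosen subtree of ``parent_b``.

    The depth cap is enforced by rejection; after bounded retries the
    child falls back to a copy of ``parent_a``.
    """
    paths_a = _all_paths(parent_a.root)
    paths_b = _all_paths(parent_b.root)
    for _ in range(_MAX_RETRIES):
        pa = paths_a[int(rng.integers(len(paths_a)))]
        pb = paths_b[int(rng.integers(len(paths_b)))]
        child = _replace_subtree(parent_a.root, pa, _get_subtree(parent_b.root, pb))
        if _depth(child) <= config.max_depth:
            return ExpressionTree(child)
    return ExpressionTree(parent_a.root)


def subtree_mutation(
    parent: ExpressionTree,
    rng: np.random.Generator,
    config: GPConfig,
    feature_names: Sequence[str],
) -> ExpressionTree:
    """Replace a uniformly chosen subtree with a freshly grown one."""
    paths = _all_paths(parent.root)
    for _ in range(_MAX_RETRIES):
        p = paths[int(rng.integers(len(paths)))]
        new = _grow(
            rng, feature_names, config, int(rng.integers(1, config.mutation_depth + 1)),
            full=False,
        )
        child = _replace_subtree(parent.root, p, new)
        if _depth(child) <= config.max_depth:
            return ExpressionTree(child)
    return ExpressionTree(parent.root)


# ---------------------------------------------------------------------------
# The evolutionary loop
# ---------------------------------------------------------------------------


def _tournament(
    population: list[ExpressionTree],
    penalized: np.ndarray,
    rng: np.random.Generator,
    k: int,
) -> ExpressionTree:
    idx = rng.integers(len(population), size=min(k, len(population)))
    best = idx[int(np.argmax(penalized[idx]))]
    return population[int(best)]


def evolve(dataset: RegressionDataset, config: GPConfig) -> EvolutionResult:
    """Run the generational GP loop.

    Per generation: fitness of every individual is computed on a fresh
    subsample of ``ceil(max_samples * n)`` rows drawn without
    replacement; parents are chosen by tournament on the penalized
    fitness; offspring are produced by crossover / subtree mutation /
    reproduction with the configured probabilities.  The generation
    champion (by penalized fitness) is re-scored on the full dataset,
    and the best full-data individual seen so far is recorded in the
    history and, with ``elitism``, copied unchanged into the next
    generation — hence the history is non-decreasing.

    Returns the best individual (full-data raw R^2) and the history of
    best-so-far raw R^2 per generation.
    """
    rng = np.random.default_rng(config.seed)
    names = dataset.feature_names
    n = dataset.n_rows
    n_sample = max(2, math.ceil(config.max_samples * n))

    population = [random_tree(rng, names, config) for _ in range(config.population_size)]

    best_tree: ExpressionTree | None = None
    best_raw = -math.inf
    history: list[float] = []

    for _gen in range(config.generations):
        if n_sample < n:
            rows = rng.choice(n, size=n_sample, replace=False)
        else:
            rows = None
        penalized = np.empty(len(population))
        for i, tree in enumerate(population):
            _, penalized[i] = fitness(tree, dataset, config, rows)

        champ = population[int(np.argmax(penalized))]
        champ_raw, _ = fitness(champ.copy(), dataset, config, rows=None)
        if champ_raw > best_raw:
            best_raw = champ_raw
            best_tree = champ.copy()
            best_tree.fitness_raw = champ_raw
        history.append(best_raw)

        if _gen == config.generations - 1:
            break

        next_pop: list[ExpressionTree] = []
        if config.elitism and best_tree is not None:
            next_pop.append(best_tree.copy())
        while len(next_pop) < config.population_size:
            u = rng.random()
            if u < config.p_crossover:
                pa = _tournament(population, penalized, rng, config.tournament_size)
                pb = _tournament(population, penalized, rng, config.tournament_size)
                child = subtree_crossover(pa, pb, rng, config)
            elif u < config.p_crossover + config.p_subtree_mutation:
                pa = _tournament(population, penalized, rng, config.tournament_size)
                child = subtree_mutation(pa, rng, config, names)
            else:
                pa = _tournament(population, penalized, rng, config.tournament_size)
                child = pa.copy()
            next_pop.append(child)
        population = next_pop

    assert best_tree is not None
    return EvolutionResult(best=best_tree, history=history)
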