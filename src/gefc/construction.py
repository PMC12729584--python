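"""Genetic construction of artificial features guided by an RBF network.

A population of integer chromosomes is evolved; each chromosome maps (via the
grammatical-evolution machinery in :mod:`gefc.grammar`) to ``Nf`` symbolic
expressions over the original feature vector.  A chromosome's fitness is the
training sum of squared errors of a radial-basis-function network fitted on
the transformed patterns:

    f_i = sum_j ( C(x_hat_j) - t_j )^2

where ``x_hat_j`` is pattern ``j`` pushed through the candidate expressions
and ``C`` the RBF network.  The RBF model is used because its training —
k-means centers plus a linear least-squares output layer — is orders of
magnitude cheaper than backprop, which matters inside a fitness loop.

The GA is elitist: per generation the best (1 - ps) * Nc chromosomes survive
intact and ps * Nc offspring are bred by tournament selection, one-point
crossover and per-codon uniform mutation, replacing the worst individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .grammar import (
    BNFGrammar,
    Chromosome,
    ExpressionTree,
    default_feature_grammar,
    evaluate_expression_batch,
    map_expressions,
    serialize_expression,
)
from .signal_features import FeatureMatrix

__all__ = [
    "FCConfig",
    "TrainingSet",
    "FitnessRecord",
    "ConstructedFeatureSet",
    "RBFModel",
    "initialize_population",
    "build_feature_set",
    "train_rbf",
    "rbf_predict",
    "fitness",
    "evolve",
    "transform_dataset",
    "transform_patterns",
]

log = logging.getLogger(__name__)

_CLIP = 1e100


@dataclass(frozen=True)
class FCConfig:
    """Feature-construction GA parameters (defaults mirror the method's
    published configuration: 500 generations, 500 chromosomes, selection rate
    0.10, mutation rate 0.05)."""

    generations: int = 500
    population: int = 500
    selection_rate: float = 0.10
    mutation_rate: float = 0.05
    n_features: int = 2
    chromosome_length: int = 100
    codon_bound: int = 255
    tournament_size: int = 4
    max_wraps: int = 2
    rbf_nodes: int = 10
    penalty_fitness: float = 1e100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.selection_rate < 1):
            raise ValueError("selection_rate must be in (0,1)")
        if not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must be in [0,1]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.generations < 1 or self.population < 1:
            raise ValueError("generations and population must be >= 1")
        if self.chromosome_length < 2:
            raise ValueError("chromosome_length must allow a crossover cut")


@dataclass(frozen=True)
class TrainingSet:
    """M (pattern, target) pairs of uniform dimension d."""

    patterns: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "patterns", np.asarray(self.patterns, dtype=float))
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=float))
        if self.patterns.ndim != 2 or len(self.patterns) == 0:
            raise ValueError("patterns must be a non-empty 2-D array")
        if len(self.patterns) != len(self.targets):
            raise ValueError("patterns and targets must align")

    @property
    def M(self) -> int:
        return len(self.patterns)

    @property
    def d(self) -> int:
        return self.patterns.shape[1]


@dataclass(frozen=True)
class FitnessRecord:
    chromosome: Chromosome
    fitness: float
    valid: bool


@dataclass(frozen=True)
class ConstructedFeatureSet:
    """The winning chromosome's Nf expressions plus the run's fitness trace."""

    expressions: tuple[ExpressionTree, ...]
    best_fitness: float
    fitness_trace: tuple[float, ...]
    config: FCConfig
    chromosome: Chromosome | None = None

    @property
    def expression_strings(self) -> list[str]:
        return [serialize_expression(e) for e in self.expressions]


@dataclass(frozen=True)
class RBFModel:
    """Gaussian RBF network: k centers/widths plus a linear output layer."""

    centers: np.ndarray
    widths: np.ndarray
    output_weights: np.ndarray  # k basis weights followed by the bias

    def __post_init__(self) -> None:
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")


# ---------------------------------------------------------------------------
# Population and mapping


def initialize_population(cfg: FCConfig, rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Nc uniform random chromosomes, reproducible from the config seed."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    codons = rng.integers(0, cfg.codon_bound + 1, size=(cfg.population, cfg.chromosome_length))
    return [Chromosome(tuple(int(v) for v in row), cfg.codon_bound) for row in codons]


def build_feature_set(
    chrom: Chromosome | Sequence[int],
    cfg: FCConfig,
    grammar: BNFGrammar,
) -> tuple[ExpressionTree, ...] | None:
    """Map Nf expressions from one chromosome, or None if any mapping fails.

    Expressions are consumed sequentially from a single codon stream:
    expression i+1 starts at the codon after the one expression i finished
    on, so early expressions do not cap the complexity available to later
    ones.
    """
    results = map_expressions(chrom, grammar, cfg.n_features, cfg.max_wraps)
    if len(results) < cfg.n_features or not all(r.valid for r in results):
        return None
    return tuple(r.expression for r in results)  # type: ignore[misc]


# ---------------------------------------------------------------------------
# RBF network


def train_rbf(
    X: np.ndarray,
    t: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> RBFModel:
    """Fit a Gaussian RBF network: k-means centers, data-driven widths,
    ridge-stabilised least-squares output weights.

    ``width_j`` is the mean distance of cluster j's members to its center,
    floored at 1e-6 (singleton clusters would otherwise produce a
    zero-width, hence singular, basis).  If fewer patterns than nodes are
    given, k is reduced to the pattern count (logged).
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    M = len(X)
    if k > M:
        log.debug("reducing RBF nodes from %d to %d (only %d patterns)", k, M, M)
        k = M
    if k == M:
        centers = X.copy()
        assignment = np.arange(M)
    else:
        km = KMeans(n_clusters=k, n_init=1, random_state=seed)
        with warnings.catch_warnings():
            # candidate expressions routinely produce constant columns, so
            # fewer distinct points than clusters is business as usual here
            warnings.simplefilter("ignore")
            assignment = km.fit_predict(X)
        centers = km.cluster_centers_
    widths = np.empty(k)
    for j in range(k):
        members = X[assignment == j]
        if len(members) == 0:
            widths[j] = 1e-6
        else:
            widths[j] = max(float(np.mean(np.linalg.norm(members - centers[j], axis=1))), 1e-6)
    Phi = _design_matrix(X, centers, widths)
    # ridge-stabilised normal equations; tiny ridge keeps collinear bases solvable
    A = Phi.T @ Phi + 1e-8 * np.eye(Phi.shape[1])
    b = Phi.T @ t
    weights = np.linalg.solve(A, b)
    return RBFModel(centers, widths, weights)


def _design_matrix(X: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    Phi = np.exp(-d2 / (2.0 * widths[None, :] ** 2))
    return np.hstack([Phi, np.ones((len(X), 1))])


def rbf_predict(model: RBFModel, X: np.ndarray) -> np.ndarray:
    """Network output C(x) for each pattern."""
    Phi = _design_matrix(np.asarray(X, dtype=float), model.centers, model.widths)
    return Phi @ model.output_weights


# ---------------------------------------------------------------------------
# Fitness and evolution


def transform_patterns(
    X: np.ndarray, expressions: Sequence[ExpressionTree]
) -> tuple[np.ndarray, np.ndarray]:
    """Push an (M, d) pattern matrix through the expressions.

    Returns ``(transformed, all_finite_mask)`` where ``transformed`` is
    (M, Nf); guard-failing cells hold 0 and clear the row's finite flag.
    """
    cols = []
    finite = np.ones(len(X), dtype=bool)
    for expr in expressions:
        vals, ok = evaluate_expression_batch(expr, X)
        cols.append(vals)
        finite &= ok
    return np.stack(cols, axis=1), finite


def fitness(
    chrom: Chromosome | Sequence[int],
    train: TrainingSet,
    cfg: FCConfig,
    grammar: BNFGrammar,
) -> float:
    """Eq.-style training SSE of an RBF net on the transformed patterns.

    An unmappable chromosome, or one whose expressions produce any
    non-finite transformed value, earns the (finite) penalty fitness so the
    population ordering stays total.
    """
    expressions = build_feature_set(chrom, cfg, grammar)
    if expressions is None:
        return cfg.penalty_fitness
    Z, ok = transform_patterns(train.patterns, expressions)
    if not ok.all():
        return cfg.penalty_fitness
    model = train_rbf(Z, train.targets, cfg.rbf_nodes, cfg.seed)
    residuals = rbf_predict(model, Z) - train.targets
    return float(np.sum(residuals**2))


def evolve(
    train: TrainingSet,
    cfg: FCConfig,
    grammar: BNFGrammar | None = None,
) -> ConstructedFeatureSet:
    """Run the elitist GA and return the best chromosome's feature set.

    Per generation: sort by fitness; keep the best (1 - ps) * Nc intact;
    breed ps * Nc offspring (tournament selection of parents from the whole
    population, one-point crossover with a uniform cut in [1, L-1], then
    per-codon mutation to a fresh uniform codon with probability pm) and let
    them replace the worst individuals.  Elitism makes the best-fitness
    trace monotone non-increasing.
    """
    if grammar is None:
        grammar = default_feature_grammar(train.d)
    rng = np.random.default_rng(cfg.seed)
    pop = np.array(
        rng.integers(0, cfg.codon_bound + 1, size=(cfg.population, cfg.chromosome_length)),
        dtype=np.int64,
    )
    fits = np.array([fitness(pop[i], train, cfg, grammar) for i in range(cfg.population)])

    n_off = max(2, int(round(cfg.selection_rate * cfg.population)))
    n_off = min(n_off + (n_off % 2), cfg.population)  # even, for pairing

    trace: list[float] = []
    for _gen in range(cfg.generations):
        order = np.argsort(fits, kind="stable")
        pop, fits = pop[order], fits[order]
        trace.append(float(fits[0]))
        if _gen == cfg.generations - 1:
            break
        children = np.empty((n_off, cfg.chromosome_length), dtype=np.int64)
        for pair in range(n_off // 2):
            i = _tournament(fits, cfg.tournament_size, rng)
            j = _tournament(fits, cfg.tournament_size, rng)
            while j == i:
                j = _tournament(fits, cfg.tournament_size, rng)
            cut = int(rng.integers(1, cfg.chromosome_length))
            children[2 * pair, :cut] = pop[i, :cut]
            children[2 * pair, cut:] = pop[j, cut:]
            children[2 * pair + 1, :cut] = pop[j, :cut]
            children[2 * pair + 1, cut:] = pop[i, cut:]
        mutate = rng.random(children.shape) <= cfg.mutation_rate
        fresh = rng.integers(0, cfg.codon_bound + 1, size=children.shape)
        children[mutate] = fresh[mutate]
        child_fits = np.array([fitness(c, train, cfg, grammar) for c in children])
        pop[-n_off:] = children
        fits[-n_off:] = child_fits

    best_idx = int(np.argmin(fits))
    best = Chromosome(tuple(int(v) for v in pop[best_idx]), cfg.codon_bound)
    expressions = build_feature_set(best, cfg, grammar)
    if expressions is None:
        # Every individual unmappable; extraordinarily unlikely at sane
        # settings but the contract requires a total function.
        raise RuntimeError("evolution terminated without a mappable chromosome")
    # best-ever trace: elitism guarantees per-generation bests never worsen
    running = np.minimum.accumulate(trace)
    return ConstructedFeatureSet(
        expressions=expressions,
        best_fitness=float(fits[best_idx]),
        fitness_trace=tuple(float(v) for v in running),
        config=cfg,
        chromosome=best,
    )


def _tournament(fits: np.ndarray, size: int, rng: np.random.Generator) -> int:
    contenders = rng.integers(0, len(fits), size=size)
    return int(contenders[np.argmin(fits[contenders])])


def transform_dataset(data: FeatureMatrix, fs: ConstructedFeatureSet) -> FeatureMatrix:
    """Replace the original columns with the Nf constructed features.

    Columns are named ``gf_1 .. gf_Nf``; labels and row metadata carry over.
    Guard-failing cells are clipped to +/-1e100 (count logged) rather than
    invalidating rows, since at transform time every row must survive.
    """
    import pandas as pd

    d_needed = max(e.max_variable_index() for e in fs.expressions)
    if d_needed > data.X.shape[1]:
        raise ValueError(
            f"expressions reference x{d_needed} but data has {data.X.shape[1]} columns"
        )
    Z, ok = transform_patterns(data.X, fs.expressions)
    n_bad = int(np.sum(~ok))
    if n_bad:
        log.warning("%d rows had guarded non-finite values; clipped to +/-1e100", n_bad)
    Z = np.clip(Z, -_CLIP, _CLIP)
    cols = {f"gf_{i + 1}": Z[:, i] for i in range(Z.shape[1])}
    return FeatureMatrix(
        pd.DataFrame(cols),
        data.labels.copy(),
        data.patient_ids.copy(),
        data.window_index.copy(),
    )
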