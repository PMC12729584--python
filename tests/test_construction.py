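"""Feature-construction GA and RBF-network tests."""

import numpy as np
import pandas as pd
import pytest

from gefc.construction import (
    FCConfig,
    TrainingSet,
    build_feature_set,
    evolve,
    fitness,
    initialize_population,
    rbf_predict,
    train_rbf,
    transform_dataset,
)
from gefc.grammar import (
    default_feature_grammar,
    evaluate_expression,
    serialize_expression,
)
from gefc.signal_features import FeatureMatrix

WORKED_CODONS = (9, 8, 6, 4, 16, 10, 17, 23, 8, 14)


def _small_cfg(**kw):
    base = dict(generations=10, population=30, n_features=2, seed=0)
    base.update(kw)
    return FCConfig(**base)


# ---------------------------------------------------------------------------
# population


def test_population_size_and_bounds():
    cfg = _small_cfg(population=500)
    pop = initialize_population(cfg)
    assert len(pop) == 500
    assert all(len(c) == cfg.chromosome_length for c in pop)
    assert all(0 <= v <= 255 for c in pop for v in c.codons)


def test_population_reproducible_from_seed():
    cfg = _small_cfg(seed=42)
    assert initialize_population(cfg) == initialize_population(cfg)


# ---------------------------------------------------------------------------
# feature sets


def test_feature_set_has_nf_expressions(rng):
    g = default_feature_grammar(3)
    cfg = _small_cfg(n_features=2)
    while True:
        chrom = tuple(int(v) for v in rng.integers(0, 256, size=100))
        exprs = build_feature_set(chrom, cfg, g)
        if exprs is not None:
            break
    assert len(exprs) == 2


def test_first_expression_from_worked_prefix():
    g = default_feature_grammar(3)
    cfg = _small_cfg(n_features=2)
    chrom = WORKED_CODONS + (2, 0, 1) + (0,) * 87
    exprs = build_feature_set(chrom, cfg, g)
    assert exprs is not None
    assert serialize_expression(exprs[0]) == "(x2+cos(x3))"


def test_unmappable_chromosome_invalidates_set():
    g = default_feature_grammar(3)
    # all-zero codons always pick the expansive rule -> wrap budget exceeded
    assert build_feature_set((0,) * 100, _small_cfg(), g) is None


# ---------------------------------------------------------------------------
# RBF network


def test_rbf_single_node_constant_target(rng):
    X = rng.normal(size=(20, 2))
    model = train_rbf(X, np.full(20, 4.2), k=1)
    assert np.allclose(rbf_predict(model, X), 4.2, atol=1e-6)


def test_rbf_interpolates_xor_layout():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    t = np.array([0.0, 1.0, 1.0, 0.0])
    model = train_rbf(X, t, k=4)
    assert np.sum((rbf_predict(model, X) - t) ** 2) < 1e-6


def test_rbf_weights_match_normal_equations_oracle():
    """Output layer solves the (ridge) normal equations for the fitted basis."""
    X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
    t = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    model = train_rbf(X, t, k=2, seed=0)
    # oracle: rebuild the design matrix from the model's own centers/widths
    d2 = np.sum((X[:, None, :] - model.centers[None, :, :]) ** 2, axis=2)
    Phi = np.hstack([np.exp(-d2 / (2 * model.widths**2)), np.ones((5, 1))])
    oracle = np.linalg.solve(Phi.T @ Phi + 1e-8 * np.eye(3), Phi.T @ t)
    assert np.allclose(model.output_weights, oracle, atol=1e-6)


def test_rbf_reduces_nodes_when_few_patterns():
    X = np.array([[0.0], [1.0]])
    model = train_rbf(X, np.array([0.0, 1.0]), k=10)
    assert len(model.centers) == 2


# ---------------------------------------------------------------------------
# fitness


def test_invalid_chromosome_gets_penalty():
    train = TrainingSet(np.zeros((5, 3)), np.zeros(5))
    cfg = _small_cfg(n_features=2)
    g = default_feature_grammar(3)
    assert fitness((0,) * 100, train, cfg, g) == cfg.penalty_fitness


def test_fitness_nonnegative(rng):
    train = TrainingSet(rng.normal(size=(15, 3)), rng.integers(0, 2, 15).astype(float))
    cfg = _small_cfg(n_features=2)
    g = default_feature_grammar(3)
    for _ in range(10):
        chrom = tuple(int(v) for v in rng.integers(0, 256, size=100))
        assert fitness(chrom, train, cfg, g) >= 0.0


def test_fitness_matches_external_sse_oracle(rng):
    """Recompute the SSE with per-pattern evaluation and an external RBF fit."""
    train = TrainingSet(rng.normal(size=(5, 3)), np.array([0, 1, 0, 1, 1.0]))
    cfg = _small_cfg(n_features=2, rbf_nodes=3)
    g = default_feature_grammar(3)
    while True:
        chrom = tuple(int(v) for v in rng.integers(0, 256, size=100))
        exprs = build_feature_set(chrom, cfg, g)
        if exprs is None:
            continue
        Z = np.array(
            [[evaluate_expression(e, x)[0] for e in exprs] for x in train.patterns]
        )
        finite = all(
            evaluate_expression(e, x)[1] for e in exprs for x in train.patterns
        )
        if not finite:
            continue
        model = train_rbf(Z, train.targets, cfg.rbf_nodes, cfg.seed)
        oracle = float(np.sum((rbf_predict(model, Z) - train.targets) ** 2))
        assert fitness(chrom, train, cfg, g) == pytest.approx(oracle, rel=1e-9)
        break


# ---------------------------------------------------------------------------
# evolution


def _toy_train(rng, n=30):
    X = rng.normal(size=(n, 2))
    y = (np.sign(X[:, 0] * X[:, 1]) > 0).astype(float)
    return TrainingSet(X, y)


def test_evolution_trace_monotone_and_deterministic(rng):
    train = _toy_train(rng)
    cfg = _small_cfg(generations=8, population=20, seed=3)
    a = evolve(train, cfg)
    b = evolve(train, cfg)
    assert a.expression_strings == b.expression_strings
    assert a.fitness_trace == b.fitness_trace
    assert all(x >= y for x, y in zip(a.fitness_trace, a.fitness_trace[1:]))
    assert len(a.fitness_trace) == cfg.generations
    assert len(a.expressions) == cfg.n_features


def test_single_generation_returns_best_of_initial_population(rng):
    train = _toy_train(rng)
    cfg = _small_cfg(generations=1, population=25, seed=9)
    result = evolve(train, cfg)
    g = default_feature_grammar(train.d)
    init_best = min(
        fitness(c, train, cfg, g) for c in initialize_population(cfg)
    )
    assert result.best_fitness == pytest.approx(init_best)


def test_best_chromosome_respects_codon_bounds(rng):
    train = _toy_train(rng, 20)
    result = evolve(train, _small_cfg(generations=6, population=16, seed=1))
    assert all(0 <= v <= 255 for v in result.chromosome.codons)


def test_planted_interaction_beats_identity_features(rng):
    """On labels = sign(x1*x2) the evolved features cut RBF training SSE
    versus feeding the raw coordinates straight to the same network."""
    train = _toy_train(rng, 60)
    cfg = _small_cfg(generations=20, population=40, n_features=2, seed=2)
    result = evolve(train, cfg)
    identity = train_rbf(train.patterns, train.targets, cfg.rbf_nodes, cfg.seed)
    sse_identity = float(np.sum((rbf_predict(identity, train.patterns) - train.targets) ** 2))
    assert result.best_fitness < sse_identity


# ---------------------------------------------------------------------------
# transform


def test_transform_shapes_and_cells(rng):
    train = _toy_train(rng, 20)
    cfg = _small_cfg(generations=4, population=15, n_features=3, seed=5)
    result = evolve(train, cfg)
    data = FeatureMatrix(
        pd.DataFrame(train.patterns, columns=["f0", "f1"]),
        train.targets.astype(int),
    )
    out = transform_dataset(data, result)
    assert out.column_names == ["gf_1", "gf_2", "gf_3"]
    assert len(out) == len(data)
    assert np.array_equal(out.labels, data.labels)
    for i in range(5):
        for j, expr in enumerate(result.expressions):
            v, ok = evaluate_expression(expr, train.patterns[i])
            if ok:
                assert out.X[i, j] == pytest.approx(v, rel=1e-12, abs=1e-12)


def test_transform_rejects_dimension_mismatch():
    from gefc.construction import ConstructedFeatureSet
    from gefc.grammar import parse_expression

    fs = ConstructedFeatureSet(
        expressions=(parse_expression("(x1+x2)"),),
        best_fitness=0.0,
        fitness_trace=(0.0,),
        config=_small_cfg(n_features=1),
    )
    data = FeatureMatrix(pd.DataFrame({"f0": [1.0, 2.0]}), np.array([0, 1]))
    with pytest.raises(ValueError):
        transform_dataset(data, fs)
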