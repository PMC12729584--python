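"""Classifier evaluation: stratified repeated k-fold CV, metrics, baselines.

The experimental protocol is binary OFF/ON motor-state classification with
stratified 10-fold cross-validation repeated several times under different
shuffles; the headline metric is the mean classification error (percent),
accompanied by macro-averaged precision and recall and ROC / PR curves.

Baselines:

* ``rbf``     — RBF network on the raw features (k-means centers + linear
                output layer), thresholded at 0.5;
* ``gen_mlp`` — one-hidden-layer sigmoid MLP whose weights are evolved by a
                real-coded genetic algorithm minimising training SSE;
* ``pca_mlp`` — project to 2 principal components, then train the same MLP by
                BFGS from a seeded random initialisation;
* ``fc``      — the feature-construction pipeline: composite scoring + top-80%
                retention + GE feature construction on the training fold only,
                then an RBF classifier on the constructed features.  Test
                folds are transformed with the evolved expressions, so no
                information leaks from test to train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.decomposition import PCA
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .construction import (
    ConstructedFeatureSet,
    FCConfig,
    TrainingSet,
    evolve,
    rbf_predict,
    train_rbf,
    transform_dataset,
)
from .grammar import default_feature_grammar
from .scoring import ScoringConfig, score_features, select_top_features
from .signal_features import FeatureMatrix

__all__ = [
    "EvalConfig",
    "ConfusionMatrix",
    "EvaluationReport",
    "compute_metrics",
    "confusion_from_predictions",
    "crossval_evaluate",
    "train_baseline",
    "roc_pr_points",
    "RBFClassifier",
    "GenMLPClassifier",
    "PCAMLPClassifier",
    "FCClassifier",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    folds: int = 10
    repeats: int = 30
    hidden_nodes: int = 10
    pca_components: int = 2
    seed: int = 0
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with class 1 (ON) as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationReport:
    method: str
    fold_errors: list[float] = field(default_factory=list)
    fold_precisions: list[float] = field(default_factory=list)
    fold_recalls: list[float] = field(default_factory=list)
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    auroc: float = float("nan")
    config: EvalConfig | None = None

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.fold_errors))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.fold_precisions))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.fold_recalls))


# ---------------------------------------------------------------------------
# Metrics


def compute_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(error %, macro precision, macro recall) from a confusion matrix.

    Precision and recall are averaged over both classes; a class with a zero
    denominator contributes 0 (logged), which penalises degenerate
    one-class predictors instead of silently dropping the class.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    error = 100.0 * (cm.fp + cm.fn) / cm.total

    def _safe(num: int, den: int, what: str) -> float:
        if den == 0:
            log.debug("zero denominator for %s; contributing 0", what)
            return 0.0
        return num / den

    prec_on = _safe(cm.tp, cm.tp + cm.fp, "precision(ON)")
    prec_off = _safe(cm.tn, cm.tn + cm.fn, "precision(OFF)")
    rec_on = _safe(cm.tp, cm.tp + cm.fn, "recall(ON)")
    rec_off = _safe(cm.tn, cm.tn + cm.fp, "recall(OFF)")
    return error, (prec_on + prec_off) / 2.0, (rec_on + rec_off) / 2.0


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
    )


def roc_pr_points(
    scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> tuple[list[tuple[float, float]], list[tuple[float, float]], float, float]:
    """ROC (FPR, TPR) and PR (recall, precision) curves plus trapezoid areas.

    Thresholds sweep the unique score values.  Requires both classes.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC/PR need both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    auroc = float(np.trapezoid(tpr, fpr))
    # PR curve comes recall-descending from sklearn; integrate over recall
    aupr = float(-np.trapezoid(prec, rec))
    roc_pts = list(zip(fpr.tolist(), tpr.tolist()))
    pr_pts = list(zip(rec.tolist(), prec.tolist()))
    return roc_pts, pr_pts, auroc, aupr


# ---------------------------------------------------------------------------
# Models: a minimal fit/decision interface


class RBFClassifier:
    """RBF network regression on 0/1 targets, thresholded at 0.5."""

    def __init__(self, k: int = 10, seed: int = 0) -> None:
        self.k = k
        self.seed = seed
        self.model = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFClassifier":
        self.model = train_rbf(X, y.astype(float), self.k, self.seed)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return rbf_predict(self.model, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


def _mlp_forward(params: np.ndarray, X: np.ndarray, h: int) -> np.ndarray:
    d = X.shape[1]
    W1 = params[: h * d].reshape(h, d)
    b1 = params[h * d : h * d + h]
    w2 = params[h * d + h : h * d + 2 * h]
    b2 = params[-1]
    act = 1.0 / (1.0 + np.exp(-np.clip(X @ W1.T + b1, -500, 500)))
    return act @ w2 + b2


def _mlp_n_params(d: int, h: int) -> int:
    return h * d + 2 * h + 1


class GenMLPClassifier:
    """Sigmoid MLP trained by a real-coded elitist GA on training SSE.

    Genes live in [-10, 10]; selection/crossover/mutation mirror the
    feature-construction GA (tournament parents, arithmetic one-point
    crossover on the weight vector, per-gene uniform reset mutation).
    """

    def __init__(
        self,
        hidden: int = 10,
        population: int = 50,
        generations: int = 100,
        selection_rate: float = 0.10,
        mutation_rate: float = 0.05,
        seed: int = 0,
    ) -> None:
        self.hidden = hidden
        self.population = population
        self.generations = generations
        self.selection_rate = selection_rate
        self.mutation_rate = mutation_rate
        self.seed = seed
        self.weights: np.ndarray | None = None
        self.fitness_trace: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GenMLPClassifier":
        rng = np.random.default_rng(self.seed)
        n = _mlp_n_params(X.shape[1], self.hidden)
        pop = rng.uniform(-10, 10, size=(self.population, n))
        t = y.astype(float)

        def sse(p: np.ndarray) -> float:
            r = _mlp_forward(p, X, self.hidden) - t
            return float(r @ r)

        fits = np.array([sse(p) for p in pop])
        n_off = max(2, int(round(self.selection_rate * self.population)))
        n_off = min(n_off + (n_off % 2), self.population)
        self.fitness_trace = []
        for gen in range(self.generations):
            order = np.argsort(fits, kind="stable")
            pop, fits = pop[order], fits[order]
            self.fitness_trace.append(float(fits[0]))
            if gen == self.generations - 1:
                break
            children = np.empty((n_off, n))
            for pair in range(n_off // 2):
                i, j = _two_tournament(fits, 4, rng)
                cut = int(rng.integers(1, n))
                children[2 * pair] = np.concatenate([pop[i, :cut], pop[j, cut:]])
                children[2 * pair + 1] = np.concatenate([pop[j, :cut], pop[i, cut:]])
            mask = rng.random(children.shape) <= self.mutation_rate
            children[mask] = rng.uniform(-10, 10, size=int(mask.sum()))
            child_fits = np.array([sse(p) for p in children])
            pop[-n_off:] = children
            fits[-n_off:] = child_fits
        self.weights = pop[int(np.argmin(fits))]
        self.fitness_trace = list(np.minimum.accumulate(self.fitness_trace))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return _mlp_forward(self.weights, X, self.hidden)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


def _two_tournament(fits: np.ndarray, size: int, rng: np.random.Generator) -> tuple[int, int]:
    def one() -> int:
        c = rng.integers(0, len(fits), size=size)
        return int(c[np.argmin(fits[c])])

    i = one()
    j = one()
    while j == i:
        j = one()
    return i, j


class PCAMLPClassifier:
    """Project to a few principal components, then BFGS-train the MLP."""

    def __init__(self, components: int = 2, hidden: int = 10, seed: int = 0) -> None:
        self.components = components
        self.hidden = hidden
        self.seed = seed
        self.pca: PCA | None = None
        self.weights: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PCAMLPClassifier":
        self.pca = PCA(n_components=min(self.components, X.shape[1]), random_state=self.seed)
        Z = self.pca.fit_transform(X)
        t = y.astype(float)
        rng = np.random.default_rng(self.seed)
        x0 = rng.normal(scale=0.5, size=_mlp_n_params(Z.shape[1], self.hidden))

        def sse(p: np.ndarray) -> float:
            r = _mlp_forward(p, Z, self.hidden) - t
            return float(r @ r)

        res = minimize(sse, x0, method="BFGS", options={"maxiter": 200})
        self.weights = res.x
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return _mlp_forward(self.weights, self.pca.transform(X), self.hidden)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


class FCClassifier:
    """The full feature-construction pipeline as a fold-fittable model.

    On ``fit``: score the training matrix with the composite scheme, retain
    the top fraction, evolve Nf expressions over the retained columns, and
    fit an RBF classifier on the constructed features.  ``predict`` pushes
    unseen rows through the same retained-column selection and expressions.
    """

    def __init__(
        self,
        fc_cfg: FCConfig,
        scoring_cfg: ScoringConfig | None = None,
        rbf_nodes: int = 10,
        skip_scoring: bool = False,
    ) -> None:
        self.fc_cfg = fc_cfg
        self.scoring_cfg = scoring_cfg or ScoringConfig(seed=fc_cfg.seed)
        self.rbf_nodes = rbf_nodes
        self.skip_scoring = skip_scoring
        self.retained: list[str] | None = None
        self.feature_set: ConstructedFeatureSet | None = None
        self.classifier: RBFClassifier | None = None

    def fit_matrix(self, data: FeatureMatrix) -> "FCClassifier":
        if self.skip_scoring:
            self.retained = data.column_names
            reduced = data
        else:
            scored = score_features(data, self.scoring_cfg)
            self.retained = select_top_features(scored, self.scoring_cfg)
            reduced = data.select_columns(self.retained)
        train = TrainingSet(reduced.X, reduced.labels.astype(float))
        grammar = default_feature_grammar(train.d)
        self.feature_set = evolve(train, self.fc_cfg, grammar)
        constructed = transform_dataset(reduced, self.feature_set)
        self.classifier = RBFClassifier(self.rbf_nodes, self.fc_cfg.seed).fit(
            constructed.X, constructed.labels
        )
        return self

    def transform_matrix(self, data: FeatureMatrix) -> FeatureMatrix:
        reduced = data.select_columns(self.retained)
        return transform_dataset(reduced, self.feature_set)

    def decision_matrix(self, data: FeatureMatrix) -> np.ndarray:
        return self.classifier.decision_function(self.transform_matrix(data).X)

    def predict_matrix(self, data: FeatureMatrix) -> np.ndarray:
        return (self.decision_matrix(data) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Cross-validation


ModelFactory = Callable[[int], object]


def train_baseline(data: FeatureMatrix, kind: str, cfg: EvalConfig):
    """Fit one of the reference models on the full matrix (no CV)."""
    if kind == "rbf":
        return RBFClassifier(cfg.hidden_nodes, cfg.seed).fit(data.X, data.labels)
    if kind == "gen_mlp":
        return GenMLPClassifier(hidden=cfg.hidden_nodes, seed=cfg.seed).fit(data.X, data.labels)
    if kind == "pca_mlp":
        return PCAMLPClassifier(cfg.pca_components, cfg.hidden_nodes, cfg.seed).fit(
            data.X, data.labels
        )
    raise ValueError(f"unknown baseline kind {kind!r}")


def baseline_factory(kind: str, cfg: EvalConfig) -> ModelFactory:
    """Per-fold model factory for :func:`crossval_evaluate` (seed-indexed)."""

    def make(seed: int):
        if kind == "rbf":
            return RBFClassifier(cfg.hidden_nodes, seed)
        if kind == "gen_mlp":
            return GenMLPClassifier(hidden=cfg.hidden_nodes, seed=seed)
        if kind == "pca_mlp":
            return PCAMLPClassifier(cfg.pca_components, cfg.hidden_nodes, seed)
        raise ValueError(f"unknown baseline kind {kind!r}")

    return make


def fc_factory(fc_cfg: FCConfig, scoring_cfg: ScoringConfig | None = None,
               skip_scoring: bool = False) -> ModelFactory:
    def make(seed: int):
        return FCClassifier(
            replace(fc_cfg, seed=seed),
            replace(scoring_cfg, seed=seed) if scoring_cfg else None,
            rbf_nodes=fc_cfg.rbf_nodes,
            skip_scoring=skip_scoring,
        )

    return make


def _fold_indices(
    data: FeatureMatrix, cfg: EvalConfig, repeat: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    y = data.labels
    seed = cfg.seed * 1000 + repeat
    if cfg.group_by_patient:
        return _grouped_folds(data, cfg.folds, seed)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=seed % (2**31))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _grouped_folds(data: FeatureMatrix, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped folds: all windows of one patient share a fold."""
    rng = np.random.default_rng(seed)
    patients = np.array(sorted(set(data.patient_ids)))
    rng.shuffle(patients)
    assignment = {p: i % folds for i, p in enumerate(patients)}
    fold_of = np.array([assignment[p] for p in data.patient_ids])
    out = []
    for f in range(folds):
        te = np.where(fold_of == f)[0]
        tr = np.where(fold_of != f)[0]
        if len(te) == 0 or len(np.unique(data.labels[tr])) < 2:
            continue
        out.append((tr, te))
    return out


def crossval_evaluate(
    data: FeatureMatrix,
    method: ModelFactory | str,
    cfg: EvalConfig | None = None,
    fc_cfg: FCConfig | None = None,
) -> EvaluationReport:
    """Stratified k-fold CV repeated ``cfg.repeats`` times.

    ``method`` is either a baseline name ("rbf", "gen_mlp", "pca_mlp", "fc")
    or a factory mapping a fold seed to a model.  Models exposing
    ``fit_matrix`` (the FC pipeline) receive the training fold as a
    FeatureMatrix, so scoring and construction see training rows only; plain
    models receive arrays.  Metrics are averaged over folds x repeats; ROC
    and PR points are pooled from the last repeat's out-of-fold scores.
    """
    cfg = cfg or EvalConfig()
    if len(np.unique(data.labels)) < 2:
        raise ValueError("both classes must be present")
    if isinstance(method, str):
        name = method
        if method == "fc":
            if fc_cfg is None:
                raise ValueError("fc method requires fc_cfg")
            factory = fc_factory(fc_cfg)
        else:
            factory = baseline_factory(method, cfg)
    else:
        factory = method
        name = getattr(method, "__name__", "custom")

    report = EvaluationReport(method=name, config=cfg)
    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    for repeat in range(cfg.repeats):
        for fold_i, (tr, te) in enumerate(_fold_indices(data, cfg, repeat)):
            assert len(np.intersect1d(tr, te)) == 0
            model = factory(cfg.seed * 100_000 + repeat * 100 + fold_i)
            if hasattr(model, "fit_matrix"):
                model.fit_matrix(data.subset_rows(tr))
                scores = model.decision_matrix(data.subset_rows(te))
                preds = (scores >= 0.5).astype(int)
            else:
                train, test = data.subset_rows(tr), data.subset_rows(te)
                model.fit(train.X, train.labels)
                scores = model.decision_function(test.X)
                preds = model.predict(test.X)
            y_te = data.labels[te]
            err, prec, rec = compute_metrics(confusion_from_predictions(y_te, preds))
            report.fold_errors.append(err)
            report.fold_precisions.append(prec)
            report.fold_recalls.append(rec)
            if repeat == cfg.repeats - 1:
                pooled_scores.extend(np.asarray(scores, dtype=float).tolist())
                pooled_labels.extend(y_te.tolist())
    if len(np.unique(pooled_labels)) == 2:
        roc_pts, pr_pts, auroc, _ = roc_pr_points(pooled_scores, pooled_labels)
        report.roc_points = roc_pts
        report.pr_points = pr_pts
        report.auroc = auroc
    return report
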