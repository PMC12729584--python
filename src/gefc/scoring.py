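"""Tripartite composite feature ranking.

Each feature is scored from three complementary angles and the scores fused
into a single composite:

* statistical significance — a paired t-test between OFF and ON values,
  mapped to ``-log10(p + eps)`` so smaller p-values earn exponentially
  larger scores (eps guards p = 0);
* model-based importance — mean decrease in Gini impurity across a random
  forest, averaged over trees and left unnormalised;
* variance contribution — the sum of a feature's absolute PCA loadings
  (correlation loadings on standardised data) across all retained
  components.

The three raw score vectors are min-max normalised independently and fused
as ``0.4 * t-test + 0.3 * forest + 0.3 * PCA``; the top 80% of features by
composite score are retained for downstream feature construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier

from .signal_features import FeatureMatrix

__all__ = [
    "ScoringConfig",
    "ScoreBreakdown",
    "ttest_score",
    "rf_gini_importance",
    "pca_loading_score",
    "composite_scores",
    "select_top_features",
    "score_features",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    epsilon: float = 1e-10
    weight_ttest: float = 0.4
    weight_rf: float = 0.3
    weight_pca: float = 0.3
    n_trees: int = 200
    retention_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        w = (self.weight_ttest, self.weight_rf, self.weight_pca)
        if any(wi < 0 for wi in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0 < self.retention_fraction <= 1):
            raise ValueError("retention_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ScoreBreakdown:
    """One feature's raw, normalised and composite scores plus its rank."""

    feature_name: str
    score_ttest: float = 0.0
    score_rf: float = 0.0
    score_pca: float = 0.0
    norm_ttest: float = 0.0
    norm_rf: float = 0.0
    norm_pca: float = 0.0
    composite: float = 0.0
    rank: int = 0


def ttest_score(
    off_values: Sequence[float] | np.ndarray,
    on_values: Sequence[float] | np.ndarray,
    pairing: tuple[Sequence, Sequence] | None = None,
    cfg: ScoringConfig | None = None,
) -> float:
    """Significance of the OFF/ON shift as ``-log10(p + eps)``.

    With ``pairing = (off_patient_ids, on_patient_ids)`` the window-level
    values are first aggregated to per-patient means per state and a paired
    t-test is run over the common patients; without pairing keys a Welch
    unpaired test is used (logged, since pairing is the intended design).
    The eps guard caps the score at ``-log10(eps)`` (10 for the default
    1e-10) when separation is perfect.
    """
    cfg = cfg or ScoringConfig()
    off = np.asarray(off_values, dtype=float)
    on = np.asarray(on_values, dtype=float)
    if len(off) == 0 or len(on) == 0:
        raise ValueError("both groups must be non-empty")
    if pairing is not None:
        off_mean = _per_key_means(off, pairing[0])
        on_mean = _per_key_means(on, pairing[1])
        if set(off_mean) != set(on_mean):
            raise ValueError(
                "paired t-test requires the same patients in both states; "
                f"mismatch: {sorted(set(off_mean) ^ set(on_mean))}"
            )
        keys = sorted(off_mean)
        a = np.array([off_mean[k] for k in keys])
        b = np.array([on_mean[k] for k in keys])
        diff = a - b
        if np.std(diff) == 0.0:
            # zero-variance difference: perfectly consistent shift (p -> 0)
            # or perfectly identical samples (p = 1)
            p = 1.0 if np.mean(diff) == 0.0 else 0.0
        else:
            p = float(sps.ttest_rel(a, b).pvalue)
    else:
        log.debug("no pairing keys given; falling back to Welch's unpaired t-test")
        if np.std(off) == 0.0 and np.std(on) == 0.0:
            p = 1.0 if np.mean(off) == np.mean(on) else 0.0
        elif len(off) == len(on) and np.allclose(off, on):
            p = 1.0
        else:
            p = float(sps.ttest_ind(off, on, equal_var=False).pvalue)
    if not np.isfinite(p):
        p = 1.0
    return float(-np.log10(p + cfg.epsilon))


def _per_key_means(values: np.ndarray, keys: Sequence) -> dict:
    sums: dict = {}
    counts: dict = {}
    for v, k in zip(values, keys):
        sums[k] = sums.get(k, 0.0) + float(v)
        counts[k] = counts.get(k, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def rf_gini_importance(X: FeatureMatrix, cfg: ScoringConfig | None = None) -> dict[str, float]:
    """Per-feature mean decrease in Gini impurity over a seeded forest.

    Uses unnormalised per-tree impurity decreases averaged across trees (an
    average, not a distribution over features), so the values are absolute
    impurity reductions rather than fractions summing to 1.
    """
    cfg = cfg or ScoringConfig()
    y = X.labels
    if len(np.unique(y)) < 2:
        raise ValueError("Gini importance needs at least two classes")
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion="gini",
        max_features="sqrt",
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(X.X, y)
    per_tree = np.stack(
        [est.tree_.compute_feature_importances(normalize=False) for est in forest.estimators_]
    )
    mean_decrease = per_tree.mean(axis=0)
    return dict(zip(X.column_names, mean_decrease.astype(float)))


def pca_loading_score(X: FeatureMatrix) -> dict[str, float]:
    """Sum of absolute correlation loadings across all principal components.

    Columns are standardised; the loading of feature j on component i is the
    eigenvector entry scaled by sqrt(eigenvalue), i.e. the correlation of the
    feature with the component.  All components with eigenvalue > 1e-12 are
    retained.  Zero-variance columns get score 0 (logged).
    """
    A = X.X
    if A.shape[0] < 2:
        raise ValueError("PCA scoring needs at least 2 rows")
    std = A.std(axis=0)
    nonzero = std > 0
    if not nonzero.any():
        raise ValueError("all columns have zero variance")
    if (~nonzero).any():
        log.warning("%d zero-variance columns scored 0", int((~nonzero).sum()))
    Z = (A[:, nonzero] - A[:, nonzero].mean(axis=0)) / std[nonzero]
    corr = (Z.T @ Z) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    keep = eigval > 1e-12
    loadings = eigvec[:, keep] * np.sqrt(eigval[keep])[None, :]
    scores_nz = np.sum(np.abs(loadings), axis=1)
    scores = np.zeros(A.shape[1])
    scores[nonzero] = scores_nz
    return dict(zip(X.column_names, scores.astype(float)))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo <= 0:
        # A constant raw vector carries no ranking information; map to 0.
        log.warning("constant raw score vector min-max normalised to all zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def composite_scores(
    raw: Sequence[ScoreBreakdown], cfg: ScoringConfig | None = None
) -> list[ScoreBreakdown]:
    """Min-max normalise each raw score vector and fuse with 0.4/0.3/0.3.

    Ranks are assigned by descending composite score (ties broken by
    ascending feature name so ranking is deterministic).
    """
    cfg = cfg or ScoringConfig()
    if len(raw) < 2:
        raise ValueError("composite scoring needs at least 2 features")
    t = _minmax(np.array([s.score_ttest for s in raw]))
    r = _minmax(np.array([s.score_rf for s in raw]))
    p = _minmax(np.array([s.score_pca for s in raw]))
    composite = cfg.weight_ttest * t + cfg.weight_rf * r + cfg.weight_pca * p
    order = sorted(
        range(len(raw)), key=lambda i: (-composite[i], raw[i].feature_name)
    )
    ranks = np.empty(len(raw), dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    return [
        replace(
            s,
            norm_ttest=float(t[i]),
            norm_rf=float(r[i]),
            norm_pca=float(p[i]),
            composite=float(composite[i]),
            rank=int(ranks[i]),
        )
        for i, s in enumerate(raw)
    ]


def select_top_features(
    scored: Sequence[ScoreBreakdown], cfg: ScoringConfig | None = None
) -> list[str]:
    """Names of the best ``max(1, floor(retention * n))`` features by composite."""
    cfg = cfg or ScoringConfig()
    if not scored:
        raise ValueError("no scored features")
    k = max(1, int(np.floor(cfg.retention_fraction * len(scored))))
    ordered = sorted(scored, key=lambda s: (-s.composite, s.feature_name))
    return [s.feature_name for s in ordered[:k]]


def score_features(
    X: FeatureMatrix,
    cfg: ScoringConfig | None = None,
    paired: bool = True,
) -> list[ScoreBreakdown]:
    """Full scoring pass over a labelled feature matrix.

    Runs the three scorers per feature, fuses them into composites, and
    returns the breakdowns ordered as the matrix columns.  ``paired=True``
    aggregates window values to per-patient means for the t-test when
    patient ids are available.
    """
    cfg = cfg or ScoringConfig()
    y = X.labels
    off_rows = y == 0
    on_rows = y == 1
    if not off_rows.any() or not on_rows.any():
        raise ValueError("both OFF and ON rows are required")
    have_patients = paired and bool(np.all(X.patient_ids != ""))
    pairing = None
    if have_patients:
        pairing = (X.patient_ids[off_rows], X.patient_ids[on_rows])
        if set(pairing[0]) != set(pairing[1]):
            log.warning("patient sets differ between states; using unpaired t-test")
            pairing = None
    rf = rf_gini_importance(X, cfg)
    pca = pca_loading_score(X)
    raw = []
    A = X.X
    for j, name in enumerate(X.column_names):
        t_score = ttest_score(A[off_rows, j], A[on_rows, j], pairing, cfg)
        raw.append(
            ScoreBreakdown(
                feature_name=name,
                score_ttest=t_score,
                score_rf=rf[name],
                score_pca=pca[name],
            )
        )
    return composite_scores(raw, cfg)
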