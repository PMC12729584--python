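"""Composite feature-scoring tests: closed forms, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gefc.scoring import (
    ScoreBreakdown,
    ScoringConfig,
    composite_scores,
    pca_loading_score,
    rf_gini_importance,
    score_features,
    select_top_features,
    ttest_score,
)
from gefc.signal_features import FeatureMatrix


def _matrix(X, y, patients=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])]),
        np.asarray(y),
        np.asarray(patients, dtype=object) if patients is not None else None,
    )


# ---------------------------------------------------------------------------
# t-test score


def test_perfect_separation_hits_epsilon_ceiling():
    """A perfectly consistent shift gives p=0, capped at -log10(eps)=10."""
    patients = ["a", "b", "c", "d"]
    off = [1.0, 2.0, 3.0, 4.0]
    on = [0.0, 1.0, 2.0, 3.0]  # constant unit shift per patient
    score = ttest_score(off, on, pairing=(patients, patients))
    assert score == pytest.approx(10.0, abs=1e-12)


def test_identical_paired_samples_score_zero():
    patients = ["a", "b", "c"]
    vals = [1.0, 5.0, 9.0]
    score = ttest_score(vals, vals, pairing=(patients, patients))
    assert abs(score) < 1e-9


def test_welch_fallback_matches_textbook_oracle(rng):
    a = rng.normal(0.0, 1.0, 20)
    b = rng.normal(0.8, 1.3, 20)
    # textbook Welch statistic and two-sided p from the t distribution
    va, vb = a.var(ddof=1) / 20, b.var(ddof=1) / 20
    t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    dof = (va + vb) ** 2 / (va**2 / 19 + vb**2 / 19)
    p = 2 * sps.t.sf(abs(t_stat), dof)
    assert ttest_score(a, b) == pytest.approx(-np.log10(p + 1e-10), abs=1e-9)


def test_paired_mode_rejects_unmatched_patients():
    with pytest.raises(ValueError):
        ttest_score([1, 2], [3, 4], pairing=(["a", "b"], ["a", "c"]))


def test_pairing_aggregates_windows_to_patient_means():
    # two windows per patient; per-patient means shift by exactly 1
    off = [2.0, 4.0, 10.0, 12.0]
    on = [1.0, 3.0, 9.0, 11.0]
    pairing = (["a", "a", "b", "b"], ["a", "a", "b", "b"])
    assert ttest_score(off, on, pairing=pairing) == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# random forest importance


def test_separating_feature_outranks_noise(rng):
    y = np.repeat([0, 1], 30)
    X = np.column_stack([y + rng.normal(0, 0.05, 60), rng.normal(0, 1, 60)])
    imp = rf_gini_importance(_matrix(X, y), ScoringConfig(n_trees=50, seed=0))
    assert imp["f0"] > imp["f1"]
    assert all(v >= 0 for v in imp.values())


def test_stump_importance_equals_hand_gini():
    """4 points, 1 feature, pure split: root ΔGini = 0.5 - 0 = 0.5."""
    from sklearn.ensemble import RandomForestClassifier

    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 1, 1])
    forest = RandomForestClassifier(
        n_estimators=10, max_depth=1, bootstrap=False, max_features=1, random_state=0
    ).fit(X, y)
    per_tree = [
        est.tree_.compute_feature_importances(normalize=False)[0]
        for est in forest.estimators_
    ]
    assert np.mean(per_tree) == pytest.approx(0.5, abs=1e-12)


def test_importance_deterministic_given_seed(rng):
    y = np.repeat([0, 1], 20)
    X = rng.normal(size=(40, 5))
    m = _matrix(X, y)
    cfg = ScoringConfig(n_trees=30, seed=7)
    assert rf_gini_importance(m, cfg) == rf_gini_importance(m, cfg)


def test_importance_rejects_single_class(rng):
    with pytest.raises(ValueError):
        rf_gini_importance(_matrix(rng.normal(size=(10, 2)), np.zeros(10, int)))


# ---------------------------------------------------------------------------
# PCA loading score


def test_duplicated_columns_score_equally(rng):
    col = rng.normal(size=40)
    X = np.column_stack([col, col, rng.normal(size=40)])
    scores = pca_loading_score(_matrix(X, np.repeat([0, 1], 20)))
    assert scores["f0"] == pytest.approx(scores["f1"], abs=1e-9)


def test_two_column_closed_form(rng):
    """Scores match the analytic eigendecomposition of [[1, r], [r, 1]]."""
    z = rng.normal(size=(200, 2))
    X = np.column_stack([z[:, 0], 0.6 * z[:, 0] + 0.8 * z[:, 1]])
    m = _matrix(X, np.repeat([0, 1], 100))
    r = np.corrcoef((X - X.mean(0)) / X.std(0), rowvar=False)[0, 1]
    # eigenvectors (1,1)/sqrt2 and (1,-1)/sqrt2; eigenvalues 1+r and 1-r
    expected = (np.sqrt(1 + r) + np.sqrt(abs(1 - r))) / np.sqrt(2)
    scores = pca_loading_score(m)
    assert scores["f0"] == pytest.approx(expected, abs=1e-9)
    assert scores["f1"] == pytest.approx(expected, abs=1e-9)


def test_zero_variance_column_scores_zero(rng):
    X = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
    scores = pca_loading_score(_matrix(X, np.repeat([0, 1], 10)))
    assert scores["f0"] == 0.0


# ---------------------------------------------------------------------------
# composite and selection


def _raw(names, t, r, p):
    return [
        ScoreBreakdown(n, score_ttest=ti, score_rf=ri, score_pca=pi)
        for n, ti, ri, pi in zip(names, t, r, p)
    ]


def test_composite_weight_closed_forms():
    scored = composite_scores(
        _raw(["a", "b", "c"], t=[1, 0, 0.5], r=[0, 1, 0.5], p=[0, 1, 0.5])
    )
    by_name = {s.feature_name: s for s in scored}
    assert by_name["a"].composite == pytest.approx(0.4)  # normalised (1,0,0)
    assert by_name["b"].composite == pytest.approx(0.6)  # normalised (0,1,1)
    assert by_name["c"].composite == pytest.approx(0.5)


def test_composite_all_max_is_one():
    scored = composite_scores(_raw(["a", "b"], t=[1, 0], r=[2, 0], p=[5, 1]))
    assert {s.feature_name: s.composite for s in scored}["a"] == pytest.approx(1.0)


def test_composite_affine_invariance(rng):
    t, r, p = rng.normal(size=(3, 8))
    base = composite_scores(_raw(list("abcdefgh"), t, r, p))
    scaled = composite_scores(_raw(list("abcdefgh"), 3 * t - 7, 0.1 * r + 2, p))
    for s1, s2 in zip(base, scaled):
        assert s1.composite == pytest.approx(s2.composite, abs=1e-12)
        assert s1.rank == s2.rank


def test_constant_raw_vector_normalises_to_zero():
    scored = composite_scores(_raw(["a", "b"], t=[3, 3], r=[0, 1], p=[1, 0]))
    assert all(s.norm_ttest == 0.0 for s in scored)


def test_ranks_are_permutation():
    scored = composite_scores(
        _raw(list("abcde"), *np.random.default_rng(3).normal(size=(3, 5)))
    )
    assert sorted(s.rank for s in scored) == [1, 2, 3, 4, 5]


def test_raising_raw_tscore_never_lowers_rank(rng):
    names = [f"f{i}" for i in range(10)]
    t, r, p = rng.uniform(size=(3, 10))
    base = composite_scores(_raw(names, t, r, p))
    # bump a mid-pack feature without moving the min/max endpoints
    j = int(np.argsort(t)[5])
    t2 = t.copy()
    t2[j] = min(t2[j] + 0.5 * (t.max() - t2[j]), t.max())
    bumped = composite_scores(_raw(names, t2, r, p))
    assert bumped[j].rank <= base[j].rank


@pytest.mark.parametrize("n,kept", [(20, 16), (5, 4), (1, 1)])
def test_top_80pct_selection(n, kept, rng):
    scored = composite_scores(
        _raw([f"f{i}" for i in range(n)], *rng.uniform(size=(3, n)))
    ) if n > 1 else [ScoreBreakdown("f0", composite=1.0, rank=1)]
    assert len(select_top_features(scored)) == kept


def test_score_features_end_to_end_deterministic(rng):
    y = np.repeat([0, 1], 20)
    X = np.column_stack([y + rng.normal(0, 0.3, 40), rng.normal(size=(40, 3))])
    patients = np.repeat([f"p{i}" for i in range(8)], 5)
    m = _matrix(X, y, patients)
    a = score_features(m, ScoringConfig(seed=5))
    b = score_features(m, ScoringConfig(seed=5))
    assert a == b
    assert a[0].feature_name == "f0"  # informative feature columns stay aligned
    assert a[0].rank == 1  # and win the composite ranking
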