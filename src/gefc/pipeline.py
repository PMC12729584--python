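"""End-to-end orchestration: simulate -> extract -> score -> construct -> evaluate.

Each stage is available separately (and through the CLI); ``run_pipeline``
chains them for a set of exercises, writing per-exercise artifacts into an
output directory:

* ``features_ex{e}.csv``   — the 87-column windowed feature matrix;
* ``scores_ex{e}.csv``     — the composite score table;
* ``expressions_ex{e}.txt``— the evolved feature expressions (infix);
* ``report.csv``           — per-exercise mean error / precision / recall
                             for the evaluated methods;
* ``manifest.json``        — config snapshot, seed, artifact list and the
                             evolved expressions (enough to re-run the exact
                             same computation).

All randomness flows from the config's global seed: the simulator derives
per-session generators from it, and cross-validation derives fold seeds
from ``seed``, the repeat index and the fold index.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .construction import ConstructedFeatureSet, TrainingSet, evolve
from .evaluation import EvaluationReport, crossval_evaluate
from .grammar import default_feature_grammar
from .io import (
    PipelineConfig,
    config_snapshot,
    write_feature_matrix,
    write_manifest,
    write_scores_csv,
)
from .scoring import score_features, select_top_features
from .signal_features import FeatureMatrix, RecordingSession, extract_feature_matrix
from .simulate import generate_cohort

__all__ = ["run_pipeline", "construct_features", "PipelineResult"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    reports: dict[int, dict[str, EvaluationReport]]
    feature_sets: dict[int, ConstructedFeatureSet]
    artifacts: list[str]


def construct_features(
    data: FeatureMatrix, cfg: PipelineConfig
) -> tuple[ConstructedFeatureSet, list[str]]:
    """Score, retain the top fraction, and evolve Nf expressions (full data).

    This is the exploratory, whole-dataset construction used for reporting
    the evolved expressions; the cross-validated evaluation re-runs
    construction inside each training fold instead.
    """
    scored = score_features(data, cfg.scoring)
    retained = select_top_features(scored, cfg.scoring)
    reduced = data.select_columns(retained)
    train = TrainingSet(reduced.X, reduced.labels.astype(float))
    fs = evolve(train, cfg.fc, default_feature_grammar(train.d))
    return fs, retained


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    sessions: Sequence[RecordingSession] | None = None,
    methods: Sequence[str] = ("rbf", "fc"),
) -> PipelineResult:
    """Run every stage for each configured exercise and write artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sessions is None:
        log.info("simulating cohort: %d patients, seed %d", cfg.sim.n_patients, cfg.sim.seed)
        sessions = generate_cohort(cfg.sim).sessions

    artifacts: list[str] = []
    reports: dict[int, dict[str, EvaluationReport]] = {}
    feature_sets: dict[int, ConstructedFeatureSet] = {}
    report_rows = []
    for exercise in cfg.exercises:
        ex_sessions = [s for s in sessions if s.exercise == exercise]
        if not ex_sessions:
            raise ValueError(f"no sessions for exercise {exercise}")
        data = extract_feature_matrix(ex_sessions, cfg.window)
        log.info("exercise %d: %d windows x %d features", exercise, len(data), len(data.column_names))
        fpath = outdir / f"features_ex{exercise}.csv"
        write_feature_matrix(data, fpath)
        artifacts.append(fpath.name)

        scored = score_features(data, cfg.scoring)
        spath = outdir / f"scores_ex{exercise}.csv"
        write_scores_csv(scored, spath, exercise)
        artifacts.append(spath.name)

        retained = select_top_features(scored, cfg.scoring)
        reduced = data.select_columns(retained)
        train = TrainingSet(reduced.X, reduced.labels.astype(float))
        fs = evolve(train, cfg.fc, default_feature_grammar(train.d))
        feature_sets[exercise] = fs
        epath = outdir / f"expressions_ex{exercise}.txt"
        epath.write_text("\n".join(fs.expression_strings) + "\n")
        artifacts.append(epath.name)

        reports[exercise] = {}
        for method in methods:
            rep = crossval_evaluate(data, method, cfg.eval, fc_cfg=cfg.fc)
            reports[exercise][method] = rep
            report_rows.append(
                {
                    "exercise": exercise,
                    "method": method,
                    "error_pct": rep.mean_error,
                    "precision": rep.mean_precision,
                    "recall": rep.mean_recall,
                    "auroc": rep.auroc,
                }
            )
            log.info(
                "exercise %d %s: error %.2f%% precision %.3f recall %.3f",
                exercise, method, rep.mean_error, rep.mean_precision, rep.mean_recall,
            )

    rpath = outdir / "report.csv"
    pd.DataFrame(report_rows).to_csv(rpath, index=False, float_format="%.12g")
    artifacts.append(rpath.name)

    write_manifest(
        outdir / "manifest.json",
        {
            "config": config_snapshot(cfg),
            "artifacts": artifacts,
            "expressions": {str(e): fs.expression_strings for e, fs in feature_sets.items()},
            "best_fitness": {str(e): fs.best_fitness for e, fs in feature_sets.items()},
        },
    )
    artifacts.append("manifest.json")
    return PipelineResult(reports, feature_sets, artifacts)
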