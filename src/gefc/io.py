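"""CSV and config I/O for the pipeline.

All data exchange uses a single dialect — UTF-8, comma-separated, "."
decimal point — with two table schemas:

* session CSV (long form): ``patient_id, exercise, state, sensor, t_index,
  x, y, z``, one row per sample per sensor;
* feature-matrix CSV: one column per feature, then trailing ``label``,
  ``patient_id``, ``window_index`` columns.

Configuration files are YAML with nested blocks (``sampling``, ``window``,
``scoring``, ``fc``, ``eval``, ``sim`` plus top-level ``seed`` /
``exercises``); unknown keys are rejected rather than ignored so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .construction import FCConfig
from .evaluation import EvalConfig
from .scoring import ScoreBreakdown, ScoringConfig
from .signal_features import (
    SENSOR_NAMES,
    FeatureMatrix,
    RecordingSession,
    TriAxialSeries,
    WindowSpec,
)
from .simulate import SimulationConfig

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_sessions_csv",
    "write_sessions_csv",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_scores_csv",
    "write_manifest",
]

_META_COLUMNS = ("label", "patient_id", "window_index")
_FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# Sessions


def write_sessions_csv(sessions: Sequence[RecordingSession], path: str | Path) -> None:
    frames = []
    for s in sessions:
        for sensor in SENSOR_NAMES:
            series = s.sensors[sensor]
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": s.patient_id,
                        "exercise": s.exercise,
                        "state": s.state,
                        "sensor": sensor,
                        "t_index": np.arange(len(series)),
                        "x": series.x,
                        "y": series.y,
                        "z": series.z,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_sessions_csv(path: str | Path, fs: float = 100.0) -> list[RecordingSession]:
    df = pd.read_csv(path)
    required = {"patient_id", "exercise", "state", "sensor", "t_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"session CSV missing columns: {sorted(missing)}")
    sessions = []
    keys = df[["patient_id", "exercise", "state"]].drop_duplicates()
    for _, key in keys.iterrows():
        sub = df[
            (df.patient_id == key.patient_id)
            & (df.exercise == key.exercise)
            & (df.state == key.state)
        ]
        sensors = {}
        for sensor, block in sub.groupby("sensor"):
            block = block.sort_values("t_index")
            sensors[sensor] = TriAxialSeries(
                block.x.to_numpy(), block.y.to_numpy(), block.z.to_numpy(), fs
            )
        sessions.append(
            RecordingSession(str(key.patient_id), int(key.exercise), str(key.state), sensors)
        )
    return sessions


# ---------------------------------------------------------------------------
# Feature matrices


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    df = m.values.copy()
    for col in df.columns:
        if col in _META_COLUMNS:
            raise ValueError(f"feature column name collides with metadata: {col!r}")
    df["label"] = m.labels
    df["patient_id"] = m.patient_ids
    df["window_index"] = m.window_index
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if df.columns.duplicated().any():
        raise ValueError("duplicated column names in feature CSV")
    if "label" not in df.columns:
        raise ValueError("feature CSV lacks the 'label' column")
    feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
    values = df[feature_cols]
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        bad = [c for c, dt in zip(feature_cols, values.dtypes) if not np.issubdtype(dt, np.number)]
        raise ValueError(f"non-numeric feature columns: {bad}")
    return FeatureMatrix(
        values.astype(float).reset_index(drop=True),
        df["label"].to_numpy(dtype=int),
        df["patient_id"].to_numpy(dtype=object) if "patient_id" in df else None,
        df["window_index"].to_numpy(dtype=int) if "window_index" in df else None,
    )


def write_scores_csv(
    scored: Sequence[ScoreBreakdown], path: str | Path, exercise: int | None = None
) -> None:
    """Score table: exercise, sensor, feature name, raw scores, composite, rank."""
    rows = []
    for s in scored:
        sensor, _, feat = s.feature_name.partition("_")
        if sensor not in SENSOR_NAMES:
            sensor, feat = "", s.feature_name
        rows.append(
            {
                "exercise": exercise if exercise is not None else "",
                "sensor": sensor,
                "feature_name": feat,
                "score_ttest": s.score_ttest,
                "score_rf": s.score_rf,
                "score_pca": s.score_pca,
                "composite": s.composite,
                "rank": s.rank,
            }
        )
    pd.DataFrame(rows).sort_values("rank").to_csv(path, index=False, float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for the end-to-end pipeline."""

    seed: int = 0
    exercises: tuple[int, ...] = (0, 1, 2, 3)
    fs_hz: float = 100.0
    window: WindowSpec = field(default_factory=WindowSpec)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    fc: FCConfig = field(default_factory=FCConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)


_BLOCK_TYPES = {
    "window": WindowSpec,
    "scoring": ScoringConfig,
    "fc": FCConfig,
    "eval": EvalConfig,
    "sim": SimulationConfig,
}
def load_config(source: str | Path | Mapping[str, Any] | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from YAML (path) or a mapping.

    Unknown block names or keys raise a ``ValueError`` naming the offender.
    The global ``seed`` propagates into every block that accepts one unless
    the block sets its own.
    """
    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    known_top = {"seed", "exercises", "sampling"} | set(_BLOCK_TYPES)
    unknown = set(data) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    seed = int(data.get("seed", 0))
    exercises = tuple(int(e) for e in data.get("exercises", (0, 1, 2, 3)))
    sampling = data.get("sampling", {}) or {}
    if set(sampling) - {"fs_hz"}:
        raise ValueError(f"unknown sampling keys: {sorted(set(sampling) - {'fs_hz'})}")
    fs_hz = float(sampling.get("fs_hz", 100.0))

    blocks: dict[str, Any] = {}
    for name, cls in _BLOCK_TYPES.items():
        block_data = dict(data.get(name, {}) or {})
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(block_data) - valid
        if bad:
            raise ValueError(f"unknown {name}.* keys: {sorted(bad)}")
        if "seed" in valid and "seed" not in block_data:
            block_data["seed"] = seed
        blocks[name] = cls(**block_data)
    return PipelineConfig(
        seed=seed, exercises=exercises, fs_hz=fs_hz,
        window=blocks["window"], scoring=blocks["scoring"], fc=blocks["fc"],
        eval=blocks["eval"], sim=blocks["sim"],
    )


def config_snapshot(cfg: PipelineConfig) -> dict[str, Any]:
    out: dict[str, Any] = {"seed": cfg.seed, "exercises": list(cfg.exercises),
                           "sampling": {"fs_hz": cfg.fs_hz}}
    for name in _BLOCK_TYPES:
        out[name] = dataclasses.asdict(getattr(cfg, name))
    return out


def write_manifest(path: str | Path, payload: Mapping[str, Any]) -> None:
    """JSON run manifest: config snapshot, seeds, artifacts, expressions."""

    def default(o):  # tuples inside dataclass asdict etc.
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
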