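"""End-to-end orchestration: extract -> select -> train -> evaluate -> score.

``extract_features`` turns every available participant-task recording into
the canonical 234-value feature vector (39 time + 39 frequency features
per sensor, three sensors).  ``run_full`` drives the complete experiment —
feature tables per task, cross-validated ensemble classification, and the
leave-one-out MIS regression on the HD participants — writing all
artifacts into a run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import EvalReport, kfold_evaluate
from .io_core import (
    CohortDataset,
    FeatureVector,
    Group,
    Task,
    ValidationError,
    write_feature_table,
)
from .mis import RegressionReport, fit_mis, loocv_mis
from .registry import FEATURE_NAMES
from .selection import discretize_matrix, jmim_rank
from .synth import SimulationConfig, simulate_cohort
from .timefeat import RqaParams, time_features_sensor
from .freqfeat import freq_features_sensor

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-level configuration; every block is overridable from YAML."""

    seed: int = 7
    out_dir: str = "run"
    manifest: str | None = None  # None -> simulate a cohort
    n_control: int = 48
    n_hd: int = 44
    k_folds: int = 5
    n_bins: int = 5
    n_grid: tuple[int, ...] = (5, 10, 20, 40)
    inner_k: int = 3
    ablate_chest: bool = False
    mis_top_k: int = 5
    rqa: RqaParams = field(default_factory=RqaParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rqa = RqaParams(**raw.pop("rqa", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k != "rqa"}, rqa=rqa)
        if isinstance(cfg.n_grid, list):
            cfg.n_grid = tuple(cfg.n_grid)
        return cfg


def extract_session_features(
    recording, rqa_params: RqaParams | None = None
) -> FeatureVector:
    """All 234 features of one three-sensor recording."""
    values: dict[str, float] = {}
    for sensor in recording.sensors.values():
        values.update(time_features_sensor(sensor, rqa_params))
        values.update(freq_features_sensor(sensor))
    values = {n: values[n] for n in FEATURE_NAMES}
    return FeatureVector(
        participant_id=recording.participant_id, task=recording.task, values=values
    )


def extract_features(
    cohort: CohortDataset, rqa_params: RqaParams | None = None
) -> dict[tuple[str, Task], FeatureVector]:
    """One feature vector per available participant-task; missing tasks
    are skipped, an invalid recording aborts naming the offender."""
    out: dict[tuple[str, Task], FeatureVector] = {}
    for (pid, task), rec in sorted(cohort.recordings.items()):
        try:
            out[(pid, task)] = extract_session_features(rec, rqa_params)
        except ValidationError as exc:
            raise ValidationError(
                f"feature extraction failed for participant {pid}, "
                f"task {task.value}: {exc}"
            ) from exc
    return out


def feature_tables(
    features: dict[tuple[str, Task], FeatureVector]
) -> dict[Task, pd.DataFrame]:
    """Per-task DataFrames (participants x 234), indexed by participant id."""
    tables: dict[Task, pd.DataFrame] = {}
    for task in Task:
        rows = {
            pid: vec.as_array()
            for (pid, t), vec in features.items()
            if t is task
        }
        if rows:
            df = pd.DataFrame.from_dict(
                rows, orient="index", columns=list(FEATURE_NAMES)
            ).sort_index()
            df.attrs["task"] = task
            tables[task] = df
    return tables


def rank_baseline_features(
    table: pd.DataFrame,
    labels: dict[str, Group],
    k: int,
    n_bins: int = 5,
):
    """Whole-cohort JMIM ranking of a task table against the group labels."""
    y = np.array([1 if Group(labels[p]) == Group.HD else 0 for p in table.index])
    codes = discretize_matrix(table.to_numpy(dtype=float), n_bins)
    return jmim_rank(codes, y, k, list(table.columns))


def run_full(
    config: PipelineConfig,
    cohort: CohortDataset | None = None,
) -> dict:
    """Run the whole experiment; returns the result dictionary and writes
    artifacts (feature tables, ranking, reports) under ``config.out_dir``."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        if config.manifest is not None:
            from .io_core import read_cohort

            cohort = read_cohort(config.manifest)
        else:
            cohort = simulate_cohort(
                SimulationConfig(
                    n_control=config.n_control,
                    n_hd=config.n_hd,
                    seed=config.seed,
                )
            )
    labels = cohort.labels()

    logger.info("extracting features for %d recordings", len(cohort.recordings))
    features = extract_features(cohort, config.rqa)
    tables = feature_tables(features)
    for task, df in tables.items():
        vecs = [features[(pid, task)] for pid in df.index]
        write_feature_table(vecs, out_dir / f"features_{task.value}.csv")

    report: EvalReport = kfold_evaluate(
        tables,
        labels,
        k=config.k_folds,
        seed=config.seed,
        n_grid=config.n_grid,
        inner_k=config.inner_k,
        n_bins=config.n_bins,
        ablate_chest=config.ablate_chest,
    )
    report.to_json(out_dir / "eval_report.json")

    # MIS: top-5 features of the whole-cohort baseline-simple ranking,
    # regression on HD participants only
    base = tables[Task.BASELINE_SIMPLE]
    ranking = rank_baseline_features(
        base, labels, k=config.mis_top_k, n_bins=config.n_bins
    )
    top5 = ranking.names
    hd_ids = [p.id for p in cohort.participants if p.group is Group.HD]
    hd_ids = [p for p in base.index if p in set(hd_ids)]
    mulms = np.array(
        [next(p.mulms for p in cohort.participants if p.id == pid) for pid in hd_ids],
        dtype=float,
    )
    X5 = base.loc[hd_ids, top5]
    mis_report: RegressionReport = loocv_mis(X5, mulms)
    mis_report.to_json(out_dir / "mis_report.json")
    mis_model = fit_mis(X5, mulms)
    mis_model.to_json(out_dir / "mis_model.json")

    results = {
        "seed": config.seed,
        "n_participants": len(cohort.participants),
        "classification": {
            "pooled": report.pooled,
            "fold_averaged": report.fold_averaged,
            "per_task_pooled_accuracy": report.per_task_pooled_accuracy,
        },
        "mis": mis_report.metrics,
        "mis_features": top5,
        "wall_time_s": round(time.time() - t0, 2),
        "config": {
            k: (v if not dataclasses.is_dataclass(v) else dataclasses.asdict(v))
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with (out_dir / "results.json").open("w") as fh:
        json.dump(results, fh, indent=2)
    return results
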