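import random

import numpy as np
import pytest

from hdmotion.classify import kfold_evaluate
from hdmotion.io_core import Group, Task
from hdmotion.mis import loocv_mis
from hdmotion.pipeline import extract_features, feature_tables, rank_baseline_features
from hdmotion.synth import SimulationConfig, simulate_cohort, simulate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def healthy_session():
    return simulate_session(
        Group.CONTROL, 0.0, Task.BASELINE_SIMPLE,
        np.random.default_rng(1), participant_id="hc",
    )


@pytest.fixture(scope="session")
def severe_session():
    return simulate_session(
        Group.HD, 18.0, Task.BASELINE_SIMPLE,
        np.random.default_rng(1), participant_id="hd",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 48 controls, 44 HD, seed 7."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_experiment(default_cohort):
    """Full experiment on the default cohort, computed once per test run:
    feature tables, 5-fold ensemble evaluation (full, chest-ablated, and
    label-permuted), and the LOOCV severity regression (true and permuted
    targets)."""
    cohort = default_cohort
    labels = cohort.labels()
    tables = feature_tables(extract_features(cohort))

    report = kfold_evaluate(tables, labels, k=5, seed=7)
    report_ablated = kfold_evaluate(tables, labels, k=5, seed=7, ablate_chest=True)

    ids = sorted(labels)
    shuffled = [labels[p] for p in ids]
    random.Random(7).shuffle(shuffled)
    report_null = kfold_evaluate(tables, dict(zip(ids, shuffled)), k=5, seed=7)

    base = tables[Task.BASELINE_SIMPLE]
    ranking = rank_baseline_features(base, labels, k=5)
    hd_ids = [p.id for p in cohort.participants if p.group == Group.HD]
    mulms = np.array(
        [next(p.mulms for p in cohort.participants if p.id == pid) for pid in hd_ids],
        dtype=float,
    )
    X5 = base.loc[hd_ids, ranking.names]
    mis_report = loocv_mis(X5, mulms)
    null_rng = np.random.default_rng(7)
    mis_null = loocv_mis(X5, null_rng.permutation(mulms))

    return {
        "cohort": cohort,
        "labels": labels,
        "tables": tables,
        "report": report,
        "report_ablated": report_ablated,
        "report_null": report_null,
        "mis_report": mis_report,
        "mis_null": mis_null,
        "mis_features": ranking.names,
    }
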