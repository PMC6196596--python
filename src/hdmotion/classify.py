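"""HD vs. control classification: per-task RBF-SVM ensemble.

One RBF-kernel SVM is trained per task (baseline simple, baseline
complex, dual) on the top JMIM-ranked features of that task's table; the
three votes are fused by majority.  Participants too impaired to perform
the harder tasks are classified from the tasks they completed — in the
extreme, from the baseline simple classifier alone, which every
participant performs.  A two-vote split breaks toward HD: the clinical
cost of missing an early-manifest patient outweighs a false alarm.

Evaluation is stratified participant-level k-fold cross-validation with
feature ranking, feature-count tuning and hyperparameter search repeated
inside each training fold (no information from test participants reaches
selection or tuning).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_core import Group, Task, ValidationError
from .registry import CHEST_FEATURE_NAMES
from .selection import RankedFeatures, discretize_matrix, jmim_rank

logger = logging.getLogger(__name__)

HD, CONTROL = 1, 0

DEFAULT_N_GRID = (5, 10, 20, 40)
DEFAULT_C_GRID = (1.0, 10.0, 100.0)
DEFAULT_GAMMA_FACTORS = (0.1, 1.0, 10.0)


@dataclass
class TaskClassifier:
    task: Task
    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    svm: SVC
    C: float
    gamma: float

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[self.feature_names].to_numpy(dtype=float)
        return (arr - self.mean) / self.sd

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.svm.predict(self._standardize(X))


def train_task_classifier(
    X: pd.DataFrame,
    y: np.ndarray,
    ranking: RankedFeatures,
    n_top: int,
    C: float = 1.0,
    gamma: float | str = "scale",
) -> TaskClassifier:
    """Standardize the top-n ranked features on the training data and fit
    an RBF-SVM; deterministic given its inputs."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    names = ranking.top(n_top)
    arr = X[names].to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    svm = SVC(C=C, gamma=gamma, kernel="rbf")
    svm.fit((arr - mean) / sd, y)
    task = X.attrs.get("task", Task.BASELINE_SIMPLE)
    gamma_val = float(gamma) if not isinstance(gamma, str) else float(svm._gamma)
    return TaskClassifier(
        task=task, feature_names=names, mean=mean, sd=sd, svm=svm, C=C,
        gamma=gamma_val,
    )


def _inner_cv_accuracy(
    X: np.ndarray, y: np.ndarray, C: float, gamma, inner_k: int, seed: int
) -> float:
    _, counts = np.unique(y, return_counts=True)
    k_eff = min(inner_k, int(counts.min()))
    if k_eff < 2:
        # too few members of a class to cross-validate: score in-sample
        svm = SVC(C=C, gamma=gamma, kernel="rbf")
        mean, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mean) / sd
        svm.fit(Xs, y)
        return float(np.mean(svm.predict(Xs) == y))
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        mean = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        svm = SVC(C=C, gamma=gamma, kernel="rbf")
        svm.fit((X[tr] - mean) / sd, y[tr])
        correct += int(np.sum(svm.predict((X[te] - mean) / sd) == y[te]))
    return correct / len(y)


def tune_feature_count(
    X: pd.DataFrame,
    y: np.ndarray,
    ranking: RankedFeatures,
    grid: tuple[int, ...] = DEFAULT_N_GRID,
    inner_k: int = 5,
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> int:
    """Feature count maximising inner-CV accuracy; smallest n on ties."""
    if not grid:
        raise ValidationError("empty feature-count grid")
    y = np.asarray(y)
    best_n, best_acc = None, -1.0
    for n in sorted(grid):
        if n > len(ranking.ranking):
            continue
        arr = X[ranking.top(n)].to_numpy(dtype=float)
        acc = _inner_cv_accuracy(arr, y, C, gamma, inner_k, seed)
        if acc > best_acc:
            best_n, best_acc = n, acc
    if best_n is None:
        raise ValidationError("feature-count grid exceeds the ranking length")
    return best_n


def tune_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_factors: tuple[float, ...] = DEFAULT_GAMMA_FACTORS,
    inner_k: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Small inner-CV grid search around the scale heuristic for gamma."""
    var = X.var()
    gamma_scale = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    best = (C_grid[0], gamma_scale)
    best_acc = -1.0
    for C in C_grid:
        for f in gamma_factors:
            gamma = gamma_scale * f
            acc = _inner_cv_accuracy(X, y, C, gamma, inner_k, seed)
            if acc > best_acc:
                best, best_acc = (C, gamma), acc
    return best


def ensemble_predict(votes: dict[Task, int | None]) -> int:
    """Fuse per-task votes: majority of three; the baseline simple vote
    alone when it is the only one; a two-vote split goes to HD."""
    if votes.get(Task.BASELINE_SIMPLE) is None:
        raise ValidationError("baseline_simple vote is required")
    cast = [v for v in votes.values() if v is not None]
    n_hd = sum(1 for v in cast if v == HD)
    n_ctrl = len(cast) - n_hd
    if n_hd > n_ctrl:
        return HD
    if n_ctrl > n_hd:
        return CONTROL
    return HD  # split vote: favour sensitivity


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as percentages."""
    if min(tp, fn, tn, fp) < 0:
        raise ValidationError("confusion counts must be >= 0")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValidationError("empty confusion matrix")
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("a confusion-metric denominator is zero")
    return (
        100.0 * (tp + tn) / total,
        100.0 * tp / (tp + fn),
        100.0 * tn / (tn + fp),
    )


@dataclass
class EvalReport:
    seed: int
    k: int
    fold_of: dict[str, int]
    per_fold: list[dict]
    pooled: dict
    fold_averaged: dict
    per_task_pooled_accuracy: dict[str, float]
    predictions: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "k": self.k,
                    "fold_of": self.fold_of,
                    "per_fold": self.per_fold,
                    "pooled": self.pooled,
                    "fold_averaged": self.fold_averaged,
                    "per_task_pooled_accuracy": self.per_task_pooled_accuracy,
                    "predictions": self.predictions,
                },
                fh,
                indent=2,
            )


def _counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == HD) & (y_pred == HD)))
    fn = int(np.sum((y_true == HD) & (y_pred == CONTROL)))
    tn = int(np.sum((y_true == CONTROL) & (y_pred == CONTROL)))
    fp = int(np.sum((y_true == CONTROL) & (y_pred == HD)))
    return tp, fn, tn, fp


def kfold_evaluate(
    features: dict[Task, pd.DataFrame],
    labels: dict[str, Group],
    k: int = 5,
    seed: int = 0,
    n_grid: tuple[int, ...] = DEFAULT_N_GRID,
    inner_k: int = 3,
    n_bins: int = 5,
    ablate_chest: bool = False,
    tune_svm: bool = True,
) -> EvalReport:
    """Stratified participant-level k-fold evaluation of the ensemble.

    ``features`` maps each task to a DataFrame indexed by participant id
    (rows exist only for participants who performed the task).  Ranking,
    feature-count tuning and hyperparameter search run inside each
    training fold.
    """
    if Task.BASELINE_SIMPLE not in features:
        raise ValidationError("baseline_simple feature table is required")
    if ablate_chest:
        features = {
            t: df.drop(columns=[c for c in CHEST_FEATURE_NAMES if c in df.columns])
            for t, df in features.items()
        }
    pids = sorted(features[Task.BASELINE_SIMPLE].index)
    y_all = np.array([HD if Group(labels[p]) == Group.HD else CONTROL for p in pids])
    if min(np.sum(y_all == HD), np.sum(y_all == CONTROL)) < k:
        raise ValidationError(f"each class needs >= {k} members for {k}-fold CV")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    per_fold = []
    predictions: dict[str, int] = {}
    task_true: dict[Task, list[int]] = {t: [] for t in features}
    task_pred: dict[Task, list[int]] = {t: [] for t in features}

    for fold, (tr_idx, te_idx) in enumerate(skf.split(pids, y_all)):
        train_ids = {pids[i] for i in tr_idx}
        test_ids = [pids[i] for i in te_idx]
        for p in test_ids:
            fold_of[p] = fold

        classifiers: dict[Task, TaskClassifier] = {}
        for task, table in features.items():
            tr_rows = [p for p in table.index if p in train_ids]
            X_tr = table.loc[tr_rows]
            y_tr = np.array(
                [HD if Group(labels[p]) == Group.HD else CONTROL for p in tr_rows]
            )
            if len(np.unique(y_tr)) < 2:
                logger.warning("fold %d: single-class training set for %s", fold, task)
                continue
            codes = discretize_matrix(X_tr.to_numpy(dtype=float), n_bins)
            k_rank = min(max(n_grid), X_tr.shape[1])
            ranking = jmim_rank(codes, y_tr, k_rank, list(X_tr.columns))
            n_top = tune_feature_count(
                X_tr, y_tr, ranking, n_grid, inner_k, seed=seed
            )
            arr = X_tr[ranking.top(n_top)].to_numpy(dtype=float)
            if tune_svm:
                C, gamma = tune_hyperparams(arr, y_tr, inner_k=inner_k, seed=seed)
            else:
                C, gamma = 1.0, "scale"
            classifiers[task] = train_task_classifier(
                X_tr, y_tr, ranking, n_top, C=C, gamma=gamma
            )

        y_true_fold, y_pred_fold = [], []
        for p in test_ids:
            votes: dict[Task, int | None] = {}
            for task, clf in classifiers.items():
                if p in features[task].index:
                    vote = int(clf.predict(features[task].loc[[p]])[0])
                    votes[task] = vote
                    task_true[task].append(
                        HD if Group(labels[p]) == Group.HD else CONTROL
                    )
                    task_pred[task].append(vote)
                else:
                    votes[task] = None
            pred = ensemble_predict(votes)
            predictions[p] = pred
            y_true_fold.append(HD if Group(labels[p]) == Group.HD else CONTROL)
            y_pred_fold.append(pred)

        tp, fn, tn, fp = _counts(np.array(y_true_fold), np.array(y_pred_fold))
        acc = 100.0 * (tp + tn) / max(tp + fn + tn + fp, 1)
        sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
        per_fold.append(
            {"fold": fold, "tp": tp, "fn": fn, "tn": tn, "fp": fp,
             "accuracy": acc, "sensitivity": sens, "specificity": spec}
        )

    y_pred_all = np.array([predictions[p] for p in pids])
    tp, fn, tn, fp = _counts(y_all, y_pred_all)
    acc, sens, spec = confusion_metrics(tp, fn, tn, fp)
    pooled = {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
              "accuracy": acc, "sensitivity": sens, "specificity": spec}
    fold_averaged = {
        m: float(np.nanmean([f[m] for f in per_fold]))
        for m in ("accuracy", "sensitivity", "specificity")
    }
    per_task_pooled = {
        task.value: 100.0 * float(np.mean(np.array(task_pred[t]) == np.array(task_true[t])))
        for t, task in ((t, t) for t in features)
        if task_true[t]
    }
    return EvalReport(
        seed=seed, k=k, fold_of=fold_of, per_fold=per_fold, pooled=pooled,
        fold_averaged=fold_averaged, per_task_pooled_accuracy=per_task_pooled,
        predictions=predictions,
    )
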