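"""Information-theoretic feature ranking.

Continuous features are equal-width discretized, then ranked greedily by
joint mutual information maximisation (JMIM): the first feature maximises
I(f; C); each subsequent feature maximises the minimum, over the features
already selected, of the joint mutual information I((f, s); C).  Unlike
purely marginal rankings this keeps complementary features (a feature
useless alone but informative jointly still enters) while suppressing
redundant ones.

Mutual information uses the plug-in estimator in bits; ties break by
column order, which in the pipeline is the canonical registry order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_core import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RankedFeatures:
    """JMIM ranking: (name, criterion value at selection time) in order."""

    ranking: list[tuple[str, float]]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.ranking]

    def top(self, n: int) -> list[str]:
        if n < 1 or n > len(self.ranking):
            raise ValidationError(f"cannot take top {n} of {len(self.ranking)}")
        return self.names[:n]


def ewd_discretize(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-width discretization into codes 0..n_bins-1.

    The maximum value maps into the last bin; a constant feature maps to
    all zeros with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValidationError("need >= 2 values to discretize")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite value in feature to discretize")
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        logger.warning("constant feature: all codes 0")
        return np.zeros(len(values), dtype=np.int64)
    width = (hi - lo) / n_bins
    codes = np.floor((values - lo) / width).astype(np.int64)
    return np.minimum(codes, n_bins - 1)


def _joint_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValidationError("code sequences must have equal length")
    if len(a) < 2:
        raise ValidationError("need >= 2 samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(counts, (ai, bi), 1)
    return counts


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information between two code sequences, in bits."""
    counts = _joint_counts(a, b)
    n = counts.sum()
    pab = counts / n
    pa = pab.sum(axis=1, keepdims=True)
    pb = pab.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pab > 0, pab * np.log2(pab / (pa * pb)), 0.0)
    return max(float(terms.sum()), 0.0)


def pair_code(f: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Cartesian-product encoding of two code sequences."""
    f = np.asarray(f)
    s = np.asarray(s)
    if len(f) != len(s):
        raise ValidationError("code sequences must have equal length")
    k = int(s.max()) + 1 if len(s) else 1
    return f.astype(np.int64) * k + s.astype(np.int64)


def joint_mutual_information(f: np.ndarray, s: np.ndarray, c: np.ndarray) -> float:
    """I((f, s); C): mutual information of the paired variable with the class."""
    return mutual_information(pair_code(f, s), c)


def discretize_matrix(X: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """EWD per column."""
    X = np.asarray(X, dtype=float)
    return np.column_stack([ewd_discretize(X[:, j], n_bins) for j in range(X.shape[1])])


def jmim_rank(
    codes: np.ndarray,
    labels: np.ndarray,
    k: int,
    feature_names: list[str] | None = None,
) -> RankedFeatures:
    """Greedy JMIM ranking of discretized features against class labels.

    Ties break toward the earlier column so rankings are reproducible for
    a fixed feature order.
    """
    codes = np.asarray(codes)
    labels = np.asarray(labels)
    n, n_feat = codes.shape
    if len(labels) != n:
        raise ValidationError("labels length must match the feature matrix")
    if not 1 <= k <= n_feat:
        raise ValidationError(f"k={k} outside [1, {n_feat}]")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(n_feat)]

    mi = np.array([mutual_information(codes[:, j], labels) for j in range(n_feat)])
    first = int(np.argmax(mi))  # argmax takes the earliest on ties
    selected = [first]
    ranking = [(feature_names[first], float(mi[first]))]
    # running minimum over selected features of I((f, s); C)
    min_joint = np.full(n_feat, np.inf)

    while len(selected) < k:
        s = selected[-1]
        for j in range(n_feat):
            if j in selected:
                continue
            jmi = joint_mutual_information(codes[:, j], codes[:, s], labels)
            if jmi < min_joint[j]:
                min_joint[j] = jmi
        crit = min_joint.copy()
        crit[selected] = -np.inf
        nxt = int(np.argmax(crit))
        selected.append(nxt)
        ranking.append((feature_names[nxt], float(crit[nxt])))
    return RankedFeatures(ranking=ranking)
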