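"""Time-domain features per sensor.

For each axis of a tri-axial signal: mean, standard deviation, the seven
recurrence-quantification measures (recurrence rate, determinism, mean and
maximum diagonal line length, line-length entropy, laminarity, trapping
time), the largest Lyapunov exponent, sample entropy and permutation
entropy — 12 values per axis — plus the three inter-axis Pearson
correlations: 39 values per sensor.

Signals are used raw (no filtering or downsampling) so that the jerky,
irregular structure characteristic of choreic movement is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from . import _kernels
from .io_core import TriaxialSignal, ValidationError
from .registry import TIME_AXIS_FEATURES, sensor_time_feature_names

logger = logging.getLogger(__name__)


@dataclass
class RqaParams:
    """Recurrence-analysis settings.

    ``radius`` is a fraction of the signal standard deviation; the Theiler
    window excludes near-diagonal entries (temporally adjacent, trivially
    similar states) from the diagonal line statistics.
    """

    embed_dim: int = 3
    delay: int = 10  # samples; 0.1 s at 100 Hz
    radius: float = 0.2
    l_min: int = 2
    v_min: int = 2
    theiler_window: int = 10

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or self.delay < 1:
            raise ValidationError("embed_dim and delay must be >= 1")
        if self.radius <= 0:
            raise ValidationError("radius must be > 0")
        if self.l_min < 2 or self.v_min < 2:
            raise ValidationError("l_min and v_min must be >= 2")
        if self.theiler_window < 0:
            raise ValidationError("theiler_window must be >= 0")


def basic_stats(signal: np.ndarray) -> tuple[float, float]:
    """Sample mean and standard deviation (n-1 denominator)."""
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2:
        raise ValidationError("need >= 2 samples for mean/SD")
    return float(np.mean(signal)), float(np.std(signal, ddof=1))


def axis_correlations(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float, float]:
    """Pearson correlations (xy, xz, yz); a constant axis yields 0."""
    arrs = [np.asarray(a, dtype=float) for a in (x, y, z)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs) or n < 3:
        raise ValidationError("axes must have equal length >= 3")
    out = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        a, b = arrs[i], arrs[j]
        if np.std(a) == 0 or np.std(b) == 0:
            logger.warning("constant axis in correlation; using 0")
            out.append(0.0)
        else:
            out.append(float(np.corrcoef(a, b)[0, 1]))
    return tuple(out)


def delay_embed(signal: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Time-delay embedding: rows are m-dimensional reconstructed states."""
    signal = np.asarray(signal, dtype=float)
    n = len(signal) - (m - 1) * tau
    if n < 2:
        raise ValidationError("series too short for embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return signal[idx]


def recurrence_matrix(signal: np.ndarray, params: RqaParams | None = None) -> np.ndarray:
    """Thresholded distance matrix of the delay-embedded trajectory.

    ``R[i, j] = 1`` iff the Euclidean distance between embedded states is
    at most ``radius * SD(signal)``.  A zero-variance signal degenerates to
    an all-ones matrix (every state recurs), with a warning.
    """
    params = params or RqaParams()
    signal = np.asarray(signal, dtype=float)
    if len(signal) < params.embed_dim * params.delay + 10:
        raise ValidationError("series too short for recurrence analysis")
    sd = float(np.std(signal))
    if sd == 0:
        logger.warning("zero-variance signal: recurrence matrix is all ones")
    emb = delay_embed(signal, params.embed_dim, params.delay)
    eps = params.radius * sd
    dist = squareform(pdist(emb, metric="euclidean"))
    return (dist <= eps).astype(np.uint8)


def _diag_vert_histograms(
    R: np.ndarray, theiler_window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Line-length histograms of a (possibly asymmetric) binary matrix.

    Diagonal lines are enumerated over every offset ``|k| > theiler``
    (the main diagonal is always excluded); vertical lines over full
    columns.
    """
    n = R.shape[0]
    diag_hist = np.zeros(n + 1, dtype=np.int64)
    vert_hist = np.zeros(n + 1, dtype=np.int64)

    def runs_of_ones(v: np.ndarray, hist: np.ndarray) -> None:
        padded = np.concatenate(([0], v.astype(np.int8), [0]))
        changes = np.flatnonzero(np.diff(padded))
        for start, stop in zip(changes[::2], changes[1::2]):
            hist[stop - start] += 1

    for k in range(-(n - 1), n):
        if abs(k) <= theiler_window or k == 0:
            continue
        runs_of_ones(np.diagonal(R, k), diag_hist)
    for j in range(n):
        runs_of_ones(R[:, j], vert_hist)
    return diag_hist, vert_hist


def _measures_from_histograms(
    n_recurrent: int,
    n: int,
    diag_hist: np.ndarray,
    vert_hist: np.ndarray,
    l_min: int,
    v_min: int,
) -> dict[str, float]:
    lengths = np.arange(len(diag_hist))
    rr = n_recurrent / (n * n)

    diag_points_all = float(np.sum(lengths * diag_hist))
    det_sel = lengths >= l_min
    diag_points_det = float(np.sum(lengths[det_sel] * diag_hist[det_sel]))
    n_det_lines = float(np.sum(diag_hist[det_sel]))
    det = diag_points_det / diag_points_all if diag_points_all > 0 else 0.0
    l_mean = diag_points_det / n_det_lines if n_det_lines > 0 else 0.0
    qualifying = np.flatnonzero(diag_hist[l_min:])
    l_max = float(qualifying[-1] + l_min) if len(qualifying) else 0.0
    if n_det_lines > 0:
        p = diag_hist[det_sel][diag_hist[det_sel] > 0] / n_det_lines
        entr = float(-np.sum(p * np.log(p)))
    else:
        entr = 0.0

    vlengths = np.arange(len(vert_hist))
    vert_points_all = float(np.sum(vlengths * vert_hist))
    lam_sel = vlengths >= v_min
    vert_points_lam = float(np.sum(vlengths[lam_sel] * vert_hist[lam_sel]))
    n_lam_lines = float(np.sum(vert_hist[lam_sel]))
    lam = vert_points_lam / vert_points_all if vert_points_all > 0 else 0.0
    tt = vert_points_lam / n_lam_lines if n_lam_lines > 0 else 0.0

    return {
        "rr": float(rr),
        "det": float(det),
        "l_mean": float(l_mean),
        "l_max": float(l_max),
        "entr": float(entr),
        "lam": float(lam),
        "tt": float(tt),
    }


def rqa_measures(
    R: np.ndarray,
    l_min: int = 2,
    v_min: int = 2,
    theiler_window: int = 0,
) -> dict[str, float]:
    """Recurrence measures of a binary matrix.

    RR is the density of recurrent points over the whole matrix; DET,
    L_mean, L_max and ENTR are computed from diagonal lines (main diagonal
    and Theiler-window offsets excluded); LAM and TT from vertical lines
    over full columns.  Measures with no qualifying lines are 0 by
    convention.
    """
    R = np.asarray(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValidationError("recurrence matrix must be square")
    diag_hist, vert_hist = _diag_vert_histograms(R, theiler_window)
    return _measures_from_histograms(
        int(np.sum(R != 0)), R.shape[0], diag_hist, vert_hist, l_min, v_min
    )


def rqa_from_signal(
    signal: np.ndarray, params: RqaParams | None = None
) -> dict[str, float]:
    """All seven RQA measures without materialising the matrix (fast path)."""
    params = params or RqaParams()
    signal = np.asarray(signal, dtype=float)
    if len(signal) < params.embed_dim * params.delay + 10:
        raise ValidationError("series too short for recurrence analysis")
    sd = float(np.std(signal))
    emb = np.ascontiguousarray(delay_embed(signal, params.embed_dim, params.delay))
    eps = params.radius * sd
    n_rec, diag_hist, vert_hist = _kernels.rqa_counts(emb, eps, params.theiler_window)
    return _measures_from_histograms(
        int(n_rec), emb.shape[0], diag_hist, vert_hist, params.l_min, params.v_min
    )


def dominant_period(signal: np.ndarray) -> float:
    """Mean oscillation period in samples, from the dominant FFT peak."""
    signal = np.asarray(signal, dtype=float)
    spec = np.abs(np.fft.rfft(signal - np.mean(signal)))
    if len(spec) < 2 or np.all(spec[1:] == 0):
        return float(len(signal))
    k = 1 + int(np.argmax(spec[1:]))
    return len(signal) / k


def largest_lyapunov(
    signal: np.ndarray,
    m: int = 3,
    tau: int = 10,
    mean_period: int | None = None,
    fit_range: tuple[int, int] = (0, 30),
) -> float:
    """Largest Lyapunov exponent, Rosenstein estimator, in nats/sample.

    Each embedded state is paired with its nearest neighbour at temporal
    separation greater than the mean period; the slope of the mean
    log-divergence curve over ``fit_range`` (in steps) estimates the
    exponent.  Positive values indicate exponential divergence (chaos);
    periodic signals give values near zero.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < m * tau + 20:
        raise ValidationError("series too short for LE")
    if np.std(signal) == 0:
        logger.warning("zero-variance signal: LE set to 0")
        return 0.0
    if mean_period is None:
        mean_period = max(10, int(round(dominant_period(signal))))
    emb = np.ascontiguousarray(delay_embed(signal, m, tau))
    n = emb.shape[0]
    theiler = min(mean_period, max(1, n // 4))
    k0, k1 = fit_range
    curve = _kernels.nn_divergence(emb, theiler, k1)
    ks = np.arange(k0, k1 + 1)
    vals = curve[k0 : k1 + 1]
    ok = np.isfinite(vals)
    if np.sum(ok) < 2:
        raise ValidationError("series too short for LE")
    slope = float(np.polyfit(ks[ok], vals[ok], 1)[0])
    return slope


def sample_entropy(signal: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) over Chebyshev template matches.

    B counts matching m-point template pairs, A matching (m+1)-point
    pairs, self-matches excluded.  ``r`` defaults to 0.2 of the signal SD.
    If either count is zero the defined fallback ``-ln(1 / n_pairs)`` is
    returned with a warning.
    """
    signal = np.ascontiguousarray(signal, dtype=float)
    n = len(signal)
    if n < m + 2:
        raise ValidationError("series too short for sample entropy")
    if r is None:
        r = 0.2 * float(np.std(signal))
    b_count, a_count = _kernels.sampen_counts(signal, m, float(r))
    if a_count == 0 or b_count == 0:
        n_templates = n - m
        n_pairs = n_templates * (n_templates - 1) // 2
        logger.warning("no template matches; sample entropy fallback used")
        return float(math.log(n_pairs))
    return float(-math.log(a_count / b_count))


def permutation_entropy(
    signal: np.ndarray,
    order: int = 4,
    delay: int = 1,
    normalized: bool = True,
) -> float:
    """Permutation entropy of ordinal patterns.

    Ranks within each window of ``order`` points (spaced ``delay`` apart)
    form the pattern; ties rank by order of appearance.  Normalized output
    divides by ln(order!), giving [0, 1]; unnormalized output is the
    Shannon entropy in bits.
    """
    signal = np.asarray(signal, dtype=float)
    n_pat = len(signal) - (order - 1) * delay
    if n_pat < 1:
        raise ValidationError("series too short for permutation entropy")
    idx = np.arange(n_pat)[:, None] + delay * np.arange(order)[None, :]
    patterns = np.argsort(signal[idx], axis=1, kind="stable")
    # encode each pattern as an integer for counting
    base = order ** np.arange(order)
    codes = patterns @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n_pat
    h_nats = float(-np.sum(p * np.log(p)))
    if normalized:
        return h_nats / math.log(math.factorial(order))
    return h_nats / math.log(2.0)


def time_features_sensor(
    signal: TriaxialSignal,
    rqa_params: RqaParams | None = None,
    le_fit_range: tuple[int, int] = (0, 30),
) -> dict[str, float]:
    """The 39 time-domain features of one sensor, keyed by registry name."""
    params = rqa_params or RqaParams()
    out: dict[str, float] = {}
    axes = signal.axes()
    for ax, sig in axes.items():
        mean, sd = basic_stats(sig)
        rqa = rqa_from_signal(sig, params)
        if sd == 0:
            le = 0.0
            logger.warning("constant axis %s: LE set to 0", ax)
        else:
            le = largest_lyapunov(
                sig, m=params.embed_dim, tau=params.delay, fit_range=le_fit_range
            ) * signal.fs  # nats/s
        vals = {
            "mean": mean,
            "sd": sd,
            **rqa,
            "le": le,
            "sampen": sample_entropy(sig),
            "permen": permutation_entropy(sig),
        }
        for feat in TIME_AXIS_FEATURES:
            out[f"{signal.placement.value}.{ax}.{feat}"] = vals[feat]
    r_xy, r_xz, r_yz = axis_correlations(axes["x"], axes["y"], axes["z"])
    out[f"{signal.placement.value}.xy.corr_xy"] = r_xy
    out[f"{signal.placement.value}.xz.corr_xz"] = r_xz
    out[f"{signal.placement.value}.yz.corr_yz"] = r_yz
    expected = sensor_time_feature_names(signal.placement.value)
    return {name: out[name] for name in expected}
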