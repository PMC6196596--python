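import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdmotion.io_core import Placement, TriaxialSignal, ValidationError
from hdmotion.registry import sensor_time_feature_names
from hdmotion.timefeat import (
    RqaParams,
    axis_correlations,
    basic_stats,
    largest_lyapunov,
    permutation_entropy,
    recurrence_matrix,
    rqa_from_signal,
    rqa_measures,
    sample_entropy,
    time_features_sensor,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def rqa_oracle(R, l_min, v_min, theiler=0):
    """Brute-force line enumeration over an explicit binary matrix."""
    R = np.asarray(R)
    n = R.shape[0]
    diag_lines = []
    for k in range(-(n - 1), n):
        if k == 0 or abs(k) <= theiler:
            continue
        run = 0
        for i in range(n):
            j = i + k
            if not 0 <= j < n:
                continue
            if R[i, j]:
                run += 1
            else:
                if run:
                    diag_lines.append(run)
                run = 0
        if run:
            diag_lines.append(run)
    vert_lines = []
    for j in range(n):
        run = 0
        for i in range(n):
            if R[i, j]:
                run += 1
            else:
                if run:
                    vert_lines.append(run)
                run = 0
        if run:
            vert_lines.append(run)

    total = sum(diag_lines)
    det_pts = sum(l for l in diag_lines if l >= l_min)
    det_lines = [l for l in diag_lines if l >= l_min]
    lam_total = sum(vert_lines)
    lam_pts = sum(l for l in vert_lines if l >= v_min)
    lam_lines = [l for l in vert_lines if l >= v_min]
    if det_lines:
        counts = {l: det_lines.count(l) for l in set(det_lines)}
        probs = [c / len(det_lines) for c in counts.values()]
        entr = -sum(p * math.log(p) for p in probs)
    else:
        entr = 0.0
    return {
        "rr": float(np.sum(R != 0)) / n**2,
        "det": det_pts / total if total else 0.0,
        "l_mean": det_pts / len(det_lines) if det_lines else 0.0,
        "l_max": float(max(det_lines)) if det_lines else 0.0,
        "entr": entr,
        "lam": lam_pts / lam_total if lam_total else 0.0,
        "tt": lam_pts / len(lam_lines) if lam_lines else 0.0,
    }


def sampen_oracle(sig, m, r):
    """O(n^2) template counting, pure Python."""
    n = len(sig)
    b = a = 0
    for i in range(n - m - 1):
        for j in range(i + 1, n - m):
            if max(abs(sig[i + k] - sig[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(sig[i + m] - sig[j + m]) <= r:
                    a += 1
    return -math.log(a / b)


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sig,expected",
    [
        ([1, 1, 1, 1], (1.0, 0.0)),
        ([0, 2], (1.0, math.sqrt(2))),
        ([1, 2, 3, 4, 5], (3.0, math.sqrt(2.5))),
    ],
)
def test_basic_stats(sig, expected):
    mean, sd = basic_stats(np.array(sig, dtype=float))
    assert mean == pytest.approx(expected[0])
    assert sd == pytest.approx(expected[1])


def test_axis_correlations():
    x = np.array([1.0, 2.0, 3.0])
    assert axis_correlations(x, x, -x) == pytest.approx((1.0, -1.0, -1.0))
    r_xy, _, _ = axis_correlations(x, np.array([1.0, 3.0, 2.0]), x)
    assert r_xy == pytest.approx(0.5)


def test_constant_axis_correlation_is_zero():
    x = np.array([1.0, 2.0, 3.0])
    const = np.ones(3)
    assert axis_correlations(x, const, x)[0] == 0.0


# ---------------------------------------------------------------------------
# recurrence analysis
# ---------------------------------------------------------------------------


class TestRecurrence:
    def test_constant_signal_all_ones(self):
        R = recurrence_matrix(np.ones(40), RqaParams(embed_dim=1, delay=1))
        assert np.all(R == 1)
        assert rqa_measures(R)["rr"] == 1.0

    def test_alternating_signal_rr_half(self):
        sig = np.array([0.0, 1.0] * 8)
        R = recurrence_matrix(sig, RqaParams(embed_dim=1, delay=1, radius=1.0))
        assert rqa_measures(R)["rr"] == 0.5
        # recurrences join equal values only (eps = SD = 0.5 < 1)
        assert R[0, 2] == 1 and R[0, 1] == 0

    def test_identity_matrix(self):
        n = 7
        m = rqa_measures(np.eye(n, dtype=int))
        assert m["rr"] == pytest.approx(1 / n)
        assert m["det"] == 0.0

    def test_all_ones_line_lengths(self):
        m = rqa_measures(np.ones((5, 5), dtype=int), l_min=2)
        oracle = rqa_oracle(np.ones((5, 5), dtype=int), 2, 2)
        assert m == pytest.approx(oracle)
        assert m["l_max"] == 4.0  # longest off-diagonal line

    def test_sinusoid_is_deterministic_structure(self):
        t = np.linspace(0, 10, 500, endpoint=False)
        sig = np.sin(2 * np.pi * t)
        params = RqaParams(embed_dim=2, delay=12, radius=0.3, theiler_window=12)
        R = recurrence_matrix(sig, params)
        m = rqa_measures(R, theiler_window=params.theiler_window)
        assert m["det"] >= 0.9
        assert m == pytest.approx(rqa_oracle(R, 2, 2, theiler=12))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        R = (rng.random((20, 20)) < 0.35).astype(int)
        theiler = seed % 3
        got = rqa_measures(R, l_min=2, v_min=2, theiler_window=theiler)
        assert got == pytest.approx(rqa_oracle(R, 2, 2, theiler=theiler))

    @pytest.mark.parametrize("seed", range(4))
    def test_fast_path_equals_matrix_path(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.standard_normal(160)
        params = RqaParams(embed_dim=3, delay=4, radius=0.5, theiler_window=4)
        fast = rqa_from_signal(sig, params)
        R = recurrence_matrix(sig, params)
        slow = rqa_measures(R, params.l_min, params.v_min, params.theiler_window)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_bounds_invariants(self, rng):
        sig = rng.standard_normal(200)
        m = rqa_from_signal(sig, RqaParams())
        assert 0 <= m["rr"] <= 1 and 0 <= m["det"] <= 1 and 0 <= m["lam"] <= 1
        assert m["entr"] >= 0
        if m["det"] > 0:
            assert m["l_max"] >= m["l_mean"] >= 2


# ---------------------------------------------------------------------------
# Lyapunov exponent
# ---------------------------------------------------------------------------


class TestLyapunov:
    @staticmethod
    def _logistic(n=2000, x0=0.3):
        xs = np.empty(n + 100)
        x = x0
        for i in range(n + 100):
            x = 4.0 * x * (1.0 - x)
            xs[i] = x
        return xs[100:]

    def test_logistic_map_near_ln2(self):
        le = largest_lyapunov(self._logistic(), m=2, tau=1, mean_period=10,
                              fit_range=(0, 4))
        assert abs(le - math.log(2)) < 0.1

    def test_sinusoid_near_zero(self):
        t = np.arange(2000) / 100
        le = largest_lyapunov(np.sin(2 * np.pi * t), m=3, tau=10, fit_range=(0, 30))
        assert le <= 0.05

    def test_deterministic(self, rng):
        sig = rng.standard_normal(800)
        assert largest_lyapunov(sig) == largest_lyapunov(sig)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            largest_lyapunov(np.arange(20.0))


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------


class TestSampleEntropy:
    def test_constant_signal_zero(self):
        assert sample_entropy(np.ones(50)) == 0.0

    def test_strict_alternation_zero(self):
        sig = np.array([1.0, 2.0] * 10)
        assert sample_entropy(sig, m=2, r=0.5 * np.std(sig)) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.random(300)
        r = 0.2 * float(np.std(sig))
        assert sample_entropy(sig, m=2, r=r) == pytest.approx(
            sampen_oracle(sig, 2, r), abs=1e-12
        )


class TestPermutationEntropy:
    def test_monotone_sequence_zero(self):
        assert permutation_entropy(np.arange(100.0)) == 0.0

    def test_hand_enumerated_pairs(self):
        # 6 consecutive pairs: 4 ascents, 2 descents -> H2(1/3) bits
        sig = np.array([4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0])
        h = permutation_entropy(sig, order=2, normalized=False)
        assert h == pytest.approx(0.9182958340544896)

    def test_uniform_noise_near_one(self):
        rng = np.random.default_rng(5)
        assert permutation_entropy(rng.random(100000)) > 0.95

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.standard_normal(200)
        base = permutation_entropy(sig)
        for f in (np.exp, np.tanh, lambda v: 3 * v + 2, np.cbrt):
            assert permutation_entropy(f(sig)) == pytest.approx(base)


# ---------------------------------------------------------------------------
# sensor assembly
# ---------------------------------------------------------------------------


class TestSensorAssembly:
    def test_name_set_matches_registry(self, healthy_session):
        sensor = healthy_session.sensors[Placement.NON_DOMINANT_WRIST]
        feats = time_features_sensor(sensor)
        assert list(feats) == sensor_time_feature_names("non_dominant_wrist")
        assert all(np.isfinite(v) for v in feats.values())

    def test_zero_signal_conventions(self):
        zeros = np.zeros(500)
        sig = TriaxialSignal(Placement.CHEST, 100.0, zeros, zeros, zeros)
        feats = time_features_sensor(sig)
        assert feats["chest.x.mean"] == 0.0
        assert feats["chest.x.sd"] == 0.0
        assert feats["chest.x.rr"] == 1.0
        assert feats["chest.xy.corr_xy"] == 0.0

    def test_sign_flip_invariance_except_mean(self, rng):
        n = 600
        data = 0.5 * rng.standard_normal((3, n))
        sig = TriaxialSignal(Placement.CHEST, 100.0, *data)
        flipped = TriaxialSignal(Placement.CHEST, 100.0, *(-data))
        a = time_features_sensor(sig)
        b = time_features_sensor(flipped)
        for name in a:
            if name.endswith(".mean"):
                assert b[name] == pytest.approx(-a[name])
            else:
                assert b[name] == pytest.approx(a[name], rel=1e-9), name

    def test_severity_raises_permutation_entropy(self, healthy_session, severe_session):
        h = time_features_sensor(healthy_session.sensors[Placement.NON_DOMINANT_WRIST])
        s = time_features_sensor(severe_session.sensors[Placement.NON_DOMINANT_WRIST])
        assert s["non_dominant_wrist.x.permen"] > h["non_dominant_wrist.x.permen"]
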