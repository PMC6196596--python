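import math

import numpy as np
import pytest
import pywt

from hdmotion.freqfeat import (
    StftSpectrogram,
    component_entropy,
    freq_features_sensor,
    lowpass,
    spectral_energy,
    stft_component_means,
    stft_rect,
    wpd_features,
)
from hdmotion.io_core import Placement, TriaxialSignal, ValidationError
from hdmotion.registry import sensor_freq_feature_names


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


class TestLowpass:
    def test_dc_preserved(self):
        sig = np.full(1000, 0.7)
        np.testing.assert_allclose(lowpass(sig), sig, atol=1e-9)

    def test_stopband_attenuation(self):
        t = np.arange(1000) / 100
        out = lowpass(np.sin(2 * np.pi * 40 * t))
        assert rms(out[100:-100]) < 0.05

    def test_passband_flat(self):
        t = np.arange(1000) / 100
        sig = np.sin(2 * np.pi * 1.0 * t)
        assert rms(lowpass(sig)[100:-100]) == pytest.approx(
            rms(sig[100:-100]), rel=0.02
        )

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            lowpass(np.zeros(500), cutoff_hz=50.0)


class TestStft:
    def test_bin_centered_sinusoid(self):
        t = np.arange(400) / 100
        spec = stft_rect(np.sin(2 * np.pi * 1.0 * t))
        assert spec.magnitudes.shape == (3, 101)
        peaks = np.argmax(spec.magnitudes, axis=1)
        assert np.all(peaks == 2)  # 1 Hz / 0.5 Hz per bin
        assert spec.magnitudes[:, 2] == pytest.approx(100.0)  # N/2

    def test_zero_signal(self):
        spec = stft_rect(np.zeros(600))
        assert np.all(spec.magnitudes == 0)

    def test_parseval_per_window(self, rng):
        sig = rng.standard_normal(700)
        spec = stft_rect(sig)
        weights = np.full(101, 2.0)
        weights[0] = weights[-1] = 1.0
        for w in range(spec.magnitudes.shape[0]):
            frame = sig[100 * w : 100 * w + 200]
            lhs = float((spec.magnitudes[w] ** 2) @ weights) / 200.0
            assert lhs == pytest.approx(float(np.sum(frame**2)), rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError, match="2 s"):
            stft_rect(np.zeros(150))


class TestSpectralFeatures:
    def test_unit_sinusoid_energy_half(self):
        t = np.arange(800) / 100
        spec = stft_rect(np.sin(2 * np.pi * 1.0 * t))
        assert spectral_energy(spec) == pytest.approx(0.5, rel=1e-9)

    def test_energy_homogeneity(self, rng):
        sig = rng.standard_normal(500)
        e1 = spectral_energy(stft_rect(sig))
        e2 = spectral_energy(stft_rect(2 * sig))
        assert e2 == pytest.approx(4 * e1, rel=1e-9)

    def test_single_bin_entropy_zero(self):
        t = np.arange(400) / 100
        spec = stft_rect(np.sin(2 * np.pi * 1.0 * t))
        assert component_entropy(spec) == pytest.approx(0.0, abs=1e-6)

    def test_flat_spectrum_entropy_ln_b(self):
        mags = np.ones((4, 101))
        # B = 100 movement bins: the DC bin is excluded from the distribution
        assert component_entropy(StftSpectrogram(mags)) == pytest.approx(math.log(100))

    def test_white_noise_entropy_matches_exponential_periodogram(self):
        # the periodogram of white noise has i.i.d. exponential bin powers,
        # for which E[entropy] = ln B - (1 - gamma); the flat-spectrum
        # limit ln B is approached only after spectrum averaging
        rng = np.random.default_rng(3)
        spec = stft_rect(rng.standard_normal(10000))
        expected = math.log(100) - (1.0 - np.euler_gamma)
        assert component_entropy(spec) == pytest.approx(expected, rel=0.02)

    def test_component_means_pick_out_tone(self):
        t = np.arange(600) / 100
        c = stft_component_means(stft_rect(np.sin(2 * np.pi * 1.0 * t)))
        assert c[1] == pytest.approx(100.0)
        assert max(c[0], *c[2:]) < 1e-9

    def test_dc_excluded_from_component_means(self):
        c = stft_component_means(stft_rect(np.full(500, 0.9)))
        assert c == pytest.approx((0.0,) * 5, abs=1e-9)


def wpd_oracle_impulse(n=128, pos=40, wavelet="db2", levels=5):
    """Direct convolve-and-decimate filter bank on an impulse."""
    w = pywt.Wavelet(wavelet)
    flen = len(w.dec_lo)
    pad = flen - 1

    def step(x, filt):
        ext = np.r_[x[pad - 1 :: -1], x, x[: -pad - 1 : -1]]
        return np.convolve(ext, filt)[flen::2][: (len(x) + pad) // 2]

    x = np.zeros(n)
    x[pos] = 1.0
    feats = []
    approx = x
    for _ in range(levels):
        detail = step(approx, w.dec_hi)
        approx = step(approx, w.dec_lo)
        feats.append(float(np.sum(np.abs(detail))))
    feats.append(float(np.sum(np.abs(approx))))
    return tuple(feats)


class TestWpd:
    def test_zero_signal(self):
        assert wpd_features(np.zeros(128)) == (0.0,) * 6

    def test_impulse_matches_filter_bank_oracle(self):
        x = np.zeros(128)
        x[40] = 1.0
        assert wpd_features(x) == pytest.approx(wpd_oracle_impulse(), abs=1e-10)

    def test_homogeneity(self, rng):
        sig = rng.standard_normal(300)
        f1 = np.array(wpd_features(sig))
        f3 = np.array(wpd_features(3 * sig))
        np.testing.assert_allclose(f3, 3 * f1, rtol=1e-9)

    def test_energy_conservation_periodized_packet_tree(self, rng):
        # the db2 filter bank is orthogonal: with periodization the full
        # level-5 packet tree preserves signal energy
        sig = rng.standard_normal(256)
        wp = pywt.WaveletPacket(sig, "db2", mode="periodization", maxlevel=5)
        total = sum(
            float(np.sum(node.data**2)) for node in wp.get_level(5, "natural")
        )
        assert total == pytest.approx(float(np.sum(sig**2)), rel=1e-8)


class TestFreqAssembly:
    def test_zero_signal_gives_39_zeros(self):
        zeros = np.zeros(500)
        sig = TriaxialSignal(Placement.CHEST, 100.0, zeros, zeros, zeros)
        feats = freq_features_sensor(sig)
        assert list(feats) == sensor_freq_feature_names("chest")
        assert all(v == 0.0 for v in feats.values())

    def test_offset_invariance_except_energy(self, rng):
        n = 800
        data = 0.3 * rng.standard_normal((3, n))
        sig = TriaxialSignal(Placement.CHEST, 100.0, *data)
        shifted = TriaxialSignal(Placement.CHEST, 100.0, *(data + 0.5))
        a, b = freq_features_sensor(sig), freq_features_sensor(shifted)
        for name in a:
            feat = name.rsplit(".", 1)[1]
            if feat.startswith("stft_c") or feat == "component_entropy":
                assert b[name] == pytest.approx(a[name], rel=1e-6, abs=1e-9), name
        assert b["chest.x.spectral_energy"] > a["chest.x.spectral_energy"]

    def test_healthy_fundamental_in_low_components(self, healthy_session):
        sensor = healthy_session.sensors[Placement.NON_DOMINANT_WRIST]
        feats = freq_features_sensor(sensor)
        c = [feats[f"non_dominant_wrist.x.stft_c{i}"] for i in range(1, 6)]
        # the ~0.6 Hz transfer-cycle fundamental falls in components 1-2
        assert np.argmax(c) in (0, 1)

    def test_all_finite_across_seeds(self):
        from hdmotion.io_core import Group, Task
        from hdmotion.synth import simulate_session

        for seed in range(10):
            rng = np.random.default_rng(seed)
            rec = simulate_session(Group.HD, 12.0, Task.DUAL, rng)
            for sensor in rec.sensors.values():
                feats = freq_features_sensor(sensor)
                assert all(np.isfinite(v) for v in feats.values())
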