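"""Feature extractors against naive reference implementations and their
analytic limits."""

import math

import numpy as np
import pytest

from epifly.features import (SUBBAND_FEATURE_NAMES, approximate_entropy,
                             assemble_feature_vector, higuchi_fd, hurst_rs,
                             katz_fd, shannon_entropy, spectral_features,
                             subband_features, time_domain_features)
from epifly.synthetic import SyntheticEEGConfig, generate_record
from epifly.tqwt import QWaveletParams, analyze


# ---------------------------------------------------------------- oracles
def apen_bruteforce(x, m, r):
    """O(N^2) double-loop ApEn with self-matches and Chebyshev distance."""
    x = np.asarray(x, float)
    n = len(x)

    def phi(mm):
        vecs = np.array([x[i:i + mm] for i in range(n - mm + 1)])
        total = 0.0
        for i in range(len(vecs)):
            count = 0
            for j in range(len(vecs)):
                if np.max(np.abs(vecs[i] - vecs[j])) <= r:
                    count += 1
            total += math.log(count / len(vecs))
        return total / len(vecs)

    return phi(m) - phi(m + 1)


def higuchi_bruteforce(x, kmax):
    x = np.asarray(x, float)
    n = len(x)
    ln_k, ln_l = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            s = sum(abs(x[idx[i]] - x[idx[i - 1]]) for i in range(1, len(idx)))
            lm.append(s * (n - 1) / ((len(idx) - 1) * k) / k)
        ln_k.append(math.log(k))
        ln_l.append(math.log(sum(lm) / len(lm)))
    slope = np.polyfit(ln_k, ln_l, 1)[0]
    return -slope


def katz_bruteforce(x):
    x = np.asarray(x, float)
    length = sum(math.sqrt(1 + (x[i + 1] - x[i]) ** 2) for i in range(len(x) - 1))
    d = max(math.sqrt(i ** 2 + (x[i] - x[0]) ** 2) for i in range(1, len(x)))
    n = len(x) - 1
    return math.log10(n) / (math.log10(n) + math.log10(d / length))


def hurst_bruteforce(x):
    x = np.asarray(x, float)
    n = len(x)
    pts = []
    size = 8
    while size <= n // 2:
        rs = []
        for start in range(0, (n // size) * size, size):
            w = x[start:start + size]
            dev = w - w.mean()
            cum = np.cumsum(dev)
            r = cum.max() - cum.min()
            s = w.std(ddof=1)
            if s > 0:
                rs.append(r / s)
        if rs:
            pts.append((math.log(size), math.log(np.mean(rs))))
        size *= 2
    return np.polyfit([p[0] for p in pts], [p[1] for p in pts], 1)[0]


def spectral_bruteforce(x, fs):
    mag = np.abs(np.fft.rfft(np.asarray(x, float)))
    q = np.arange(len(mag))
    sc = np.sum(q * mag) / np.sum(mag)
    ss = math.sqrt(np.sum((q - sc) ** 2 * mag) / np.sum(mag))
    nz = mag[mag > 0]
    sf = math.exp(np.mean(np.log(nz))) / np.mean(nz)
    f = q * fs / len(x)
    ssi = np.polyfit(f, mag, 1)[0]
    p = mag / mag.sum()
    p = p[p > 0]
    pse = -np.sum(p * np.log(p))
    return sc, ss, sf, ssi, pse


# ------------------------------------------------------ oracle agreement
class TestOracleAgreement:
    def test_apen_matches_bruteforce(self, rng):
        for _ in range(5):
            x = rng.standard_normal(96)
            r = 0.2 * x.std(ddof=1)
            assert approximate_entropy(x, 2, r) == pytest.approx(
                apen_bruteforce(x, 2, r), abs=1e-12)

    def test_apen_periodic_sequence(self):
        x = np.array([0.0, 1.0] * 32)
        assert approximate_entropy(x, 2, 0.1) == pytest.approx(
            apen_bruteforce(x, 2, 0.1), abs=1e-12)

    @pytest.mark.parametrize("n", [64, 256])
    def test_higuchi_matches_bruteforce(self, rng, n):
        for _ in range(5):
            x = rng.standard_normal(n)
            assert higuchi_fd(x, 10) == pytest.approx(higuchi_bruteforce(x, 10), abs=1e-9)

    def test_katz_matches_bruteforce(self, rng):
        for _ in range(10):
            x = rng.standard_normal(65)
            assert katz_fd(x) == pytest.approx(katz_bruteforce(x), abs=1e-12)

    def test_katz_zigzag(self):
        x = np.array([0.0, 1.0] * 33)[:65]
        assert katz_fd(x) == pytest.approx(katz_bruteforce(x), abs=1e-12)

    def test_hurst_matches_bruteforce(self, rng):
        for _ in range(5):
            x = rng.standard_normal(256)
            assert hurst_rs(x)[0] == pytest.approx(hurst_bruteforce(x), abs=1e-9)

    def test_spectral_matches_bruteforce(self, rng):
        for _ in range(10):
            x = rng.standard_normal(256)
            sp = spectral_features(x, fs=173.61)
            sc, ss, sf, ssi, pse = spectral_bruteforce(x, 173.61)
            assert sp.centroid == pytest.approx(sc, abs=1e-9)
            assert sp.spread == pytest.approx(ss, abs=1e-9)
            assert sp.flatness == pytest.approx(sf, abs=1e-9)
            assert sp.slope == pytest.approx(ssi, abs=1e-9)
            assert sp.entropy == pytest.approx(pse, abs=1e-9)

    def test_time_domain_hand_example(self):
        x = np.array([1.0, 2, 3, 4, 5] * 4)  # length >= 16, same per-window stats
        td = time_domain_features(np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5,
                                            1, 2, 3, 4, 5, 1, 2, 3, 4, 5]))
        assert td.mean == pytest.approx(3.0)
        five = np.array([1.0, 2, 3, 4, 5])
        assert np.var(five, ddof=1) == pytest.approx(2.5)
        assert np.std(five, ddof=1) == pytest.approx(math.sqrt(2.5))
        assert td.var == pytest.approx(td.std ** 2, rel=1e-12)


# ------------------------------------------------------- analytic limits
class TestAnalyticLimits:
    def test_constant_signal_degenerate_but_valid(self):
        td = time_domain_features(np.full(64, 3.7))
        assert td.std == pytest.approx(0.0, abs=1e-12)
        assert td.shannon_entropy == 0 and td.approx_entropy == 0

    def test_apen_constant_zero(self):
        assert approximate_entropy(np.full(64, 2.0), 2, 0.5) == pytest.approx(0.0)

    def test_apen_noise_exceeds_sine(self):
        wins = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            noise = g.standard_normal(512)
            t = np.arange(512)
            sine = np.sin(2 * np.pi * 5 * t / 512)
            sine *= noise.std(ddof=1) / sine.std(ddof=1)
            a_n = approximate_entropy(noise, 2, 0.2 * noise.std(ddof=1))
            a_s = approximate_entropy(sine, 2, 0.2 * sine.std(ddof=1))
            wins += a_n > a_s
        assert wins == 20

    def test_uniform_histogram_is_four_bits(self):
        # one sample per bin centre: 16 equally filled bins
        x = (np.arange(16) + 0.5) / 16
        assert shannon_entropy(x, 16) == pytest.approx(4.0)

    def test_higuchi_line_is_one(self):
        assert higuchi_fd(np.arange(1000.0), 10) == pytest.approx(1.0, abs=0.02)

    def test_higuchi_white_noise_near_two(self):
        vals = [higuchi_fd(np.random.default_rng(s).standard_normal(1000), 10)
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_higuchi_scale_invariant(self, rng):
        x = rng.standard_normal(300)
        assert higuchi_fd(3.7 * x, 10) == pytest.approx(higuchi_fd(x, 10), rel=1e-12)

    def test_hurst_white_noise_near_half(self):
        vals = [hurst_rs(np.random.default_rng(s).standard_normal(4096))[0]
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_hurst_integrated_noise_persistent(self):
        vals = [hurst_rs(np.cumsum(np.random.default_rng(s).standard_normal(4096)))[0]
                for s in range(5)]
        assert np.mean(vals) > 0.85

    def test_hurst_affine_invariant(self, rng):
        x = rng.standard_normal(512)
        assert hurst_rs(2.0 * x + 5.0)[0] == pytest.approx(hurst_rs(x)[0], rel=1e-9)

    def test_hurst_constant_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            hurst_rs(np.full(128, 1.0))

    def test_katz_line_exactly_one(self):
        assert katz_fd(-2.5 * np.arange(100.0)) == pytest.approx(1.0, abs=1e-12)

    def test_katz_above_one_for_nonmonotone(self, rng):
        for _ in range(10):
            assert katz_fd(rng.standard_normal(64)) > 1.0

    def test_flat_spectrum_flatness_one(self):
        x = np.zeros(64)
        x[0] = 1.0  # unit impulse: perfectly flat magnitude spectrum
        sp = spectral_features(x, fs=100.0)
        assert sp.flatness == pytest.approx(1.0, abs=1e-12)
        assert sp.entropy == pytest.approx(np.log(33), abs=1e-12)

    def test_pure_tone_point_mass(self):
        n, q0 = 128, 10
        x = np.cos(2 * np.pi * q0 * np.arange(n) / n)
        sp = spectral_features(x, fs=100.0)
        assert sp.centroid == pytest.approx(q0, abs=1e-9)
        assert sp.spread == pytest.approx(0.0, abs=1e-4)
        assert sp.entropy == pytest.approx(0.0, abs=1e-9)

    def test_linear_spectrum_slope_closed_form(self):
        # build a signal whose magnitude spectrum decreases linearly in f
        n, fs = 128, 64.0
        m = n // 2 + 1
        mag = np.linspace(10.0, 1.0, m)
        x = np.fft.irfft(mag.astype(complex), n=n)
        sp = spectral_features(x, fs)
        f = np.arange(m) * fs / n
        expected = np.polyfit(f, np.abs(np.fft.rfft(x)), 1)[0]
        assert sp.slope == pytest.approx(expected, abs=1e-9)
        assert sp.slope < 0

    def test_all_zero_signal_flagged_degenerate(self):
        sp = spectral_features(np.zeros(64), fs=100.0)
        assert sp.degenerate
        assert (sp.centroid, sp.spread, sp.flatness, sp.slope, sp.entropy) == (0,) * 5

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.arange(64.0), 2, r=0.0)
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(64.0), kmax=1)
        with pytest.raises(ValueError):
            katz_fd(np.ones(10))
        with pytest.raises(ValueError):
            time_domain_features(np.arange(4.0))


# ----------------------------------------------------------- fused vector
@pytest.fixture(scope="module")
def record():
    return generate_record(SyntheticEEGConfig("seizure_free", rng_seed=3))


class TestFeatureVector:

    def test_length_and_schema(self, record):
        decomp = analyze(record, QWaveletParams(1, 3, 3))
        textures = {"energy": 0.5, "contrast": 1.0, "correlation": 0.0,
                    "homogeneity": 0.7}
        vec = assemble_feature_vector(decomp, textures, fs=173.61)
        assert len(vec.names) == 13 * 4 + 4 == 56
        assert len(set(vec.names)) == 56
        assert vec.names.count("sb2_ApEn") == 1
        assert vec.names.count("glcm_contrast") == 1
        assert vec.names[-4:] == ("glcm_energy", "glcm_contrast",
                                  "glcm_correlation", "glcm_homogeneity")

    def test_deterministic_bit_for_bit(self, record):
        decomp = analyze(record, QWaveletParams(1, 3, 3))
        tex = {"energy": 0.5, "contrast": 1.0, "correlation": 0.0, "homogeneity": 0.7}
        v1 = assemble_feature_vector(decomp, tex, fs=173.61)
        v2 = assemble_feature_vector(decomp, tex, fs=173.61)
        assert np.array_equal(v1.values, v2.values)

    def test_non_finite_feature_named_in_error(self, record):
        decomp = analyze(record, QWaveletParams(1, 3, 3))
        tex = {"energy": np.nan, "contrast": 1.0, "correlation": 0.0,
               "homogeneity": 0.7}
        with pytest.raises(ValueError, match="glcm_energy"):
            assemble_feature_vector(decomp, tex, fs=173.61)

    def test_feature_order_matches_canonical_names(self, record):
        feats = subband_features(record, fs=173.61)
        assert tuple(feats.keys()) == SUBBAND_FEATURE_NAMES

    def test_ictal_records_larger_std_lower_apen(self):
        """The separability the classifier relies on: seizure records are
        stronger (STD) and more regular (ApEn) than healthy background."""
        std_h, std_i, apen_h, apen_i = [], [], [], []
        for seed in range(10):
            h = generate_record(SyntheticEEGConfig("healthy", rng_seed=seed))
            ic = generate_record(SyntheticEEGConfig("ictal", rng_seed=seed))
            td_h = time_domain_features(h)
            td_i = time_domain_features(ic)
            std_h.append(td_h.std)
            std_i.append(td_i.std)
            apen_h.append(td_h.approx_entropy)
            apen_i.append(td_i.approx_entropy)
        assert np.mean(std_i) > np.mean(std_h)
        assert np.mean(apen_i) < np.mean(apen_h)
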