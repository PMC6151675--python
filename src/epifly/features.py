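"""Per-subband signal features and the fused feature vector.

Three feature groups are computed from every TQWT subband:

* time-domain statistics — mean, standard deviation, variance (sample,
  N−1 divisor), Shannon entropy of the 16-bin amplitude histogram (bits)
  and approximate entropy (nats);
* power-spectrum descriptors on the one-sided magnitude spectrum —
  spectral centroid, spread, flatness, slope and entropy;
* chaotic / fractal measures — Higuchi fractal dimension, rescaled-range
  Hurst exponent and Katz fractal dimension.

:func:`assemble_feature_vector` fuses the 13 per-subband features over the
J+1 subbands with the four whole-record GLCM textures into one named,
deterministically ordered vector (length 13·(J+1) + 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .tqwt import SubbandDecomposition

__all__ = [
    "TimeDomainFeatures",
    "SpectralFeatures",
    "ChaoticFeatures",
    "FeatureVector",
    "time_domain_features",
    "approximate_entropy",
    "spectral_features",
    "higuchi_fd",
    "hurst_rs",
    "katz_fd",
    "assemble_feature_vector",
    "SUBBAND_FEATURE_NAMES",
    "TEXTURE_NAMES",
]

SUBBAND_FEATURE_NAMES = (
    "mean", "STD", "var", "H", "ApEn",
    "SC", "SS", "SF", "SSI", "PSE",
    "HFD", "Hurst", "KATZ",
)
TEXTURE_NAMES = ("energy", "contrast", "correlation", "homogeneity")


@dataclass(frozen=True)
class TimeDomainFeatures:
    mean: float
    std: float
    var: float
    shannon_entropy: float  # bits
    approx_entropy: float   # nats


@dataclass(frozen=True)
class SpectralFeatures:
    centroid: float   # bin index units
    spread: float     # bin index units
    flatness: float   # in [0, 1]
    slope: float      # magnitude per Hz
    entropy: float    # nats
    degenerate: bool = False


@dataclass(frozen=True)
class ChaoticFeatures:
    higuchi_fd: float
    hurst: float
    katz_fd: float


@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log2(p)))


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) = φ^m(r) − φ^(m+1)(r), in nats.

    φ^m(r) averages ln of the fraction of length-m templates within
    Chebyshev distance r of each template (self-matches included, the
    original regularity-statistic convention).

    Parameters
    ----------
    x : array-like
        Input sequence, length >= m + 2.
    m : int
        Embedding dimension.
    r : float
        Match tolerance, > 0 (same units as ``x``).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {n}")
    if r is None or r <= 0:
        raise ValueError(f"tolerance r must be > 0, got {r!r}")

    def phi(mm: int) -> float:
        nvec = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        tree = cKDTree(emb)
        counts = tree.query_ball_point(emb, r=r, p=np.inf, return_length=True)
        return float(np.mean(np.log(counts / nvec)))

    return phi(m) - phi(m + 1)


def time_domain_features(x, n_bins: int = 16, m: int = 2, r_frac: float = 0.2) -> TimeDomainFeatures:
    """Mean, sample STD/variance, histogram Shannon entropy and ApEn.

    ApEn uses tolerance ``r = r_frac * STD``; a constant signal yields
    entropy 0 and ApEn 0 (degenerate but valid).
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 16:
        raise ValueError(f"need at least 16 samples, got {len(x)}")
    mu = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    std = float(np.sqrt(var))
    h = shannon_entropy(x, n_bins)
    apen = 0.0 if std == 0.0 else approximate_entropy(x, m=m, r=r_frac * std)
    return TimeDomainFeatures(mean=mu, std=std, var=var, shannon_entropy=h, approx_entropy=apen)


def spectral_features(x, fs: float) -> SpectralFeatures:
    """Spectral centroid, spread, flatness, slope and entropy.

    Computed on the one-sided magnitude spectrum |Y(q)|, q = 0..M−1
    (DC included).  Centroid and spread are in bin-index units; the slope
    is the OLS regression slope of |Y| against physical frequency
    f_q = q·fs/N; flatness is the geometric/arithmetic mean ratio over
    nonzero bins; the entropy is Shannon entropy (nats) of the
    magnitude-normalised spectrum.  An all-zero signal is flagged
    degenerate with every descriptor 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 16:
        raise ValueError(f"need at least 16 samples, got {len(x)}")
    mag = np.abs(np.fft.rfft(x))
    total = float(np.sum(mag))
    if total == 0.0:
        return SpectralFeatures(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    q = np.arange(len(mag), dtype=float)
    w = mag / total
    sc = float(np.sum(q * w))
    ss = float(np.sqrt(np.sum((q - sc) ** 2 * w)))
    nz = mag[mag > 0]
    sf = float(np.exp(np.mean(np.log(nz))) / np.mean(nz))
    f = q * fs / len(x)
    fbar = float(np.mean(f))
    denom = float(np.sum((f - fbar) ** 2))
    ssi = float(np.sum((f - fbar) * (mag - np.mean(mag))) / denom) if denom > 0 else 0.0
    p = w[w > 0]
    pse = float(-np.sum(p * np.log(p)))
    return SpectralFeatures(centroid=sc, spread=ss, flatness=sf, slope=ssi, entropy=pse)


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension: minus the log-log slope of the mean curve
    length L(k) against the time lag k (k = 1..kmax).  ~1 for smooth curves,
    approaching 2 for uncorrelated noise."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if kmax < 2:
        raise ValueError(f"kmax must be >= 2, got {kmax}")
    if n < 2 * kmax:
        raise ValueError(f"need at least 2*kmax={2 * kmax} samples, got {n}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    lk = np.maximum(lk, np.finfo(float).tiny)
    k = np.log(np.arange(1, kmax + 1))
    slope = np.polyfit(k, np.log(lk), 1)[0]
    return float(-slope)


def hurst_rs(x) -> tuple[float, float]:
    """Rescaled-range Hurst exponent.

    For dyadic window sizes n = 8, 16, ..., N/2 the range of the cumulative
    mean-adjusted series divided by the sample SD, R(n)/S(n), is averaged
    over non-overlapping windows; the Hurst exponent is the OLS slope of
    ln(R/S) against ln n.  Returns ``(hurst, c)`` where c is the fitted
    scaling constant (exp of the intercept).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 64:
        raise ValueError(f"need at least 64 samples, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: rescaled range degenerate (S = 0)")
    sizes = []
    size = 8
    while size <= n // 2:
        sizes.append(size)
        size *= 2
    log_n, log_rs = [], []
    for size in sizes:
        k = n // size
        blocks = x[: k * size].reshape(k, size)
        dev = blocks - blocks.mean(axis=1, keepdims=True)
        cum = np.cumsum(dev, axis=1)
        r = cum.max(axis=1) - cum.min(axis=1)
        s = blocks.std(axis=1, ddof=1)
        ok = s > 0
        if not np.any(ok):
            continue
        log_n.append(np.log(size))
        log_rs.append(np.log(np.mean(r[ok] / s[ok])))
    if len(log_n) < 2:
        raise ValueError("too few usable window sizes for the R/S fit")
    slope, intercept = np.polyfit(log_n, log_rs, 1)
    return float(slope), float(np.exp(intercept))


def katz_fd(x) -> float:
    """Katz fractal dimension log(n)/(log(n) + log(d/L)).

    L is the Euclidean length of the polyline through (i, x_i) with unit
    abscissa steps, d the maximum Euclidean distance from the first point,
    n = N−1 the step count.  Exactly 1 for a straight line; > 1 otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    dy = np.diff(x)
    length = float(np.sum(np.sqrt(1.0 + dy ** 2)))
    i = np.arange(1, n, dtype=float)
    d = float(np.max(np.sqrt(i ** 2 + (x[1:] - x[0]) ** 2)))
    if np.ptp(x) == 0:
        raise ValueError("constant signal: Katz dimension degenerate (d/L trivial)")
    steps = n - 1
    return float(np.log10(steps) / (np.log10(steps) + np.log10(d / length)))


def subband_features(x, fs: float, n_bins: int = 16, m: int = 2,
                     r_frac: float = 0.2, kmax: int = 10) -> dict[str, float]:
    """The 13 named features of one subband, in canonical order."""
    td = time_domain_features(x, n_bins=n_bins, m=m, r_frac=r_frac)
    sp = spectral_features(x, fs)
    hurst, _ = hurst_rs(x)
    return {
        "mean": td.mean, "STD": td.std, "var": td.var,
        "H": td.shannon_entropy, "ApEn": td.approx_entropy,
        "SC": sp.centroid, "SS": sp.spread, "SF": sp.flatness,
        "SSI": sp.slope, "PSE": sp.entropy,
        "HFD": higuchi_fd(x, kmax=kmax), "Hurst": hurst, "KATZ": katz_fd(x),
    }


def assemble_feature_vector(decomp: SubbandDecomposition, textures, fs: float,
                            n_bins: int = 16, m: int = 2, r_frac: float = 0.2,
                            kmax: int = 10) -> FeatureVector:
    """Fuse per-subband features with whole-record GLCM textures.

    Subbands are ordered stage-1 high-pass first, final low-pass last
    (names ``sb1_mean`` .. ``sb{J+1}_KATZ``), followed by
    ``glcm_energy``, ``glcm_contrast``, ``glcm_correlation``,
    ``glcm_homogeneity``.

    Parameters
    ----------
    textures : mapping or 4-sequence
        The GLCM textures of the record (see :mod:`epifly.glcm`).
    fs : float
        Sampling rate in Hz of the original record (subband descriptors
        keep bin-index units; the spectral slope uses each subband's own
        effective rate implicitly through its length).
    """
    names: list[str] = []
    values: list[float] = []
    for k, band in enumerate(decomp.subbands, start=1):
        feats = subband_features(band, fs, n_bins=n_bins, m=m, r_frac=r_frac, kmax=kmax)
        for fname in SUBBAND_FEATURE_NAMES:
            val = feats[fname]
            if not np.isfinite(val):
                raise ValueError(f"non-finite feature {fname!r} in subband {k}")
            names.append(f"sb{k}_{fname}")
            values.append(float(val))
    if hasattr(textures, "keys"):
        tex = [float(textures[t]) for t in TEXTURE_NAMES]
    else:
        tex = [float(t) for t in textures]
        if len(tex) != 4:
            raise ValueError("expected four GLCM textures")
    for tname, val in zip(TEXTURE_NAMES, tex):
        if not np.isfinite(val):
            raise ValueError(f"non-finite texture glcm_{tname}")
        names.append(f"glcm_{tname}")
        values.append(val)
    return FeatureVector(names=tuple(names), values=np.asarray(values, dtype=float))
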