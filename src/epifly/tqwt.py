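"""Tunable Q-factor wavelet transform (TQWT).

An oversampled two-channel filter bank iterated on its low-pass branch.
The bank is parameterised by the Q-factor ``Q`` (number of oscillations of
the wavelet), the oversampling (redundancy) rate ``r`` and the number of
stages ``J``.  Each stage splits the current low-pass band, sampled at rate
``fs``, into a low-pass band at rate ``alpha*fs`` and a high-pass band at
rate ``beta*fs``, where the scaling factors derive from (Q, r) as

    beta = 2 / (Q + 1),        alpha = 1 - beta / r.

Because alpha and beta are in general irrational, the filter bank is
realised in the frequency domain: each band is taken to its unitary DFT,
multiplied by the low-/high-pass frequency responses, and resampled by
spectral truncation to the scaled band length.  The two responses are power
complementary on the shared transition band, which makes the transform
perfectly invertible; :func:`synthesize` performs that inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QWaveletParams",
    "SubbandDecomposition",
    "derive_filter_scales",
    "theta_response",
    "lowpass_response",
    "highpass_response",
    "max_stages",
    "analyze",
    "synthesize",
]

#: final low-pass bands shorter than this cannot sample the transition band
MIN_LOWPASS_LEN = 8


def derive_filter_scales(q_factor: float, oversampling: float) -> tuple[float, float]:
    """Convert (Q, r) into the filter-bank scaling factors (alpha, beta).

    Inverts ``r = beta/(1-alpha)``, ``Q = (2-beta)/beta``:
    ``beta = 2/(Q+1)`` and ``alpha = 1 - beta/r``.

    Parameters
    ----------
    q_factor : float
        Q-factor, >= 1.  Q = 1 gives the least oscillatory wavelet.
    oversampling : float
        Redundancy rate r, > 1.

    Returns
    -------
    (alpha, beta) : tuple of float
        Low-pass scale in (0, 1) and high-pass scale in (0, 1].
    """
    if not np.isfinite(q_factor) or q_factor < 1:
        raise ValueError(f"q_factor must be >= 1, got {q_factor!r}")
    if not np.isfinite(oversampling) or oversampling <= 1:
        raise ValueError(f"oversampling must be > 1, got {oversampling!r}")
    beta = 2.0 / (q_factor + 1.0)
    alpha = 1.0 - beta / oversampling
    return alpha, beta


@dataclass(frozen=True)
class QWaveletParams:
    """TQWT parameter set: (Q, r, J) plus the derived filter scales."""

    q_factor: float
    oversampling: float
    stages: int
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if int(self.stages) != self.stages or self.stages < 1:
            raise ValueError(f"stages must be an integer >= 1, got {self.stages!r}")
        alpha, beta = derive_filter_scales(self.q_factor, self.oversampling)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        # oversampled bank: transition band of positive width
        if not self.alpha + self.beta > 1:
            raise ValueError("filter scales must satisfy alpha + beta > 1")


def theta_response(omega):
    """Transition-band prototype θ(ω) = ((1+cos ω)/2)·(2−cos ω)^0.5 on [0, π].

    θ decreases monotonically from θ(0)=1 to θ(π)=0 and is power
    complementary with its mirror: θ(ω)² + θ(π−ω)² = 1.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < -1e-12) or np.any(w > np.pi + 1e-12):
        raise ValueError("omega must lie in [0, pi]")
    w = np.clip(w, 0.0, np.pi)
    c = np.cos(w)
    return 0.5 * (1.0 + c) * np.sqrt(2.0 - c)


def _check_scales(alpha: float, beta: float) -> None:
    if not (0 < alpha < 1 and 0 < beta <= 1):
        raise ValueError(f"invalid filter scales alpha={alpha}, beta={beta}")
    if not alpha + beta > 1:
        raise ValueError("filter scales must satisfy alpha + beta > 1")


def lowpass_response(omega, alpha: float, beta: float):
    """Low-pass frequency response H0(ω) on [0, π].

    1 on the passband ω < (1−β)π, θ((ω+(β−1)π)/(α+β−1)) on the transition
    band, 0 on the stopband ω >= απ.
    """
    _check_scales(alpha, beta)
    w = np.asarray(omega, dtype=float)
    if np.any(w < -1e-12) or np.any(w > np.pi + 1e-12):
        raise ValueError("omega must lie in [0, pi]")
    w = np.clip(w, 0.0, np.pi)
    lo = (1.0 - beta) * np.pi
    hi = alpha * np.pi
    out = np.zeros_like(w)
    out[w < lo] = 1.0
    trans = (w >= lo) & (w < hi)
    out[trans] = theta_response((w[trans] + (beta - 1.0) * np.pi) / (alpha + beta - 1.0))
    return out if out.ndim else float(out)


def highpass_response(omega, alpha: float, beta: float):
    """High-pass frequency response H1(ω) on [0, π].

    0 on ω < (1−β)π, θ((απ−ω)/(α+β−1)) on the transition band, 1 on ω >= απ.
    """
    _check_scales(alpha, beta)
    w = np.asarray(omega, dtype=float)
    if np.any(w < -1e-12) or np.any(w > np.pi + 1e-12):
        raise ValueError("omega must lie in [0, pi]")
    w = np.clip(w, 0.0, np.pi)
    lo = (1.0 - beta) * np.pi
    hi = alpha * np.pi
    out = np.zeros_like(w)
    out[w >= hi] = 1.0
    trans = (w >= lo) & (w < hi)
    out[trans] = theta_response((hi - w[trans]) / (alpha + beta - 1.0))
    return out if out.ndim else float(out)


def _round_even(x: float) -> int:
    # half-away-from-zero rounding to the nearest even band length
    return 2 * int(np.floor(x / 2.0 + 0.5))


def _stage_lengths(n: int, alpha: float, beta: float) -> tuple[int, int]:
    """Band lengths (N0 low, N1 high) produced by one stage on a length-n band."""
    return _round_even(alpha * n), _round_even(beta * n)


def max_stages(n_samples: int, alpha: float, beta: float) -> int:
    """Largest stage count J such that the final low-pass band keeps at least
    ``MIN_LOWPASS_LEN`` samples (and every stage strictly shrinks the band)."""
    _check_scales(alpha, beta)
    if n_samples % 2 or n_samples < 2 * MIN_LOWPASS_LEN:
        raise ValueError(
            f"signal too short for decomposition: need an even length >= "
            f"{2 * MIN_LOWPASS_LEN}, got {n_samples}"
        )
    j = 0
    n = n_samples
    while True:
        n0, n1 = _stage_lengths(n, alpha, beta)
        # transition band needs a non-negative sample count and the
        # recursion must make progress
        if n0 < MIN_LOWPASS_LEN or n0 >= n or n1 < 2 or n0 + n1 < n + 2:
            return j
        j += 1
        n = n0


@dataclass
class SubbandDecomposition:
    """J high-pass coefficient sequences (stage 1 = highest frequency) plus
    the final low-pass sequence, with the metadata needed to invert."""

    highpass: list[np.ndarray]
    lowpass_final: np.ndarray
    original_length: int
    params: QWaveletParams
    #: True when a trailing zero was appended to make the input even
    padded: bool = False

    @property
    def subbands(self) -> list[np.ndarray]:
        """All J+1 bands, high-pass stages first, final low-pass last."""
        return [*self.highpass, self.lowpass_final]

    def __len__(self) -> int:
        return len(self.highpass) + 1


def _band_filters(n: int, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """H0/H1 sampled on the non-negative frequency bins 0..n/2 of a length-n
    band, with the transition band placed so it ends exactly on the low-pass
    subband Nyquist bin n0/2 (integer-breakpoint sampling of the responses)."""
    half = n // 2
    p = (n - n1) // 2            # passband bins 1..p
    t = (n0 + n1 - n) // 2 - 1   # interior transition samples
    h0 = np.zeros(half + 1)
    h1 = np.zeros(half + 1)
    h0[: p + 1] = 1.0
    h1[n0 // 2:] = 1.0
    if t > 0:
        v = np.arange(1, t + 1) * np.pi / (t + 1)
        h0[p + 1: p + 1 + t] = theta_response(v)
        h1[p + 1: p + 1 + t] = theta_response(np.pi - v)
    return h0, h1


def _afb(spectrum: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage on a full complex spectrum of even length n."""
    n = len(spectrum)
    p = (n - n1) // 2
    h0, h1 = _band_filters(n, n0, n1)
    v0 = np.zeros(n0, dtype=complex)
    v1 = np.zeros(n1, dtype=complex)

    k = np.arange(1, n0 // 2)
    v0[0] = spectrum[0] * h0[0]
    v0[k] = spectrum[k] * h0[k]
    v0[n0 - k] = spectrum[n - k] * h0[k]
    # low-pass subband Nyquist: response is 0 there by construction

    j = np.arange(1, n1 // 2)
    v1[j] = spectrum[p + j] * h1[p + j]
    v1[n1 - j] = spectrum[n - p - j] * h1[p + j]
    v1[n1 // 2] = spectrum[n // 2] * h1[n // 2]
    return v0, v1


def _sfb(v0: np.ndarray, v1: np.ndarray, n: int) -> np.ndarray:
    """One synthesis stage: rebuild the parent spectrum of even length n."""
    n0, n1 = len(v0), len(v1)
    p = (n - n1) // 2
    h0, h1 = _band_filters(n, n0, n1)
    x = np.zeros(n, dtype=complex)

    k = np.arange(1, n0 // 2)
    x[0] = v0[0] * h0[0]
    x[k] += v0[k] * h0[k]
    x[n - k] += v0[n0 - k] * h0[k]

    j = np.arange(1, n1 // 2)
    x[p + j] += v1[j] * h1[p + j]
    x[n - p - j] += v1[n1 - j] * h1[p + j]
    x[n // 2] += v1[n1 // 2] * h1[n // 2]
    return x


def _to_real(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    scale = max(1.0, float(np.max(np.abs(x))) if x.size else 1.0)
    resid = float(np.max(np.abs(x.imag))) if x.size else 0.0
    if resid > tol * scale:
        raise AssertionError(f"spectrum lost conjugate symmetry (imag residual {resid:g})")
    return np.ascontiguousarray(x.real)


def analyze(signal, params: QWaveletParams) -> SubbandDecomposition:
    """Decompose a real signal into J high-pass subbands and a final low-pass.

    Odd-length inputs are zero-padded by one trailing sample (recorded in the
    decomposition and stripped again by :func:`synthesize`).
    """
    x = np.asarray(signal, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    original_length = len(x)
    padded = False
    if len(x) % 2:
        x = np.concatenate([x, [0.0]])
        padded = True
    if len(x) < 2 * MIN_LOWPASS_LEN:
        raise ValueError(
            f"signal too short: need >= {2 * MIN_LOWPASS_LEN} samples, got {original_length}"
        )
    jmax = max_stages(len(x), params.alpha, params.beta)
    if params.stages > jmax:
        raise ValueError(
            f"J={params.stages} exceeds J_max={jmax} for length {original_length} "
            f"(final low-pass band must keep >= {MIN_LOWPASS_LEN} samples)"
        )

    spectrum = np.fft.fft(x, norm="ortho")
    highpass = []
    for _ in range(params.stages):
        n = len(spectrum)
        n0, n1 = _stage_lengths(n, params.alpha, params.beta)
        spectrum, v1 = _afb(spectrum, n0, n1)
        highpass.append(_to_real(np.fft.ifft(v1, norm="ortho")))
    lowpass = _to_real(np.fft.ifft(spectrum, norm="ortho"))
    return SubbandDecomposition(
        highpass=highpass,
        lowpass_final=lowpass,
        original_length=original_length,
        params=params,
        padded=padded,
    )


def synthesize(decomp: SubbandDecomposition) -> np.ndarray:
    """Invert :func:`analyze`; exact up to floating-point rounding."""
    params = decomp.params
    n_work = decomp.original_length + (1 if decomp.padded else 0)
    # replay the length recurrence to validate the stored bands
    lengths = [n_work]
    for _ in range(params.stages):
        n0, n1 = _stage_lengths(lengths[-1], params.alpha, params.beta)
        lengths.append(n0)
    expected_high = [
        _stage_lengths(lengths[i], params.alpha, params.beta)[1]
        for i in range(params.stages)
    ]
    if len(decomp.highpass) != params.stages:
        raise ValueError("decomposition does not hold J high-pass bands")
    for i, (band, want) in enumerate(zip(decomp.highpass, expected_high), start=1):
        if len(band) != want:
            raise ValueError(f"high-pass band {i} has length {len(band)}, expected {want}")
    if len(decomp.lowpass_final) != lengths[-1]:
        raise ValueError(
            f"final low-pass band has length {len(decomp.lowpass_final)}, "
            f"expected {lengths[-1]}"
        )

    spectrum = np.fft.fft(np.asarray(decomp.lowpass_final, dtype=float), norm="ortho")
    for stage in range(params.stages - 1, -1, -1):
        v1 = np.fft.fft(np.asarray(decomp.highpass[stage], dtype=float), norm="ortho")
        spectrum = _sfb(spectrum, v1, lengths[stage])
    x = _to_real(np.fft.ifft(spectrum, norm="ortho"))
    return x[: decomp.original_length]
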