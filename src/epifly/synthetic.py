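"""Synthetic single-channel EEG records emulating the Bonn benchmark layout.

Three record classes are emulated, each 4097 samples at 173.61 Hz
(~23.6 s) by default:

* ``healthy`` — band-limited (0.5–30 Hz) coloured Gaussian noise with a
  mild 1/f^0.7 spectral rolloff, unit standard deviation;
* ``seizure_free`` — interictal: the same background plus sparse
  low-amplitude transient spikes;
* ``ictal`` — a dominant rhythmic 3–7 Hz oscillation with harmonics over
  coloured noise, ten times the healthy amplitude scale (the subband
  amplitude contrast seizure recordings show against background EEG).

Also provides the planted-feature Gaussian tables used to exercise the
wrapper feature selector: two balanced classes whose informative columns
differ by a standardised mean shift while the rest are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyntheticEEGConfig", "PlantedTableConfig", "generate_record",
           "generate_dataset", "generate_planted_table", "CLASSES"]

CLASSES = ("healthy", "seizure_free", "ictal")

#: ictal records are this much stronger than the healthy amplitude scale
ICTAL_AMPLITUDE_RATIO = 10.0


@dataclass(frozen=True)
class SyntheticEEGConfig:
    class_label: str
    fs: float = 173.61
    n_samples: int = 4097
    amplitude_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}, got {self.class_label!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_samples < 256:
            raise ValueError("n_samples must be >= 256")


@dataclass(frozen=True)
class PlantedTableConfig:
    n_rows: int = 200
    n_features: int = 50
    n_informative: int = 3
    effect_size: float = 3.0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_informative < self.n_features:
            raise ValueError("need n_informative < n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _colored_noise(rng: np.random.Generator, n: int, fs: float,
                   band: tuple[float, float] = (0.5, 30.0),
                   rolloff: float = 0.7) -> np.ndarray:
    """Band-limited Gaussian noise with a 1/f^rolloff amplitude envelope,
    normalised to unit standard deviation."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    amp[inband] = freqs[inband] ** -rolloff
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float, f0: float,
                width: float = 0.4) -> np.ndarray:
    """Quasi-periodic rhythm: unit-SD Gaussian process concentrated in a
    narrow band around f0.  Frequency-domain synthesis keeps the spectrum
    strictly band-limited (no rectangular-window leakage), the way a
    waxing-and-waning seizure rhythm looks over a whole record."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.exp(-0.5 * ((freqs - f0) / width) ** 2)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_record(config: SyntheticEEGConfig) -> np.ndarray:
    """One synthetic EEG record; deterministic per (class, seed)."""
    rng = np.random.default_rng(config.rng_seed)
    n, fs = config.n_samples, config.fs
    t = np.arange(n) / fs
    background = _colored_noise(rng, n, fs)

    if config.class_label == "healthy":
        x = background
    elif config.class_label == "seizure_free":
        x = background.copy()
        n_spikes = rng.integers(4, 9)
        width = max(3, int(0.02 * fs))
        kernel = np.exp(-0.5 * ((np.arange(-3 * width, 3 * width + 1)) / width) ** 2)
        for _ in range(n_spikes):
            pos = rng.integers(3 * width, n - 3 * width)
            amp = rng.uniform(2.0, 3.5) * rng.choice([-1.0, 1.0])
            x[pos - 3 * width: pos + 3 * width + 1] += amp * kernel
        x = x / x.std()
    else:  # ictal: dominant low-frequency rhythm + harmonics + noise
        f0 = rng.uniform(3.0, 7.0)
        x = (_narrowband(rng, n, fs, f0)
             + 0.4 * _narrowband(rng, n, fs, 2 * f0)
             + 0.2 * _narrowband(rng, n, fs, 3 * f0)
             + 0.35 * background)
        x = x / x.std() * ICTAL_AMPLITUDE_RATIO

    return x * config.amplitude_scale


def generate_dataset(n_per_class: int, classes=("seizure_free", "ictal"),
                     rng_seed: int = 0, fs: float = 173.61,
                     n_samples: int = 4097):
    """Balanced records + string labels; per-record seeds spawn from the
    master seed so records are pairwise distinct yet fully reproducible."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    for c in classes:
        if c not in CLASSES:
            raise ValueError(f"unknown class {c!r}")
    child_seeds = np.random.SeedSequence(rng_seed).generate_state(n_per_class * len(classes))
    records, labels = [], []
    i = 0
    for label in classes:
        for _ in range(n_per_class):
            cfg = SyntheticEEGConfig(class_label=label, fs=fs, n_samples=n_samples,
                                     rng_seed=int(child_seeds[i]))
            records.append(generate_record(cfg))
            labels.append(label)
            i += 1
    return records, labels


def generate_planted_table(config: PlantedTableConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Two balanced Gaussian classes; the first ``n_informative`` columns are
    shifted by ``effect_size`` in class 1, the rest are i.i.d. N(0,1) noise.

    Returns ``(table, labels)`` with columns ``f0 .. f{D-1}`` and labels in
    {0, 1}.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, d = config.n_rows, config.n_features
    labels = np.zeros(n, dtype=int)
    labels[n // 2:] = 1
    x = rng.standard_normal((n, d))
    x[labels == 1, : config.n_informative] += config.effect_size
    table = pd.DataFrame(x, columns=[f"f{i}" for i in range(d)])
    return table, labels
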