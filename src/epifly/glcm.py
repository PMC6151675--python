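"""Gray-level co-occurrence texture of an EEG record treated as an image.

The record is min–max quantised to L gray levels and reshaped row-major to
the most-square w×h grid (w = floor(√N), trailing samples dropped).  The
GLCM counts co-occurring level pairs at a fixed pixel displacement; after
normalisation the four classic Haralick textures are read off:

    energy      = ΣΣ C(i,j)²
    contrast    = ΣΣ (i−j)² C(i,j)
    correlation = ΣΣ (i−μ_i)(j−μ_j) C(i,j) / (σ_i σ_j)
    homogeneity = ΣΣ C(i,j) / (1 + (i−j)²)

Defaults: L = 8 levels, displacement (0, 1), symmetric counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrayImage", "GLCMatrix", "signal_to_image", "compute_glcm",
           "glcm_textures", "record_textures"]


@dataclass(frozen=True)
class GrayImage:
    pixels: np.ndarray  # 2-D int array, values in [0, levels-1]
    levels: int

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
            raise ValueError("image must be at least 2x2")
        if p.min() < 0 or p.max() >= self.levels:
            raise ValueError("pixel levels out of range")


@dataclass(frozen=True)
class GLCMatrix:
    entries: np.ndarray       # L x L, normalised to sum 1
    offset: tuple[int, int]   # (row, col) displacement


def signal_to_image(x, levels: int = 8) -> GrayImage:
    """Quantise a signal to gray levels and reshape to a near-square image.

    Min–max quantisation maps the minimum to level 0 and the maximum to
    level L−1 (monotone; a constant signal maps to all-zero levels).
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError(f"need at least 4 samples, got {len(x)}")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        q = np.zeros(len(x), dtype=np.intp)
    else:
        q = np.floor((x - lo) / (hi - lo) * levels).astype(np.intp)
        q = np.minimum(q, levels - 1)  # the max itself maps to L-1
    w = int(np.floor(np.sqrt(len(x))))
    h = len(x) // w
    return GrayImage(pixels=q[: w * h].reshape(h, w), levels=levels)


def compute_glcm(img: GrayImage, offset: tuple[int, int] = (0, 1),
                 symmetric: bool = True) -> GLCMatrix:
    """Normalised co-occurrence matrix at one pixel displacement."""
    dr, dc = offset
    h, w = img.pixels.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} does not fit inside a {h}x{w} image")
    a = img.pixels
    rows = slice(max(0, -dr), min(h, h - dr))
    cols = slice(max(0, -dc), min(w, w - dc))
    src = a[rows, cols].ravel()
    dst = a[max(0, dr): min(h, h + dr), max(0, dc): min(w, w + dc)].ravel()
    counts = np.zeros((img.levels, img.levels))
    np.add.at(counts, (src, dst), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no pixel pairs at this offset")
    return GLCMatrix(entries=counts / total, offset=(dr, dc))


def glcm_textures(c: GLCMatrix) -> dict[str, float]:
    """Energy, contrast, correlation and homogeneity of a normalised GLCM.

    A single-level image has zero marginal SDs; its correlation is defined
    as 1 (perfectly degenerate).
    """
    p = c.entries
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    energy = float(np.sum(p ** 2))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    homogeneity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mi, mj = float(np.sum(i * pi)), float(np.sum(i * pj))
    si = float(np.sqrt(np.sum((i - mi) ** 2 * pi)))
    sj = float(np.sqrt(np.sum((i - mj) ** 2 * pj)))
    if si * sj == 0.0:
        correlation = 1.0
    else:
        correlation = float(np.sum((ii - mi) * (jj - mj) * p) / (si * sj))
    return {"energy": energy, "contrast": contrast,
            "correlation": correlation, "homogeneity": homogeneity}


def record_textures(x, levels: int = 8, offset: tuple[int, int] = (0, 1),
                    symmetric: bool = True) -> dict[str, float]:
    """Whole-record GLCM textures with the default Haralick setup."""
    return glcm_textures(compute_glcm(signal_to_image(x, levels), offset, symmetric))
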