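"""Shi-Tomasi minimum-eigenvalue corner detection and the
``n_interest_corners`` count feature.

At each pixel the structure tensor (Harris matrix)

    M = sum_window w * [Ix^2  IxIy; IxIy  Iy^2]

is formed from central-difference gradients under a Gaussian window.  Its two
eigenvalues characterize the local geometry: both small = flat, one large =
edge, both large = corner.  The Shi-Tomasi score is R_ST = min(l1, l2); the
Harris score R_H = l1*l2 - k*(l1+l2)^2 is provided for completeness but the
count feature uses R_ST.  Pixels with R_ST above a fraction (quality level)
of the image maximum survive, followed by greedy non-maximum suppression with
a minimum-distance exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EIG_TOL = 1e-12


def harris_score(l1: float, l2: float, k: float = 0.04) -> float:
    """Harris corner response ``l1*l2 - k*(l1+l2)^2`` from tensor eigenvalues."""
    if l1 < -_EIG_TOL or l2 < -_EIG_TOL:
        raise ValueError(f"structure-tensor eigenvalues must be >= 0, got {l1}, {l2}")
    return l1 * l2 - k * (l1 + l2) ** 2


def shi_tomasi_score(l1: float, l2: float) -> float:
    """Shi-Tomasi (minimum eigenvalue) corner response ``min(l1, l2)``."""
    if l1 < -_EIG_TOL or l2 < -_EIG_TOL:
        raise ValueError(f"structure-tensor eigenvalues must be >= 0, got {l1}, {l2}")
    return min(l1, l2)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


@dataclass
class WindowParams:
    size: int = 5
    sigma: float | None = 1.0  # None = uniform (box) weighting


def structure_tensor(image: np.ndarray, window: WindowParams | None = None) -> np.ndarray:
    """Per-pixel windowed second-moment matrices.

    Returns an (h, w, 3) array of the unique entries (Jxx, Jxy, Jyy).
    Gradients are central differences with replicated borders.
    """
    window = window or WindowParams()
    image = np.asarray(image, dtype=float)
    if window.size % 2 == 0 or window.size < 3:
        raise ValueError(f"window size must be odd >= 3, got {window.size}")
    if window.size > min(image.shape):
        raise ValueError(f"window {window.size} exceeds image {image.shape}")
    iy, ix = np.gradient(image)
    if window.sigma is None:
        kernel = np.full((window.size, window.size), 1.0 / window.size**2)
    else:
        kernel = _gaussian_kernel(window.size, window.sigma)
    smooth = lambda a: ndimage.convolve(a, kernel, mode="nearest")
    jxx = smooth(ix * ix)
    jxy = smooth(ix * iy)
    jyy = smooth(iy * iy)
    return np.stack([jxx, jxy, jyy], axis=-1)


def tensor_eigenvalues(field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigenvalues of the 2x2 symmetric tensors, (larger, smaller)."""
    jxx, jxy, jyy = field[..., 0], field[..., 1], field[..., 2]
    half_trace = (jxx + jyy) / 2.0
    disc = np.sqrt(((jxx - jyy) / 2.0) ** 2 + jxy**2)
    return half_trace + disc, half_trace - disc


def min_eigenvalue_map(image: np.ndarray, window: WindowParams | None = None) -> np.ndarray:
    _, lmin = tensor_eigenvalues(structure_tensor(image, window))
    # tensors are PSD up to rounding; clamp tiny negatives
    return np.maximum(lmin, 0.0)


@dataclass
class CornerParams:
    quality_level: float = 0.01
    min_distance: int = 3
    window: WindowParams | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.quality_level <= 1.0):
            raise ValueError(f"quality_level must be in (0, 1], got {self.quality_level}")
        if self.min_distance < 1:
            raise ValueError(f"min_distance must be >= 1, got {self.min_distance}")


def detect_corners(
    image: np.ndarray, params: CornerParams | None = None
) -> list[tuple[int, int, float]]:
    """Detect corners as ``(row, col, score)`` tuples.

    Pixels with R_ST >= quality_level * max(R_ST) are candidates; greedy
    suppression keeps the strongest first (ties by row, then col) and drops
    any candidate within Euclidean ``min_distance`` of a kept corner.
    """
    params = params or CornerParams()
    scores = min_eigenvalue_map(image, params.window)
    peak = float(scores.max())
    if peak <= 0.0:
        return []
    threshold = params.quality_level * peak
    cand = np.argwhere(scores >= threshold)
    cand_scores = scores[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -cand_scores))
    kept: list[tuple[int, int, float]] = []
    kept_rc = np.empty((0, 2))
    d2 = float(params.min_distance) ** 2
    for idx in order:
        r, c = cand[idx]
        if kept_rc.size and np.min((kept_rc[:, 0] - r) ** 2 + (kept_rc[:, 1] - c) ** 2) < d2:
            continue
        kept.append((int(r), int(c), float(cand_scores[idx])))
        kept_rc = np.vstack([kept_rc, [r, c]])
    kept.sort(key=lambda p: (p[0], p[1]))
    return kept


def count_corners(image: np.ndarray, params: CornerParams | None = None) -> int:
    """The ``n_interest_corners`` feature: number of detected corners."""
    return len(detect_corners(image, params))
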