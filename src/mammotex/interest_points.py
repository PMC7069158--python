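"""Blob-like interest-point detection (detection stage of SURF) and the
``n_interest_points`` count feature.

The detector approximates the scale-normalized determinant of the Hessian
with box filters evaluated in constant time on an integral image:

    det(H_approx) = Dxx * Dyy - (w * Dxy)^2,   w = 0.9,

where Dxx, Dyy, Dxy are second-derivative box filters of odd size L
(9, 15, 21, ... following the standard octave progression), each normalized
so the kernel's Frobenius norm is the same at every scale.  Interest points are strict maxima of the response
over a 3x3x3 neighborhood in (scale, row, col) within each octave that exceed
a response threshold.  Only the detection stage is implemented: the pipeline
uses the number of detected points, not descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

LOBE_WEIGHT = 0.9  # relative weight correcting the box approximation of Dxy


@dataclass
class IntegralImage:
    """Cumulative-sum table with a leading row/column of zeros, so the sum of
    ``I[r0:r1, c0:c1]`` is ``S[r1,c1] - S[r0,c1] - S[r1,c0] + S[r0,c0]``."""

    table: np.ndarray

    @property
    def height(self) -> int:
        return self.table.shape[0] - 1

    @property
    def width(self) -> int:
        return self.table.shape[1] - 1

    def box_sum(self, r0: int, c0: int, r1: int, c1: int) -> float:
        s = self.table
        return float(s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0])


def integral_image(image: np.ndarray) -> IntegralImage:
    image = np.asarray(image, dtype=float)
    table = np.zeros((image.shape[0] + 1, image.shape[1] + 1))
    np.cumsum(np.cumsum(image, axis=0), axis=1, out=table[1:, 1:])
    return IntegralImage(table)


def octave_filter_sizes(n_octaves: int = 3, scales_per_octave: int = 4) -> list[list[int]]:
    """Filter-size ladder: octave o uses sizes 9 + 6*2^o * {0,1,2,...}
    starting from the standard base (9, 15, 27, ... per octave)."""
    octaves = []
    for o in range(n_octaves):
        step = 6 * 2**o
        base = 9 if o == 0 else octaves[-1][1]
        octaves.append([base + i * step for i in range(scales_per_octave)])
    return octaves


def _shifted(table: np.ndarray, rows: np.ndarray, cols: np.ndarray,
             dr: int, dc: int) -> np.ndarray:
    return table[np.ix_(rows + dr, cols + dc)]


def _box_map(table: np.ndarray, rows: np.ndarray, cols: np.ndarray,
             r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
    """Box sums over rows [center+r0, center+r1) x cols [center+c0, center+c1)
    for every center in ``rows x cols``, via 4 shifted lookups."""
    return (
        _shifted(table, rows, cols, r1, c1)
        - _shifted(table, rows, cols, r0, c1)
        - _shifted(table, rows, cols, r1, c0)
        + _shifted(table, rows, cols, r0, c0)
    )


def hessian_response(ii: IntegralImage, filter_size: int) -> np.ndarray:
    """Approximate det(Hessian) response map for one box-filter size.

    Border pixels whose L x L footprint overflows the image are 0.
    """
    L = int(filter_size)
    if L < 9 or L % 3 != 0 or L % 2 == 0:
        raise ValueError(f"filter size must be an odd multiple of 3, >= 9; got {L}")
    h, w = ii.height, ii.width
    if L > h or L > w:
        raise ValueError(f"filter size {L} exceeds image {h}x{w}: empty response map")
    lobe = L // 3
    margin = L // 2
    rows = np.arange(margin, h - margin)
    cols = np.arange(margin, w - margin)
    out = np.zeros((h, w))
    if rows.size == 0 or cols.size == 0:
        return out
    t = ii.table
    half_w = lobe - 1  # half-extent of the (2*lobe-1)-wide cross-section

    # Dyy: three stacked boxes (l tall, 2l-1 wide), weights +1, -2, +1,
    # computed as (whole column) - 3 * (middle lobe).
    half_l = (lobe - 1) // 2  # lobe is odd for odd multiples of 3
    whole = _box_map(t, rows, cols, -margin, -half_w, margin + 1, half_w + 1)
    middle = _box_map(t, rows, cols, -half_l, -half_w, half_l + 1, half_w + 1)
    dyy = whole - 3.0 * middle
    # Dxx is the transpose layout.
    whole = _box_map(t, rows, cols, -half_w, -margin, half_w + 1, margin + 1)
    middle = _box_map(t, rows, cols, -half_w, -half_l, half_w + 1, half_l + 1)
    dxx = whole - 3.0 * middle
    # Dxy: four l x l boxes one pixel off the center lines, signs (+,-,-,+).
    tl = _box_map(t, rows, cols, -lobe, -lobe, 0, 0)
    tr = _box_map(t, rows, cols, -lobe, 1, 0, lobe + 1)
    bl = _box_map(t, rows, cols, 1, -lobe, lobe + 1, 0)
    br = _box_map(t, rows, cols, 1, 1, lobe + 1, lobe + 1)
    dxy = tl + br - tr - bl

    # constant-Frobenius-norm normalization: the box kernels have norm
    # proportional to L, so dividing the sums by 9L keeps responses
    # comparable across scales (and identical to area normalization at L=9),
    # letting a blob peak at its matched filter size.
    norm = 9.0 * L
    dxx /= norm
    dyy /= norm
    dxy /= norm
    out[np.ix_(rows, cols)] = dxx * dyy - (LOBE_WEIGHT * dxy) ** 2
    return out


@lru_cache(maxsize=8)
def reference_bump_response(sigma: float = 2.0) -> float:
    """Peak det(Hessian) response of a unit-amplitude isotropic Gaussian bump.

    Used to express the detection threshold on a scale-free footing: the
    response of the best-matching filter to a canonical bright spot.
    """
    size = 65
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - size // 2) ** 2 + (xx - size // 2) ** 2
    bump = np.exp(-r2 / (2.0 * sigma**2))
    ii = integral_image(bump)
    peak = 0.0
    for sizes in octave_filter_sizes():
        for L in sizes:
            if L <= size:
                peak = max(peak, float(hessian_response(ii, L).max()))
    return peak


@dataclass
class DetectorParams:
    """Interest-point detector settings.

    ``response_threshold`` is a fraction of the peak response of a canonical
    unit-amplitude Gaussian bump (sigma 2 px), making the default insensitive
    to the absolute response scale of the box filters.
    """

    response_threshold: float = 0.05
    n_octaves: int = 3
    scales_per_octave: int = 4
    reference_sigma: float = 2.0

    def absolute_threshold(self) -> float:
        return self.response_threshold * reference_bump_response(self.reference_sigma)


def detect_interest_points(
    image: np.ndarray, params: DetectorParams | None = None
) -> list[tuple[int, int, int, float]]:
    """Detect blob-like interest points.

    Returns ``(row, col, filter_size, response)`` tuples sorted by
    (filter_size, row, col).  A point is a strict maximum of the response over
    the 3x3x3 (scale, row, col) neighborhood within its octave; ties are
    resolved in favor of the lexicographically-first location.
    """
    params = params or DetectorParams()
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    ii = integral_image(image)
    threshold = params.absolute_threshold()

    response_cache: dict[int, np.ndarray] = {}

    def response(L: int) -> np.ndarray | None:
        if L not in response_cache:
            try:
                response_cache[L] = hessian_response(ii, L)
            except ValueError:
                return None
        return response_cache[L]

    found: dict[tuple[int, int, int], float] = {}
    for sizes in octave_filter_sizes(params.n_octaves, params.scales_per_octave):
        maps = [response(L) for L in sizes]
        if any(m is None for m in maps):
            continue
        stack = np.stack(maps)  # (scale, row, col)
        local_max = ndimage.maximum_filter(stack, size=3, mode="constant", cval=-np.inf)
        for si in range(1, len(sizes) - 1):  # middle scales only
            cand = np.argwhere(
                (stack[si] >= local_max[si]) & (stack[si] > max(threshold, 0.0))
            )
            # candidates sit >= filter margin from the border, so the 3x3x3
            # window below never needs clipping
            for r, c in cand:
                window = stack[si - 1 : si + 2, r - 1 : r + 2, c - 1 : c + 2]
                peak = stack[si, r, c]
                ties = np.argwhere(window == peak)
                first = ties[np.lexsort((ties[:, 2], ties[:, 1], ties[:, 0]))][0]
                if (first == (1, 1, 1)).all():
                    found[(sizes[si], int(r), int(c))] = float(peak)
    points = [(r, c, L, resp) for (L, r, c), resp in found.items()]
    points.sort(key=lambda p: (p[2], p[0], p[1]))
    return points


def count_interest_points(image: np.ndarray, params: DetectorParams | None = None) -> int:
    """The ``n_interest_points`` feature: number of detected interest points."""
    return len(detect_interest_points(image, params))
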