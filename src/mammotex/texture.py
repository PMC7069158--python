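"""Per-band statistical texture descriptors and feature-vector assembly.

Six first-order statistics are computed on the raw wavelet coefficients of
each of the 8 sub-bands: mean, variance (population), skewness m3/m2^1.5,
kurtosis m4/m2^2 (raw, i.e. 3 for a Gaussian), Shannon entropy in bits over a
histogram spanning the band's own range, and relative smoothness
R = 1 - 1/(1 + sigma^2).  Zero-variance bands use the degenerate conventions
(skewness = kurtosis = entropy = R = 0) so feature vectors are always finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import corners, interest_points
from .haar import WaveletDecomposition, haar_decompose2
from .roi_io import FeatureVector, ROIImage
from .schema import BANDS, STATS

DEFAULT_NBINS = 256


@dataclass
class BandStats:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    entropy: float
    relative_smoothness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Mean": self.mean,
            "Variance": self.variance,
            "Skewness": self.skewness,
            "Kurtosis": self.kurtosis,
            "Entropy": self.entropy,
            "RelSmoothness": self.relative_smoothness,
        }


def subband_stats(band: np.ndarray, nbins: int = DEFAULT_NBINS,
                  excess_kurtosis: bool = False) -> BandStats:
    """Compute the six descriptors of one sub-band.

    Parameters
    ----------
    band : 2-D array of wavelet coefficients.
    nbins : number of histogram bins for the entropy estimate (>= 2).
    excess_kurtosis : subtract 3 from the raw kurtosis if True.
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise ValueError("empty band")
    if nbins < 2:
        raise ValueError(f"nbins must be >= 2, got {nbins}")
    if not np.all(np.isfinite(band)):
        raise ValueError("band contains non-finite values")

    x = band.ravel()
    mean = float(x.mean())
    centered = x - mean
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        skew = kurt = entropy = 0.0
    else:
        skew = float(np.mean(centered**3)) / m2**1.5
        kurt = float(np.mean(centered**4)) / m2**2
        if excess_kurtosis:
            kurt -= 3.0
        counts, _ = np.histogram(x, bins=nbins, range=(x.min(), x.max()))
        p = counts[counts > 0] / x.size
        entropy = float(-np.sum(p * np.log2(p)))
    smooth = 1.0 - 1.0 / (1.0 + m2)
    return BandStats(mean, m2, skew, kurt, entropy, smooth)


def statistical_features(decomp: WaveletDecomposition,
                         nbins: int = DEFAULT_NBINS) -> dict[str, float]:
    """The 48-entry SF set: 6 statistics x 8 bands, in frozen schema order."""
    out: dict[str, float] = {}
    for band_name in BANDS:
        stats = subband_stats(decomp[band_name], nbins=nbins).as_dict()
        for stat_name in STATS:
            out[f"{stat_name}_{band_name}"] = stats[stat_name]
    return out


@dataclass
class FeatureParams:
    """Knobs for the feature-extraction stage."""

    nbins: int = DEFAULT_NBINS
    interest_point_params: interest_points.DetectorParams = field(
        default_factory=interest_points.DetectorParams
    )
    corner_params: corners.CornerParams = field(default_factory=corners.CornerParams)


def full_feature_vector(roi: ROIImage, params: FeatureParams | None = None) -> FeatureVector:
    """48 statistical features + interest-point count + corner count = 50."""
    params = params or FeatureParams()
    values = statistical_features(haar_decompose2(roi.pixels), nbins=params.nbins)
    values["n_interest_points"] = float(
        interest_points.count_interest_points(roi.pixels, params.interest_point_params)
    )
    values["n_interest_corners"] = float(
        corners.count_corners(roi.pixels, params.corner_params)
    )
    return FeatureVector(values, id=roi.id, label=roi.label)
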