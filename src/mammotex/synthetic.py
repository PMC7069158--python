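"""Synthetic labeled ROIs emulating the structure of mammographic crops.

Real mammographic ROIs with microcalcification clusters are hand-annotated
clinical images and cannot be redistributed; this module generates stand-ins
with the two properties the pipeline relies on: a smooth textured background
(breast parenchyma analog) and, for abnormal classes, a cluster of small
bright spots (microcalcification analog).  The class contrast mirrors the
clinical one: the benign-like preset has fewer, larger, rounder, more regular
spots; the malignant-like preset has more numerous, smaller, more irregular
ones.  Every distributional choice here is an artifact of the generator, not
a physical model of X-ray texture; presets are plain dataclasses so runs can
serialize the exact conditions used.

The default dataset composition is 130 normal, 75 benign and 55 malignant
ROIs, matching the class balance of the clinical study population this
pipeline targets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .roi_io import ROIImage, normalize_intensity, write_labels

DEFAULT_SIZE = 64


@dataclass
class BackgroundParams:
    """Smoothed-noise background field.

    ``correlation_length`` is the Gaussian smoothing sigma in pixels (larger =
    blobbier parenchyma texture); after smoothing the field is renormalized to
    [0, 1] and then compressed into [base, base + contrast] so that bright
    spots remain visible above it.  Base level, contrast and correlation
    length are drawn per ROI from the given ranges, emulating the variation
    in parenchymal density and exposure across patients: without it every
    background statistic would be nearly identical within a class, which no
    real cohort exhibits.
    """

    height: int = DEFAULT_SIZE
    width: int = DEFAULT_SIZE
    correlation_length_range: tuple[float, float] = (4.0, 8.0)
    noise_sd: float = 1.0
    base_range: tuple[float, float] = (0.05, 0.3)
    contrast_range: tuple[float, float] = (0.3, 0.65)


@dataclass
class SpotClusterParams:
    """Bright-spot cluster: the microcalcification analog."""

    n_spots: int = 5
    spot_sigma_range: tuple[float, float] = (1.8, 2.8)
    amplitude_range: tuple[float, float] = (0.5, 0.8)
    cluster_radius: float = 14.0
    shape_irregularity: float = 0.1

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        lo, hi = self.amplitude_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"amplitude_range must lie in (0, 1], got {self.amplitude_range}")
        if not (0.0 <= self.shape_irregularity <= 1.0):
            raise ValueError("shape_irregularity must be in [0, 1]")


#: Default class presets.  Benign-like: few, larger, round, regular spots.
#: Malignant-like: more numerous, smaller, irregular spots in a wider cluster.
BENIGN_PRESET = SpotClusterParams(
    n_spots=5,
    spot_sigma_range=(1.8, 2.8),
    amplitude_range=(0.5, 0.8),
    cluster_radius=14.0,
    shape_irregularity=0.1,
)
MALIGNANT_PRESET = SpotClusterParams(
    n_spots=13,
    spot_sigma_range=(0.9, 1.8),
    amplitude_range=(0.45, 0.8),
    cluster_radius=20.0,
    shape_irregularity=0.6,
)
PRESETS = {"benign": BENIGN_PRESET, "malignant": MALIGNANT_PRESET}


@dataclass
class SyntheticROI:
    image: ROIImage
    label: str
    ground_truth_spots: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.label == "normal") != (len(self.ground_truth_spots) == 0):
            raise ValueError("ground_truth_spots must be empty iff label is normal")


def generate_background(
    height: int,
    width: int,
    correlation_length: float = 6.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Gaussian-smoothed white noise, min-max renormalized to [0, 1].

    Deterministic given the seed.  ``noise_sd = 0`` yields a constant field,
    which normalizes to all zeros.
    """
    if height < 16 or width < 16:
        raise ValueError(f"background must be at least 16x16, got {height}x{width}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noise = rng.normal(0.0, noise_sd, size=(height, width)) if noise_sd > 0 else np.zeros((height, width))
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length, mode="reflect")
    return normalize_intensity(smooth)


def _add_spot(image: np.ndarray, row: float, col: float, sigma_r: float,
              sigma_c: float, theta: float, amplitude: float) -> None:
    """Add one (possibly anisotropic, rotated) Gaussian bump in place."""
    h, w = image.shape
    extent = int(np.ceil(4 * max(sigma_r, sigma_c)))
    r0, r1 = max(0, int(row) - extent), min(h, int(row) + extent + 1)
    c0, c1 = max(0, int(col) - extent), min(w, int(col) + extent + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - row, xx - col
    u = np.cos(theta) * dy + np.sin(theta) * dx
    v = -np.sin(theta) * dy + np.cos(theta) * dx
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -(u**2 / (2 * sigma_r**2) + v**2 / (2 * sigma_c**2))
    )


def generate_roi(
    label: str,
    bg_params: BackgroundParams | None = None,
    cluster_params: SpotClusterParams | None = None,
    seed: int | np.random.Generator = 0,
    roi_id: str = "",
) -> SyntheticROI:
    """Generate one labeled ROI.

    ``normal`` ROIs are background only; abnormal ones add ``n_spots``
    Gaussian bumps whose centers fall within ``cluster_radius`` of a random
    cluster center, with eccentricity and per-spot jitter controlled by
    ``shape_irregularity``.  The image is clipped to [0, 1].
    """
    if label not in ("normal", "benign", "malignant"):
        raise ValueError(f"unknown label {label!r}")
    bg_params = bg_params or BackgroundParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h, w = bg_params.height, bg_params.width
    corr = rng.uniform(*bg_params.correlation_length_range)
    base = rng.uniform(*bg_params.base_range)
    contrast = rng.uniform(*bg_params.contrast_range)
    bg = generate_background(h, w, corr, bg_params.noise_sd, rng)
    image = base + contrast * bg
    spots: list[tuple[float, float, float]] = []
    if label != "normal":
        cp = cluster_params if cluster_params is not None else PRESETS[label]
        if cp.cluster_radius >= min(h, w) / 2:
            raise ValueError(
                f"cluster_radius {cp.cluster_radius} must be < min(h, w)/2 = {min(h, w) / 2}"
            )
        margin = cp.cluster_radius + 4 * cp.spot_sigma_range[1]
        center = rng.uniform([margin, margin], [h - margin, w - margin]) \
            if margin < min(h, w) / 2 else np.array([h / 2.0, w / 2.0])
        for _ in range(cp.n_spots):
            # uniform draw in the cluster disk
            ang = rng.uniform(0, 2 * np.pi)
            rad = cp.cluster_radius * np.sqrt(rng.uniform())
            row = float(np.clip(center[0] + rad * np.cos(ang), 0, h - 1))
            col = float(np.clip(center[1] + rad * np.sin(ang), 0, w - 1))
            sigma = rng.uniform(*cp.spot_sigma_range)
            ecc = 1.0 + cp.shape_irregularity * rng.uniform(0, 1.5)
            amp = rng.uniform(*cp.amplitude_range)
            theta = rng.uniform(0, np.pi)
            _add_spot(image, row, col, sigma * ecc, sigma / ecc, theta, amp)
            spots.append((row, col, sigma))
    np.clip(image, 0.0, 1.0, out=image)
    roi = ROIImage(image, id=roi_id or f"synthetic_{label}", label=label)
    return SyntheticROI(roi, label, spots)


def generate_dataset(
    n_per_class: dict[str, int] | None = None,
    presets: dict[str, SpotClusterParams] | None = None,
    bg_params: BackgroundParams | None = None,
    seed: int = 0,
) -> list[SyntheticROI]:
    """Generate a labeled dataset with exact per-class counts.

    Per-ROI seeds are derived from (master seed, class, index), so enlarging
    any class re-creates every existing ROI identically.  Default
    composition: 130 normal, 75 benign, 55 malignant.
    """
    n_per_class = n_per_class or {"normal": 130, "benign": 75, "malignant": 55}
    presets = presets or PRESETS
    for label, n in n_per_class.items():
        if n < 1:
            raise ValueError(f"need at least one ROI per class, got {label}={n}")
    rois = []
    for class_idx, label in enumerate(("normal", "benign", "malignant")):
        for i in range(n_per_class.get(label, 0)):
            rng = np.random.default_rng(np.random.SeedSequence([seed, class_idx, i]))
            cp = None if label == "normal" else presets[label]
            rois.append(
                generate_roi(label, bg_params, cp, rng, roi_id=f"roi_{label}_{i:04d}")
            )
    return rois


def write_dataset(rois: list[SyntheticROI], out_dir: str | Path) -> None:
    """Write PNGs, a labels CSV and a ground-truth JSON for a dataset."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = {}
    for roi in rois:
        arr = np.round(roi.image.pixels * 65535).astype(np.uint16)
        iio.imwrite(out_dir / f"{roi.image.id}.png", arr)
        truth[roi.image.id] = {
            "label": roi.label,
            "spots": [[round(v, 3) for v in s] for s in roi.ground_truth_spots],
        }
    write_labels([r.image for r in rois], out_dir / "labels.csv")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def preset_dict() -> dict:
    """Serializable view of the default generation conditions."""
    return {
        "background": asdict(BackgroundParams()),
        "presets": {k: asdict(v) for k, v in PRESETS.items()},
    }
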