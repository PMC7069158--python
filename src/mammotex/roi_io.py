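"""Reading and writing of ROI images, labels and feature tables.

An ROI (region of interest) is a grayscale crop of a mammogram, optionally
carrying a class label (``normal`` / ``benign`` / ``malignant``).  Intensities
are min–max normalized to [0, 1] on load so every downstream stage sees a
scale-free image; a constant image maps to all zeros rather than dividing by
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .schema import FEATURE_NAMES, LABELS, N_FEATURES

MIN_DIM = 16


class ROIError(ValueError):
    """Raised for unreadable, malformed or undersized ROI inputs."""


class SchemaError(ValueError):
    """Raised when a feature table does not match the frozen 50-column schema."""


@dataclass
class ROIImage:
    """A normalized grayscale ROI.

    Attributes
    ----------
    pixels : ndarray of shape (height, width)
        Intensities in [0, 1], row-major, origin at the top-left corner.
    id : str
        Identifier used in label files and feature tables.
    label : str or None
        One of ``normal``, ``benign``, ``malignant`` when known.
    """

    pixels: np.ndarray
    id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ROIError(f"ROI must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < MIN_DIM or w < MIN_DIM:
            raise ROIError(f"ROI must be at least {MIN_DIM}x{MIN_DIM}, got {h}x{w}")
        if not np.all(np.isfinite(self.pixels)):
            raise ROIError("ROI contains non-finite intensities")
        if self.label is not None and self.label not in LABELS:
            raise ROIError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FeatureVector:
    """The 50 named features of one ROI, in frozen schema order."""

    values: dict[str, float]
    id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise SchemaError(
                f"feature vector must have exactly the {N_FEATURES} schema entries "
                f"in order (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        arr = np.array(list(self.values.values()), dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = [k for k, v in self.values.items() if not np.isfinite(v)]
            raise SchemaError(f"non-finite feature values: {bad}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)


def normalize_intensity(pixels: np.ndarray) -> np.ndarray:
    """Min–max normalize to [0, 1]; a constant image becomes all zeros.

    Idempotent: applying it twice gives the same array.
    """
    pixels = np.asarray(pixels, dtype=float)
    lo = pixels.min()
    hi = pixels.max()
    if hi == lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def load_roi(path: str | Path, label: str | None = None, id: str | None = None) -> ROIImage:
    """Read a PNG/TIFF grayscale image as a normalized ROI.

    Multi-channel images are accepted only when all channels are identical
    (gray stored as RGB); genuinely colored images are rejected.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ROIError(f"unreadable image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            rgb = arr[..., :3]
            if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
                raise ROIError(f"{path} has distinct color channels; expected grayscale")
            arr = rgb[..., 0]
        else:
            raise ROIError(f"{path} has unsupported shape {arr.shape}")
    elif arr.ndim != 2:
        raise ROIError(f"{path} has unsupported shape {arr.shape}")
    return ROIImage(normalize_intensity(arr), id=id or path.stem, label=label)


def write_labels(rois: Iterable[ROIImage], path: str | Path) -> None:
    """Write an ``id,label`` CSV for a set of ROIs."""
    df = pd.DataFrame(
        [{"id": r.id, "label": "" if r.label is None else r.label} for r in rois]
    )
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != ["id", "label"]:
        raise SchemaError(f"label file must have columns id,label; got {list(df.columns)}")
    return dict(zip(df["id"], df["label"]))


def write_feature_table(rows: Sequence[FeatureVector], path: str | Path) -> None:
    """Serialize feature vectors as CSV: ``id,label,<50 feature columns>``.

    Values are written with 17 significant digits so the round trip is exact
    to well beyond 12 significant digits.
    """
    records = []
    for fv in rows:
        rec = {"id": fv.id, "label": "" if fv.label is None else fv.label}
        rec.update(fv.values)
        records.append(rec)
    df = pd.DataFrame(records, columns=["id", "label", *FEATURE_NAMES])
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path, keep_default_na=False)
    expected = ["id", "label", *FEATURE_NAMES]
    if list(df.columns) != expected:
        raise SchemaError(
            f"feature table columns do not match the schema "
            f"({len(df.columns)} columns, expected {len(expected)})"
        )
    out = []
    for _, row in df.iterrows():
        values = {name: float(row[name]) for name in FEATURE_NAMES}
        label = str(row["label"]) or None
        out.append(FeatureVector(values, id=str(row["id"]), label=label))
    return out


def feature_frame(rows: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame indexed by ROI id, with a
    ``label`` column first and the 50 feature columns in schema order."""
    df = pd.DataFrame([{"label": fv.label, **fv.values} for fv in rows],
                      index=[fv.id for fv in rows])
    return df
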