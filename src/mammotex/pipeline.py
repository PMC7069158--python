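"""End-to-end helpers tying feature extraction to the two binary problems."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .roi_io import FeatureVector, ROIImage, feature_frame
from .texture import FeatureParams, full_feature_vector

PROBLEMS = ("normal_abnormal", "benign_malignant")


def featurize(rois: Iterable[ROIImage], params: FeatureParams | None = None) -> pd.DataFrame:
    """Extract the 50-feature vector for every ROI.

    Returns a DataFrame indexed by ROI id with a leading ``label`` column —
    a pure per-ROI map, so row order never affects any value.
    """
    vectors: list[FeatureVector] = [full_feature_vector(r, params) for r in rois]
    return feature_frame(vectors)


def binary_problem(frame: pd.DataFrame, problem: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Select rows and encode labels for one of the two binary problems.

    ``normal_abnormal``: all ROIs, positive class (1) = benign or malignant.
    ``benign_malignant``: lesion ROIs only, positive class (1) = malignant.
    """
    if problem not in PROBLEMS:
        raise ValueError(f"problem must be one of {PROBLEMS}, got {problem!r}")
    labels = frame["label"].to_numpy()
    if problem == "normal_abnormal":
        mask = np.isin(labels, ["normal", "benign", "malignant"])
        y = np.isin(labels[mask], ["benign", "malignant"]).astype(int)
    else:
        mask = np.isin(labels, ["benign", "malignant"])
        y = (labels[mask] == "malignant").astype(int)
    X = frame.loc[mask].drop(columns="label")
    return X, y
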