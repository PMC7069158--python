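"""Frozen feature schema for the 50-entry ROI feature vector.

The vector concatenates 48 statistical descriptors (6 statistics on each of
the 8 Haar sub-bands of a 2-level decomposition) with the two detector counts.
Band order is level-major (all level-1 bands first), statistic order is fixed;
the resulting column order is the contract for every serialized feature table.
"""

from __future__ import annotations

STATS = ("Mean", "Variance", "Skewness", "Kurtosis", "Entropy", "RelSmoothness")
BANDS = ("LL1", "HL1", "LH1", "HH1", "LL2", "HL2", "LH2", "HH2")

#: The 48 per-band statistical feature names, band-major.
STAT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{band}" for band in BANDS for stat in STATS
)

#: Detector-count feature names.
COUNT_FEATURE_NAMES: tuple[str, ...] = ("n_interest_points", "n_interest_corners")

#: Full 50-entry feature order.
FEATURE_NAMES: tuple[str, ...] = STAT_FEATURE_NAMES + COUNT_FEATURE_NAMES

N_FEATURES = len(FEATURE_NAMES)

#: Recognized class labels. ``normal`` means no lesion present.
LABELS = ("normal", "benign", "malignant")
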