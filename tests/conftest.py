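import numpy as np
import pytest

from mammotex import pipeline, synthetic


def gaussian_bump(shape, row, col, sigma, amplitude=1.0):
    """Isotropic Gaussian bump on a zero background."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-(((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sigma**2)))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-condition dataset: 130 normal / 75 benign / 55 malignant."""
    return synthetic.generate_dataset(seed=20260928)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """50-feature table for the default dataset (extracted once per session)."""
    return pipeline.featurize(r.image for r in default_dataset)
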