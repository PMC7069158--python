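"""Two-level 2D Haar wavelet decomposition.

The orthonormal convention is used: one 2D analysis step maps each 2x2 block
``[[a, b], [c, d]]`` to

    LL = (a + b + c + d) / 2      (approximation)
    HL = (a - b + c - d) / 2      (horizontal detail: differences along rows)
    LH = (a + b - c - d) / 2      (vertical detail: differences down columns)
    HH = (a - b - c + d) / 2      (diagonal detail)

so that the sum of squared coefficients equals the sum of squared pixels
(Parseval) and the transform is exactly invertible.  The second level repeats
the step on LL1.  Odd dimensions are reflect-padded to the next even size
before each step; padding affects border coefficients only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LEVEL1_BANDS = ("LL1", "HL1", "LH1", "HH1")
LEVEL2_BANDS = ("LL2", "HL2", "LH2", "HH2")
BAND_NAMES = LEVEL1_BANDS + LEVEL2_BANDS


@dataclass
class WaveletDecomposition:
    """The 8 sub-band coefficient arrays of a 2-level Haar transform."""

    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.bands) != set(BAND_NAMES):
            raise ValueError(
                f"decomposition must contain exactly bands {BAND_NAMES}, "
                f"got {sorted(self.bands)}"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.bands[name]


def _pad_even(image: np.ndarray) -> np.ndarray:
    """Reflect-pad so both dimensions are even."""
    pr = image.shape[0] % 2
    pc = image.shape[1] % 2
    if pr or pc:
        image = np.pad(image, ((0, pr), (0, pc)), mode="reflect")
    return image


def haar_step(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One orthonormal 2D Haar analysis step: ``(LL, HL, LH, HH)``.

    Requires even dimensions; callers pad first (see :func:`haar_decompose2`).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot decompose an empty array")
    if image.ndim != 2 or image.shape[0] % 2 or image.shape[1] % 2:
        raise ValueError(f"haar_step needs an even-dimension 2-D array, got {image.shape}")
    a = image[0::2, 0::2]
    b = image[0::2, 1::2]
    c = image[1::2, 0::2]
    d = image[1::2, 1::2]
    ll = (a + b + c + d) / 2.0
    hl = (a - b + c - d) / 2.0
    lh = (a + b - c - d) / 2.0
    hh = (a - b - c + d) / 2.0
    return ll, hl, lh, hh


def haar_decompose2(image: np.ndarray, levels: int = 2) -> WaveletDecomposition:
    """Decompose an image into the 8 sub-bands of a 2-level Haar transform.

    ``levels`` exists for generality but the texture pipeline uses the default
    of 2 (band names are fixed for two levels).
    """
    if levels != 2:
        raise NotImplementedError("the feature schema is defined for 2 levels")
    image = np.asarray(image, dtype=float)
    ll1, hl1, lh1, hh1 = haar_step(_pad_even(image))
    ll2, hl2, lh2, hh2 = haar_step(_pad_even(ll1))
    return WaveletDecomposition(
        {
            "LL1": ll1, "HL1": hl1, "LH1": lh1, "HH1": hh1,
            "LL2": ll2, "HL2": hl2, "LH2": lh2, "HH2": hh2,
        }
    )


def haar_step_inverse(
    ll: np.ndarray, hl: np.ndarray, lh: np.ndarray, hh: np.ndarray
) -> np.ndarray:
    """Invert one orthonormal Haar step."""
    shapes = {x.shape for x in (ll, hl, lh, hh)}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent band shapes: {sorted(shapes)}")
    h, w = ll.shape
    out = np.empty((2 * h, 2 * w), dtype=float)
    out[0::2, 0::2] = (ll + hl + lh + hh) / 2.0
    out[0::2, 1::2] = (ll - hl + lh - hh) / 2.0
    out[1::2, 0::2] = (ll + hl - lh - hh) / 2.0
    out[1::2, 1::2] = (ll - hl - lh + hh) / 2.0
    return out


def haar_reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Invert a 2-level decomposition of an even-dimension image.

    ``reconstruct(decompose(I)) == I`` to floating-point accuracy when the
    original dimensions were multiples of 4 (no padding involved).
    """
    ll1 = haar_step_inverse(
        decomp["LL2"], decomp["HL2"], decomp["LH2"], decomp["HH2"]
    )
    if ll1.shape != decomp["HL1"].shape:
        raise ValueError(
            f"level-2 bands reconstruct to {ll1.shape} but level-1 detail bands "
            f"have shape {decomp['HL1'].shape}"
        )
    return haar_step_inverse(ll1, decomp["HL1"], decomp["LH1"], decomp["HH1"])


def band_energy(decomp: WaveletDecomposition) -> float:
    """Total squared-coefficient energy over the non-redundant bands
    (level-2 bands replace LL1)."""
    names = ("HL1", "LH1", "HH1", "LL2", "HL2", "LH2", "HH2")
    return float(sum(np.sum(decomp[n] ** 2) for n in names))
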