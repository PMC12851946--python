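"""Reference stain palette and optical-density conversions.

The package uses a single fixed reference palette of optical-density (OD)
stain vectors for hematoxylin, eosin and a collagen tone.  The synthetic
slide generator composes images from these exact vectors, which gives the
Macenko estimator a known ground truth and makes stain unmixing in the
morphometry stage exactly checkable.

Conventions (used everywhere in the package):

* OD = -log10((I + 1) / I0) with I0 = 255; the +1 offset avoids log(0).
* Stain matrices store one unit-norm OD vector per column, hematoxylin
  first (hematoxylin has the larger blue-channel OD).
"""

from __future__ import annotations

import numpy as np

I0 = 255.0

#: Hematoxylin OD vector (unit norm).  Larger blue component than eosin.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
#: Eosin OD vector (unit norm).
EOSIN_OD = np.array([0.070, 0.990, 0.110])
#: Collagen tone used by the generator for fibrotic marrow texture.
COLLAGEN_OD = np.array([0.250, 0.600, 0.760])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


HEMATOXYLIN_OD = _unit(HEMATOXYLIN_OD)
EOSIN_OD = _unit(EOSIN_OD)
COLLAGEN_OD = _unit(COLLAGEN_OD)

#: 3x2 reference H&E stain matrix (columns: hematoxylin, eosin).
REFERENCE_HE = np.column_stack([HEMATOXYLIN_OD, EOSIN_OD])
#: 3x3 basis including the collagen tone, for 3-stain unmixing.
REFERENCE_HEC = np.column_stack([HEMATOXYLIN_OD, EOSIN_OD, COLLAGEN_OD])


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image (or pixel array) to optical density."""
    arr = np.asarray(image, dtype=np.float64)
    od = -np.log10((arr + 1.0) / I0)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`, returning a uint8 array."""
    intensity = I0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def compose_rgb(concentrations: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Render RGB from per-pixel stain concentrations via Beer-Lambert.

    Parameters
    ----------
    concentrations:
        Array of shape (H, W, S) with nonnegative per-stain concentrations.
    stain_matrix:
        3xS matrix of OD stain vectors (one per column).
    """
    conc = np.asarray(concentrations, dtype=np.float64)
    od = conc @ stain_matrix.T
    return od_to_rgb(od)
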