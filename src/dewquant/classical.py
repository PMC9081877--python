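"""Classical edge-detection baselines: Canny and Laplacian zero-crossing.

Both operate on single-channel images on the 8-bit intensity scale and
return binary edge masks.  They are deterministic and serve both as
comparison baselines for the learned detector and as a fallback detection
path that needs no training.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import feature


def _as_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {image.shape}")
    return image.astype(np.float64)


def canny_edges(
    gray_image: np.ndarray,
    low: float = 64.0,
    high: float = 81.0,
    sigma: float = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Canny detector with hysteresis thresholds on the 8-bit scale.

    The default (low, high) = (64, 81) is the threshold pair that works
    best for dew scenes.  ``mask``, if given, restricts detection to the
    analysis region produced by background segmentation.
    """
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    gray = _as_gray(gray_image) / 255.0
    out = feature.canny(
        gray,
        sigma=sigma,
        low_threshold=low / 255.0,
        high_threshold=high / 255.0,
        mask=None if mask is None else mask.astype(bool),
    )
    return out.astype(np.uint8)


def laplace_edges(
    gray_image: np.ndarray,
    kernel_size: int = 3,
    zero_cross_min_contrast: float = 5.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Laplacian zero-crossing detector.

    Marks a pixel as edge where the Laplacian response changes sign
    between it and its right or lower neighbour with a jump of at least
    ``zero_cross_min_contrast`` (8-bit intensity units); of the two pixels
    straddling the crossing, the one with the smaller absolute response is
    marked.  A linear ramp has an identically zero Laplacian and yields no
    edges, and adding a constant to the image leaves the output unchanged.
    """
    gray = _as_gray(gray_image)
    if kernel_size == 3:
        lap = ndimage.laplace(gray)
    else:
        lap = ndimage.gaussian_laplace(gray, sigma=max((kernel_size - 1) / 3.0, 0.5))
    edges = np.zeros(gray.shape, dtype=np.uint8)
    for axis in (0, 1):
        a = lap.take(range(lap.shape[axis] - 1), axis=axis)
        b = lap.take(range(1, lap.shape[axis]), axis=axis)
        crossing = (a * b < 0) & (np.abs(a - b) >= zero_cross_min_contrast)
        pick_a = np.abs(a) <= np.abs(b)
        first = crossing & pick_a
        second = crossing & ~pick_a
        if axis == 0:
            edges[:-1, :] |= first.astype(np.uint8)
            edges[1:, :] |= second.astype(np.uint8)
        else:
            edges[:, :-1] |= first.astype(np.uint8)
            edges[:, 1:] |= second.astype(np.uint8)
    if mask is not None:
        edges &= mask.astype(np.uint8)
    return edges
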