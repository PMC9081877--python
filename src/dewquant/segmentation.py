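"""Color-feature background segmentation.

Dew is nearly achromatic (it refracts the ambient light at low saturation),
while the interfering parts of a plant scene -- leaf color, specular light
patches, reflections -- are color-rich.  Thresholding the HSV saturation
channel therefore separates the analysable (low-saturation) region from the
background, and a morphological closing followed by an erosion regularises
the mask and pulls it away from region boundaries so that the mask edge
itself cannot be mistaken for a droplet contour downstream.

The pipeline is fixed: saturation threshold -> closing -> erosion, with a
square structuring element for both morphological steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor


class ChannelError(ValueError):
    """Raised when an image does not have the expected channel layout."""


@dataclass
class HsvImage:
    """HSV decomposition of an RGB image.

    hue is in degrees [0, 360); saturation and value are on the 8-bit
    scale 0-255 so that the saturation threshold ``alpha`` is expressed in
    the same units as the images it is applied to.
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


@dataclass
class SegmentationConfig:
    """Parameters of the background-removal stage.

    alpha : saturation threshold (0-255).  Pixels with S < alpha are kept
        for analysis; pixels at or above it are treated as color-rich
        background.  Default 50.
    close_se_side / erode_se_side : side length (pixels, odd) of the square
        structuring element used by the closing and the erosion.
        Default 25 for both.
    fill_value : intensity written into excluded pixels of the masked image.
    """

    alpha: float = 50.0
    close_se_side: int = 25
    erode_se_side: int = 25
    fill_value: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 255:
            raise ValueError(f"alpha must be in [0, 255], got {self.alpha}")
        for name in ("close_se_side", "erode_se_side"):
            side = getattr(self, name)
            if side < 1 or side % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {side}")


def rgb_to_hsv(image: np.ndarray) -> HsvImage:
    """Convert an H x W x 3 8-bit RGB image to :class:`HsvImage`."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ChannelError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    hsv = skcolor.rgb2hsv(image.astype(np.float64) / 255.0)
    return HsvImage(
        hue=hsv[..., 0] * 360.0,
        saturation=hsv[..., 1] * 255.0,
        value=hsv[..., 2] * 255.0,
    )


def hsv_to_rgb(hsv: HsvImage) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`; returns an 8-bit RGB image."""
    stacked = np.stack(
        [hsv.hue / 360.0, hsv.saturation / 255.0, hsv.value / 255.0], axis=-1
    )
    rgb = skcolor.hsv2rgb(stacked)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def saturation_mask(hsv: HsvImage, alpha: float) -> np.ndarray:
    """Binary mask of analysable pixels: 1 where saturation < alpha.

    Monotone in alpha: a larger threshold never removes a retained pixel.
    """
    if not 0 <= alpha <= 255:
        raise ValueError(f"alpha must be in [0, 255], got {alpha}")
    return (hsv.saturation < alpha).astype(np.uint8)


def _square(se_side: int) -> np.ndarray:
    if se_side < 1:
        raise ValueError(f"structuring element side must be >= 1, got {se_side}")
    return np.ones((se_side, se_side), dtype=bool)


def morph_dilate(mask: np.ndarray, se_side: int) -> np.ndarray:
    """Binary dilation with a square structuring element (outside = 0)."""
    out = ndimage.binary_dilation(mask.astype(bool), structure=_square(se_side))
    return out.astype(np.uint8)


def morph_erode(mask: np.ndarray, se_side: int) -> np.ndarray:
    """Binary erosion with a square structuring element.

    The plane outside the frame counts as background, so a mask touching
    the border erodes inward there: an all-one mask shrinks by
    (se_side - 1) / 2 pixels on every side.
    """
    out = ndimage.binary_erosion(
        mask.astype(bool), structure=_square(se_side), border_value=0
    )
    return out.astype(np.uint8)


def morph_close(mask: np.ndarray, se_side: int) -> np.ndarray:
    """Binary closing (dilation then erosion) with a square SE.

    Computed on the zero-padded plane so the dilation may overflow the
    frame before the erosion pulls it back; this keeps closing extensive
    (input is a subset of output) and idempotent, including at the border.
    """
    half = se_side // 2
    padded = np.pad(mask.astype(bool), half, mode="constant", constant_values=0)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=_square(se_side)),
        structure=_square(se_side),
        border_value=0,
    )
    if half:
        closed = closed[half:-half, half:-half]
    return closed.astype(np.uint8)


def segment_background(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Remove color-rich background from an RGB image.

    Returns ``(masked_image, analysis_mask)`` where

        analysis_mask = erode(close(saturation < alpha))

    and ``masked_image`` equals ``image`` inside the mask and
    ``config.fill_value`` outside it.  The mask should travel with the
    image downstream so that edges created at the mask boundary by the
    fill can be suppressed.
    """
    config = config or SegmentationConfig()
    hsv = rgb_to_hsv(image)
    mask = saturation_mask(hsv, config.alpha)
    mask = morph_close(mask, config.close_se_side)
    mask = morph_erode(mask, config.erode_se_side)
    masked = image.copy()
    masked[mask == 0] = config.fill_value
    return masked, mask
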