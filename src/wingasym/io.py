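"""Image loading, binarization, mirroring and physical scaling.

Wing scans are expected to show dark veins on a light membrane/background.
Binarization splits the grayscale image at a fixed threshold (default 0.54 on
[0, 1] intensities): pixels strictly brighter than the threshold become
foreground (membrane), everything else is vein/background.  Left wings are
mirrored so both wings of a pair share the same chirality before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ImageIOError, ValidationError

#: ITU-R BT.601 luminance weights used to collapse RGB to a single channel.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Default binarization threshold on [0, 1] intensities.
DEFAULT_THRESHOLD = 0.54

MIN_IMAGE_SIDE = 8


@dataclass(frozen=True)
class RawImage:
    """A grayscale raster with intensities normalized to [0, 1].

    Attributes
    ----------
    pixels : ndarray of float64, shape (height, width)
        Intensities in [0, 1]; 1 is white (membrane), 0 is black (vein).
    source_path : str or None
        Where the raster was read from, if it came from a file.
    """

    pixels: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError("RawImage expects a 2-D intensity grid")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image too small: {px.shape}, need at least "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryWingImage:
    """Binarized wing raster.

    ``mask`` is True on membrane (light) pixels and False on vein/background
    (dark) pixels.  ``scale`` is the physical length of one pixel side; when
    absent all derived metrics are in pixel units.
    """

    mask: np.ndarray
    threshold_used: float
    mirrored: bool = False
    scale: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValidationError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]


def from_array(pixels: np.ndarray, source_path: str | None = None) -> RawImage:
    """Build a :class:`RawImage` from an array.

    Accepts float arrays already in [0, 1] or unsigned-integer arrays, which
    are normalized by their dtype maximum.  3-channel arrays are collapsed to
    luminance first.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise ValidationError("expected an RGB(A) array with >= 3 channels")
        arr = arr[..., :3].astype(float) @ LUMA_WEIGHTS
        if np.issubdtype(np.asarray(pixels).dtype, np.integer):
            arr = arr / np.iinfo(np.asarray(pixels).dtype).max
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return RawImage(pixels=arr, source_path=source_path)


def load_image(path: str | Path) -> RawImage:
    """Read a PNG/TIFF/JPEG/BMP raster and normalize it to [0, 1].

    RGB images are converted to luminance with the BT.601 weights
    (0.299, 0.587, 0.114) before normalization.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGB", "RGBA", "P", "CMYK"):
                im = im.convert("RGB")
                arr = np.asarray(im, dtype=float) @ LUMA_WEIGHTS
                arr = arr / 255.0
            else:
                im = im.convert("F") if im.mode not in ("L", "I;16", "F") else im
                arr = np.asarray(im, dtype=float)
                if arr.size and arr.max() > 1.0:
                    # integer-coded grayscale: normalize by the coding maximum
                    full = 65535.0 if arr.max() > 255.0 else 255.0
                    arr = arr / full
    except UnidentifiedImageError as exc:
        raise ImageIOError(f"unreadable raster file: {path}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    return RawImage(pixels=np.clip(arr, 0.0, 1.0), source_path=str(path))


def binarize(image: RawImage, threshold: float = DEFAULT_THRESHOLD) -> BinaryWingImage:
    """Threshold a grayscale image into membrane (True) and vein (False).

    A pixel is foreground iff its intensity is strictly greater than
    ``threshold``; a pixel exactly at the threshold is treated as vein, which
    errs toward keeping the vein network connected.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    return BinaryWingImage(
        mask=image.pixels > threshold,
        threshold_used=threshold,
    )


def mirror_horizontal(image: BinaryWingImage) -> BinaryWingImage:
    """Reverse the column order (left-right flip) and toggle the mirror flag."""
    return replace(
        image,
        mask=image.mask[:, ::-1].copy(),
        mirrored=not image.mirrored,
    )


def set_scale(image: BinaryWingImage, units_per_pixel: float) -> BinaryWingImage:
    """Attach a physical scale (length units per pixel side).

    Downstream lengths multiply by the scale and areas by its square;
    dimensionless quantities (circularity, counts, regression, NRMSE) are
    unaffected.
    """
    if not units_per_pixel > 0:
        raise ValidationError(f"scale must be positive, got {units_per_pixel}")
    return replace(image, scale=float(units_per_pixel))
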