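"""Raster image loading and the canonical grayscale float representation.

Images are handled internally as 2-D float64 arrays with intensities in
[0, 1].  Loading scales by the bit depth of the source file (255 for 8-bit,
65535 for 16-bit); RGB inputs are collapsed to a single channel according to
a configurable policy.  A registered pair of images is represented by
:class:`ImagePair`, which enforces that both members share a shape.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import tifffile

#: BT.601 luma weights used for the default RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

CHANNEL_POLICIES = ("luma", "green", "mean")


class ImageFormatError(ValueError):
    """Raised when a raster file has an unsupported layout."""


class DimensionError(ValueError):
    """Raised when two images that must be co-dimensional are not."""


def validate_image(pixels: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Validate and canonicalize a grayscale image array.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities. Values must be finite; they are not
        required to lie in [0, 1] (intermediate maps may leave the range)
        but must be real.

    Returns
    -------
    ndarray
        The input as a C-contiguous float64 array.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageFormatError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ImageFormatError(f"{name} must be non-empty, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return np.ascontiguousarray(arr)


@dataclass(frozen=True)
class ImagePair:
    """A registered (reference, current) pair of grayscale images.

    The reference image is the earlier acquisition; the current image is the
    later one in which changes (lesions) are to be detected.  Both must have
    identical shape — registration is assumed to have happened upstream.
    """

    reference: np.ndarray
    current: np.ndarray

    def __post_init__(self):
        ref = validate_image(self.reference, name="reference")
        cur = validate_image(self.current, name="current")
        if ref.shape != cur.shape:
            raise DimensionError(
                f"reference shape {ref.shape} != current shape {cur.shape}"
            )
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "current", cur)

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape


def as_pair(reference: np.ndarray, current: np.ndarray) -> ImagePair:
    """Bundle two co-dimensional grayscale images into an :class:`ImagePair`."""
    return ImagePair(reference=reference, current=current)


def to_gray(raster: np.ndarray, channel_policy: str = "luma") -> np.ndarray:
    """Collapse a decoded raster array to a 2-D float image in [0, 1].

    Integer inputs are scaled by the maximum of their dtype (255 for uint8,
    65535 for uint16); float inputs are assumed to already be in [0, 1].
    3-channel (or 4-channel RGBA, alpha dropped) inputs are collapsed using
    ``channel_policy``:

    - ``"luma"`` — BT.601 weighted sum 0.299 R + 0.587 G + 0.114 B,
    - ``"green"`` — green channel only (conventional for fundus imagery,
      where the green channel carries the most vascular contrast),
    - ``"mean"`` — unweighted channel mean.
    """
    if channel_policy not in CHANNEL_POLICIES:
        raise ValueError(
            f"channel_policy must be one of {CHANNEL_POLICIES}, got {channel_policy!r}"
        )
    arr = np.asarray(raster)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / scale
    else:
        arr = arr.astype(np.float64)

    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ImageFormatError(
                f"unsupported channel count {arr.shape[2]}; expected 1, 3 or 4"
            )
        if channel_policy == "luma":
            arr = arr @ LUMA_WEIGHTS
        elif channel_policy == "green":
            arr = arr[:, :, 1]
        else:
            arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise ImageFormatError(f"unsupported raster dimensionality {arr.ndim}")

    arr = np.clip(arr, 0.0, 1.0)
    return validate_image(arr)


def load_image(path: str | os.PathLike, channel_policy: str = "luma") -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster and return the canonical grayscale image.

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded.
    ImageFormatError
        If the decoded array has an unsupported layout.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"input image not found: {path}")
    try:
        raster = iio.imread(path)
    except ImageFormatError:
        raise
    except Exception as exc:  # decoding failures vary by plugin
        raise IOError(f"could not decode image {path}: {exc}") from exc
    return to_gray(raster, channel_policy=channel_policy)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG with values 0/255."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(os.fspath(path), (mask.astype(np.uint8) * 255))


def save_gray_png(path: str | os.PathLike, img: np.ndarray, bitdepth: int = 16) -> None:
    """Write a [0,1] image as an 8- or 16-bit PNG (clipping out-of-range values)."""
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    if bitdepth == 8:
        iio.imwrite(os.fspath(path), np.round(img * 255).astype(np.uint8))
    elif bitdepth == 16:
        iio.imwrite(os.fspath(path), np.round(img * 65535).astype(np.uint16))
    else:
        raise ValueError("bitdepth must be 8 or 16")


def save_float_tiff(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write a real-valued map (signed allowed) as a 32-bit float TIFF."""
    tifffile.imwrite(os.fspath(path), np.asarray(img, dtype=np.float32))


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask image; pixels above half range count as True."""
    raster = load_image(path, channel_policy="mean")
    return raster > 0.5
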