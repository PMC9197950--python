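"""Difference images, binary change masks, morphological cleaning and fusion.

The background-subtracted difference ``current - B2`` is the raw evidence of
change.  Its absolute value is rescaled by its maximum to [0, 1] so that the
binarization thresholds (0.3 for the plain detector, 0.15 for the fusion
pathway) are well defined regardless of exposure.  The binary mask is
cleaned morphologically (opening to remove speckle, closing to consolidate
lesions, small-component removal) and, in fusion mode, gates an
illumination-corrected difference image so that only evidence inside
SRC-detected regions survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .image_io import DimensionError, validate_image
from .sparse_coding import BackgroundImage


#: differences below one 8-bit quantization step carry no evidence of change
NOISE_FLOOR = 1.0 / 255.0


@dataclass(frozen=True)
class ChangeMap:
    """Signed and max-rescaled absolute difference images."""

    signed: np.ndarray
    absolute: np.ndarray

    @classmethod
    def from_signed(cls, signed: np.ndarray,
                    noise_floor: float = NOISE_FLOOR) -> "ChangeMap":
        """Build a map from a signed difference, rescaling |.| to [0, 1].

        The absolute map is divided by its peak so the binarization
        thresholds are exposure-independent — except when the peak itself
        is below ``noise_floor`` (one quantization step of an 8-bit image):
        a difference that small is numerical/sensor noise, and amplifying
        it to full scale would manufacture change out of nothing, so such
        maps are divided by the floor instead and never reach 1.
        """
        signed = validate_image(signed, name="signed difference")
        absolute = np.abs(signed)
        peak = absolute.max()
        if peak > 0:
            absolute = absolute / max(peak, noise_floor)
        return cls(signed=signed, absolute=absolute)


def difference(current: np.ndarray,
               background: BackgroundImage | np.ndarray) -> ChangeMap:
    """Background-subtraction change map: signed = current - background."""
    current = validate_image(current, name="current")
    bg = background.pixels if isinstance(background, BackgroundImage) else background
    bg = validate_image(bg, name="background")
    if current.shape != bg.shape:
        raise DimensionError(
            f"current shape {current.shape} != background shape {bg.shape}"
        )
    return ChangeMap.from_signed(current - bg)


def binarize(cmap: ChangeMap, threshold: float) -> np.ndarray:
    """Threshold the rescaled absolute map: mask = absolute >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return cmap.absolute >= threshold


def clean_mask(mask: np.ndarray, open_radius: int = 1, close_radius: int = 3,
               min_area: int = 20) -> np.ndarray:
    """Morphologically clean a binary mask.

    Opening with a disk of ``open_radius`` (removes speckle thinner than the
    element), closing with a disk of ``close_radius`` (bridges small gaps
    inside lesions), then removal of 8-connected components smaller than
    ``min_area`` pixels.  Zero radii / area are identity operations.
    """
    mask = np.asarray(mask, dtype=bool)
    if open_radius < 0 or close_radius < 0 or min_area < 0:
        raise ValueError("radii and min_area must be >= 0")
    out = mask
    if open_radius > 0:
        out = morphology.opening(out, morphology.disk(open_radius))
    if close_radius > 0:
        out = morphology.closing(out, morphology.disk(close_radius))
    if min_area > 0:
        # remove components strictly smaller than min_area (8-connectivity)
        out = morphology.remove_small_objects(out, max_size=min_area - 1,
                                              connectivity=2)
    return out


def fuse(src_mask: np.ndarray, illum_corrected_diff: ChangeMap) -> ChangeMap:
    """Gate an illumination-corrected difference with the SRC change mask.

    The SRC mask marks where the sparse model found unexplainable content;
    multiplying it into the corrected difference keeps that evidence at its
    full (corrected) contrast while zeroing illumination residue elsewhere.
    """
    src_mask = np.asarray(src_mask, dtype=bool)
    if src_mask.shape != illum_corrected_diff.signed.shape:
        raise DimensionError(
            f"mask shape {src_mask.shape} != map shape "
            f"{illum_corrected_diff.signed.shape}"
        )
    return ChangeMap(
        signed=illum_corrected_diff.signed * src_mask,
        absolute=illum_corrected_diff.absolute * src_mask,
    )
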