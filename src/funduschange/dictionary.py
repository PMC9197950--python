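"""Local patch dictionaries extracted from the reference image.

For a pixel P of the current image, the corresponding pixel P' of the
registered reference image anchors an l-by-l neighborhood window.  A g-by-g
uniform grid of patch centers spanning that window (endpoints included)
yields q = g^2 square patches of side s, each vectorized row-major into a
column of the dictionary matrix D (p = s^2 rows).  A current-image patch is
then represented as a sparse linear combination of these atoms; because the
atoms carry the local anatomy, the representable part is "background" and
the residual is candidate change.

Coordinates are 0-based (row, col); a patch centered on pixel (r, c) covers
rows r-(s-1)/2 .. r+(s-1)/2, so the patch side must be odd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import validate_image


@dataclass(frozen=True)
class PatchGeometry:
    """Geometry of the local dictionary.

    Parameters
    ----------
    patch_size : int
        Side s of the square patch; must be odd and >= 3.
    window_size : int
        Side l of the square neighborhood the atoms are drawn from; l > s.
    grid : int
        Patch centers per axis (g); the dictionary has q = g^2 atoms.
    """

    patch_size: int = 25
    window_size: int = 50
    grid: int = 5

    def __post_init__(self):
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError(
                f"patch_size must be odd and >= 3, got {self.patch_size}"
            )
        if self.window_size <= self.patch_size:
            raise ValueError(
                f"window_size ({self.window_size}) must exceed "
                f"patch_size ({self.patch_size})"
            )
        if self.grid < 1:
            raise ValueError(f"grid must be >= 1, got {self.grid}")

    @property
    def half(self) -> int:
        """Patch half-width (s-1)/2."""
        return (self.patch_size - 1) // 2

    @property
    def n_atoms(self) -> int:
        return self.grid**2

    @property
    def atom_length(self) -> int:
        return self.patch_size**2

    @property
    def margin(self) -> int:
        """Zero-padding margin guaranteeing all atoms fit: ceil((l+s)/2)."""
        return -(-(self.window_size + self.patch_size) // 2)

    def grid_offsets(self) -> np.ndarray:
        """Per-axis atom-center offsets from the window center, in pixels.

        g evenly spaced positions spanning [-l/2, l/2] endpoints included,
        rounded to the nearest pixel; for g = 1 the single offset is 0.
        """
        if self.grid == 1:
            return np.zeros(1, dtype=int)
        half_l = self.window_size / 2.0
        return np.rint(np.linspace(-half_l, half_l, self.grid)).astype(int)


@dataclass(frozen=True)
class PatchDictionary:
    """Column-stacked vectorized neighborhood patches.

    ``matrix`` is p-by-q with p = s^2 and q = g^2; column j is the row-major
    vectorization of the patch at grid position (j // g, j % g).
    """

    matrix: np.ndarray
    center: tuple[int, int]
    geometry: PatchGeometry

    def __post_init__(self):
        expected = (self.geometry.atom_length, self.geometry.n_atoms)
        if self.matrix.shape != expected:
            raise ValueError(
                f"dictionary matrix shape {self.matrix.shape} != {expected}"
            )


def pad_reference(img: np.ndarray, margin: int) -> np.ndarray:
    """Zero-pad an image by ``margin`` pixels on every side."""
    img = validate_image(img)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return img
    return np.pad(img, margin, mode="constant", constant_values=0.0)


def extract_patch(img: np.ndarray, center: tuple[int, int],
                  patch_size: int) -> np.ndarray:
    """Row-major vectorization of the s-by-s window centered at ``center``.

    Raises an IndexError when the patch would exceed the image bounds; the
    caller is expected to pad first.
    """
    img = validate_image(img)
    if patch_size < 1 or patch_size % 2 == 0:
        raise ValueError("patch_size must be odd and positive")
    r, c = center
    h = (patch_size - 1) // 2
    if r - h < 0 or c - h < 0 or r + h >= img.shape[0] or c + h >= img.shape[1]:
        raise IndexError(
            f"patch of size {patch_size} at center {center} exceeds image "
            f"bounds {img.shape}; pad the image first"
        )
    return img[r - h:r + h + 1, c - h:c + h + 1].ravel()


def build_local_dictionary(reference: np.ndarray, center: tuple[int, int],
                           geometry: PatchGeometry) -> PatchDictionary:
    """Assemble the local dictionary for window center ``center``.

    ``reference`` must already be zero-padded by at least ``geometry.margin``
    and ``center`` expressed in the padded coordinate frame.  Atom centers
    form the g-by-g grid of :meth:`PatchGeometry.grid_offsets`; columns are
    ordered row-major over the grid so that, for odd g, the exactly
    corresponding patch (offset 0, 0) sits in the middle column.
    """
    reference = validate_image(reference)
    offsets = geometry.grid_offsets()
    r0, c0 = center
    cols = np.empty((geometry.atom_length, geometry.n_atoms), dtype=np.float64)
    k = 0
    for dr in offsets:
        for dc in offsets:
            cols[:, k] = extract_patch(
                reference, (r0 + int(dr), c0 + int(dc)), geometry.patch_size
            )
            k += 1
    return PatchDictionary(matrix=cols, center=(int(r0), int(c0)),
                           geometry=geometry)
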