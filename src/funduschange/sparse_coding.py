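"""Sparse background reconstruction of the current image.

Each current-image patch x (vectorized, length p = s^2) is represented over
its local reference dictionary D by solving the lasso problem

    alpha* = argmin_alpha  ||x - D alpha||_2^2 + lambda ||alpha||_1

with the convention written exactly as above: no 1/2 factor on the quadratic
term and no 1/p scaling.  The reconstruction D alpha* is the estimated
background of the patch — the part of the current image explainable by local
reference content.  Because the coefficients are free to rescale the atoms,
a smooth multiplicative illumination change between the two images is
absorbed into the representation, while a lesion (content absent from the
reference neighborhood) is not, and survives as residual.

The solver delegates to LARS-lasso (`sklearn.linear_model.LassoLars`), which
follows the full regularization path and is exact for this piecewise-linear
problem.  sklearn parameterizes the lasso as (1/(2n)) ||x - D a||^2 +
lam' ||a||_1, so the objective above is obtained with lam' = lambda / (2 p);
this mapping is pinned by the single-atom closed form

    alpha = sign(c) * max(|c| - lambda / (2 ||d||^2), 0)   for x = c d.

The full background image B2 is assembled by sliding a patch grid over the
current image (default stride = patch side: a non-overlapping tiling, with
extra final-row/column centers so every pixel is covered), reconstructing
each patch, and averaging overlapping contributions per pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoLars

from .dictionary import (PatchDictionary, PatchGeometry,
                         build_local_dictionary, extract_patch,
                         pad_reference)
from .image_io import ImagePair, validate_image


@dataclass(frozen=True)
class SparseCode:
    """A solved sparse code: coefficients, the lambda used, and diagnostics."""

    alpha: np.ndarray
    lam: float
    objective: float
    nnz: int


def lasso_objective(x: np.ndarray, D: np.ndarray, alpha: np.ndarray,
                    lam: float) -> float:
    """Evaluate ||x - D alpha||_2^2 + lam * ||alpha||_1."""
    resid = x - D @ alpha
    return float(resid @ resid + lam * np.abs(alpha).sum())


def solve_lasso(x: np.ndarray, D: PatchDictionary | np.ndarray,
                lam: float) -> SparseCode:
    """Solve the patch lasso problem exactly as stated in the module docstring.

    Parameters
    ----------
    x : ndarray of shape (p,)
        Vectorized current patch.
    D : PatchDictionary or ndarray of shape (p, q)
        Local dictionary.
    lam : float
        Nonnegative sparsity weight; lam = 0 reduces to (minimum-norm)
        least squares on the dictionary columns.
    """
    Dm = D.matrix if isinstance(D, PatchDictionary) else np.asarray(D, float)
    x = np.asarray(x, dtype=np.float64).ravel()
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    p, q = Dm.shape
    if x.shape[0] != p:
        raise ValueError(f"signal length {x.shape[0]} != dictionary rows {p}")

    if not np.any(Dm):  # all-zero dictionary: alpha = 0 is optimal
        alpha = np.zeros(q)
    elif lam == 0:
        alpha, *_ = np.linalg.lstsq(Dm, x, rcond=None)
    else:
        sk_alpha = lam / (2.0 * p)
        model = LassoLars(alpha=sk_alpha, fit_intercept=False,
                          max_iter=4 * q + 100)
        with warnings.catch_warnings():
            # collinear atoms (e.g. constant regions) are dropped by LARS
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Dm, x)
        alpha = model.coef_.astype(np.float64)
        # Fundus dictionaries are severely ill-conditioned (overlapping
        # smooth patches are near-duplicates; zero-padded border windows
        # are exactly collinear) and LARS can silently return a suboptimal
        # or even divergent path there.  The SVD-based least-squares
        # solution and the zero vector are both feasible points of the same
        # convex objective, so evaluating all candidates and keeping the
        # lowest objective can only move the result toward the optimum;
        # on well-conditioned instances LARS is exact and always wins.
        ls_alpha, *_ = np.linalg.lstsq(Dm, x, rcond=None)
        candidates = [alpha, ls_alpha, np.zeros(q)]
        alpha = min(candidates,
                    key=lambda a: lasso_objective(x, Dm, a, lam))
    return SparseCode(
        alpha=alpha, lam=float(lam),
        objective=lasso_objective(x, Dm, alpha, lam),
        nnz=int(np.count_nonzero(alpha)),
    )


def reconstruct_patch_background(x: np.ndarray,
                                 D: PatchDictionary | np.ndarray,
                                 lam: float) -> np.ndarray:
    """Estimated background D alpha* of a single current patch."""
    Dm = D.matrix if isinstance(D, PatchDictionary) else np.asarray(D, float)
    code = solve_lasso(x, Dm, lam)
    return Dm @ code.alpha


@dataclass(frozen=True)
class BackgroundImage:
    """Reconstructed background B2 with per-pixel contribution counts."""

    pixels: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        if self.pixels.shape != self.coverage.shape:
            raise ValueError("pixels and coverage shapes differ")
        if np.any(self.coverage < 1):
            raise ValueError("coverage must be >= 1 everywhere")


def _patch_centers(dim: int, half: int, stride: int) -> list[int]:
    """Stride-spaced patch centers covering [0, dim), plus a final center."""
    centers = list(range(half, dim - half, stride))
    last = dim - 1 - half
    if not centers or centers[-1] != last:
        centers.append(last)
    return centers


def reconstruct_background(pair: ImagePair, geometry: PatchGeometry | None = None,
                           lam: float | str = "auto",
                           stride: int | None = None) -> BackgroundImage:
    """Reconstruct the background of the current image from the reference.

    Parameters
    ----------
    pair : ImagePair
        Registered (reference, current) pair; both sides must be at least
        ``patch_size`` pixels in each dimension.
    geometry : PatchGeometry, optional
        Dictionary geometry; defaults to 25x25 patches, 25 atoms on a 5x5
        grid in a 50-px window.
    lam : float or "auto"
        Sparsity weight; "auto" uses 1/m with m the pixel count of the
        current image.
    stride : int, optional
        Spacing of patch centers; defaults to ``patch_size`` (a
        non-overlapping tiling).  Smaller strides overlap patches and
        average their contributions.
    """
    geometry = geometry or PatchGeometry()
    h, w = pair.shape
    s = geometry.patch_size
    if h < s or w < s:
        raise ValueError(
            f"image {h}x{w} smaller than patch size {s}; reduce patch_size"
        )
    if stride is None:
        stride = s
    if stride < 1:
        raise ValueError("stride must be >= 1")
    lam_val = 1.0 / (h * w) if lam == "auto" else float(lam)
    if lam_val < 0:
        raise ValueError("lam must be nonnegative")

    margin = geometry.margin
    padded_ref = pad_reference(pair.reference, margin)
    half = geometry.half

    accum = np.zeros((h, w), dtype=np.float64)
    coverage = np.zeros((h, w), dtype=np.int64)
    for r in _patch_centers(h, half, stride):
        for c in _patch_centers(w, half, stride):
            x = extract_patch(pair.current, (r, c), s)
            D = build_local_dictionary(
                padded_ref, (r + margin, c + margin), geometry
            )
            patch_bg = reconstruct_patch_background(x, D, lam_val)
            accum[r - half:r + half + 1, c - half:c + half + 1] += (
                patch_bg.reshape(s, s)
            )
            coverage[r - half:r + half + 1, c - half:c + half + 1] += 1
    pixels = accum / coverage
    return BackgroundImage(pixels=pixels, coverage=coverage)
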