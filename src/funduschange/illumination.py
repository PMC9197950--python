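"""Inter-image intensity normalization and robust illumination-surface correction.

Two tools live here:

1. :func:`normalize_to` — the affine inter-image normalization that maps one
   image's intensity statistics (mean mu, population std sigma) onto
   another's::

       I_hat = (sigma_t / sigma_s) * (I - mu_s) + mu_t

   Applied in both directions it adjusts a registered pair to a common
   intensity level before differencing or background reconstruction.

2. :class:`RobustIlluminationCorrector` — a simplified homomorphic surface
   fit.  Fundus illumination is approximately a smooth multiplicative field,
   so log-intensity is fitted with a low-order 2-D polynomial by iteratively
   reweighted least squares (Tukey biweight), down-weighting high-residual
   structure (vessels, lesions) so the surface tracks illumination rather
   than anatomy.  Dividing out the fitted gain (subtracting in log domain,
   preserving mean log level) yields an illumination-corrected image whose
   difference against a corrected partner highlights true change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .image_io import validate_image


@dataclass(frozen=True)
class IntensityStats:
    """Mean and population standard deviation of an image's intensities."""

    mean: float
    std: float

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.std):
            raise ValueError("intensity statistics must be finite")
        if self.std < 0:
            raise ValueError("std must be nonnegative")


def intensity_stats(img: np.ndarray) -> IntensityStats:
    """Compute the mean/std (population definition, ddof=0) of an image."""
    img = validate_image(img)
    return IntensityStats(mean=float(img.mean()), std=float(img.std()))


def normalize_to(source: np.ndarray, target_stats: IntensityStats) -> np.ndarray:
    """Affinely map ``source`` so its mean/std equal ``target_stats`` exactly.

    The output is not clipped: thresholding happens later on difference
    images, never on normalized inputs.

    Raises
    ------
    ValueError
        If the source image is constant (std = 0), for which the map is
        undefined.
    """
    source = validate_image(source, name="source")
    mu_s = source.mean()
    sigma_s = source.std()
    if sigma_s == 0:
        raise ValueError("cannot normalize a constant image (std = 0)")
    return (target_stats.std / sigma_s) * (source - mu_s) + target_stats.mean


@dataclass(frozen=True)
class IlluminationSurface:
    """A fitted 2-D polynomial illumination surface in log-intensity.

    ``coefficients`` are ordered to match the design matrix of
    :func:`_poly_design`: all monomials ``y^i * x^j`` with ``i + j <= order``,
    row-major over (i, j).
    """

    coefficients: np.ndarray
    order: int
    shape: tuple[int, int]
    fitted_log_domain: bool = True

    def evaluate(self) -> np.ndarray:
        """Evaluate the surface over the image grid it was fitted on."""
        A = _poly_design(self.shape, self.order)
        surf = (A @ self.coefficients).reshape(self.shape)
        if not np.all(np.isfinite(surf)):
            raise ValueError("illumination surface evaluates to non-finite values")
        return surf


def _poly_design(shape: tuple[int, int], order: int) -> np.ndarray:
    """Design matrix of 2-D monomials over a [-1,1]^2-scaled pixel grid."""
    h, w = shape
    yy = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
    xx = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    cols = [
        (Y**i * X**j).ravel()
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    return np.column_stack(cols)


def _tukey_weights(residuals: np.ndarray, c: float) -> np.ndarray:
    """Tukey biweight weights, scaled by the MAD of the residuals."""
    scale = np.median(np.abs(residuals - np.median(residuals))) * 1.4826
    if scale <= 0:
        return np.ones_like(residuals)
    u = residuals / (c * scale)
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return w


class RobustIlluminationCorrector(BaseEstimator, TransformerMixin):
    """Simplified robust homomorphic illumination correction.

    Fits a polynomial surface to log-intensity by iteratively reweighted
    least squares with Tukey biweight, then corrects an image by removing
    the surface while preserving its mean log level.

    Parameters
    ----------
    order : int, default=4
        Total degree of the 2-D polynomial surface.
    robust_iters : int, default=5
        Number of reweighting iterations (the first is unweighted).
    tukey_c : float, default=4.685
        Tukey biweight tuning constant (4.685 gives 95% Gaussian efficiency).
    epsilon : float, default=1e-3
        Offset added before taking logs so zero pixels are representable.

    Attributes
    ----------
    surface_ : IlluminationSurface
        The fitted log-domain surface.
    """

    def __init__(self, order: int = 4, robust_iters: int = 5,
                 tukey_c: float = 4.685, epsilon: float = 1e-3):
        self.order = order
        self.robust_iters = robust_iters
        self.tukey_c = tukey_c
        self.epsilon = epsilon

    def fit(self, X: np.ndarray, y=None) -> "RobustIlluminationCorrector":
        self.surface_ = fit_illumination_surface(
            X, order=self.order, robust_iters=self.robust_iters,
            tukey_c=self.tukey_c, epsilon=self.epsilon,
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "surface_"):
            raise RuntimeError("corrector is not fitted")
        return correct_illumination(X, self.surface_, epsilon=self.epsilon)


def fit_illumination_surface(img: np.ndarray, order: int = 4,
                             robust_iters: int = 5, tukey_c: float = 4.685,
                             epsilon: float = 1e-3) -> IlluminationSurface:
    """Fit a robust polynomial surface to the log-intensity of ``img``.

    Iteratively reweighted least squares: an ordinary fit, then
    ``robust_iters - 1`` refits with Tukey-biweight weights computed from the
    previous residuals, so vessels and lesions (high residual) are
    down-weighted and the surface follows the slowly varying illumination.
    """
    img = validate_image(img)
    if order < 0:
        raise ValueError("order must be >= 0")
    if robust_iters < 1:
        raise ValueError("robust_iters must be >= 1")
    z = np.log(img + epsilon).ravel()
    A = _poly_design(img.shape, order)
    w = np.ones_like(z)
    coef = np.zeros(A.shape[1])
    for _ in range(robust_iters):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
        resid = z - A @ coef
        w = _tukey_weights(resid, tukey_c)
        if not np.any(w > 0):  # pathological residual distribution
            w = np.ones_like(z)
    return IlluminationSurface(coefficients=coef, order=order, shape=img.shape)


def correct_illumination(img: np.ndarray, surface: IlluminationSurface,
                         epsilon: float = 1e-3) -> np.ndarray:
    """Remove a fitted illumination surface from ``img``.

    Works in log domain: ``exp(log(img + eps) - S + mean(S)) - eps``, then a
    final multiplicative rescale so the arithmetic mean brightness of the
    output equals that of the input exactly.  A constant image is returned
    unchanged.
    """
    img = validate_image(img)
    if surface.shape != img.shape:
        raise ValueError(
            f"surface fitted on shape {surface.shape}, image has {img.shape}"
        )
    S = surface.evaluate()
    out = np.exp(np.log(img + epsilon) - S + S.mean()) - epsilon
    if out.mean() != 0:
        out = out * (img.mean() / out.mean())
    return out


def illumination_corrected_difference(reference: np.ndarray,
                                      current: np.ndarray,
                                      order: int = 4, robust_iters: int = 5,
                                      tukey_c: float = 4.685,
                                      epsilon: float = 1e-3):
    """Illumination-corrected difference of a registered pair.

    Each image is corrected with its own robust surface fit, the corrected
    reference is normalized to the corrected current's intensity statistics,
    and the signed difference (current - reference) is returned as a 2-D
    array. Used as the second pathway of the fusion detector.
    """
    corr_r = RobustIlluminationCorrector(order, robust_iters, tukey_c,
                                         epsilon).fit_transform(reference)
    corr_c = RobustIlluminationCorrector(order, robust_iters, tukey_c,
                                         epsilon).fit_transform(current)
    if corr_r.std() > 0:
        corr_r = normalize_to(corr_r, intensity_stats(corr_c))
    return corr_c - corr_r
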