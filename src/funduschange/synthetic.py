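"""Seeded generator of fundus-like registered image pairs with ground truth.

The generator composes, from a single integer seed, everything a
longitudinal fundus pair exhibits:

* a smooth bright retinal background with radial vignetting, a bright
  optic-disc-like blob, and dark curvilinear vessels drawn as random
  branching smoothed walks radiating from the disc;
* independent smooth illumination fields for the two acquisitions —
  a random low-order polynomial gain plus localized Gaussian bumps, and a
  smooth additive bias — emulating the uneven, changing illumination of
  real fundus photography;
* lesions alpha-blended into the current image (``out = (1-a) bg + a tex``
  inside an elliptical support, default a = 0.5) with the exact union of
  supports as ground truth;
* additive Gaussian sensor noise and optional sub-pixel jitter standing in
  for residual registration error.

Every component is independently switchable so tests can isolate causes:
with lesions, illumination, noise and jitter all disabled the two images
are bitwise identical.  One seed, one output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .illumination import _poly_design
from .image_io import ImagePair

# fixed per-component stream tags so each cause draws independently
_STREAMS = {"background": 11, "reference": 101, "current": 202,
            "lesions": 303, "jitter": 505,
            "noise_reference": 606, "noise_current": 707}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic fundus-pair generator.

    All intensities are on the [0, 1] scale; sizes are in pixels.
    """

    height: int = 256
    width: int = 256
    seed: int = 0
    n_vessels: int = 8
    vessel_contrast: float = 0.25
    texture_amplitude: float = 0.0
    texture_scale: float = 3.0
    n_lesions: int = 5
    lesion_size_range: tuple[int, int] = (7, 15)
    lesion_contrast: float = 0.3
    blend_alpha: float = 0.5
    gain_order: int = 2
    gain_amplitude: float = 0.2
    bias_amplitude: float = 0.05
    bump_count: int = 2
    bump_sigma: float = 30.0
    noise_sigma: float = 0.005
    jitter: float = 0.5

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be positive")
        lo, hi = self.lesion_size_range
        if lo < 1 or hi < lo:
            raise ValueError("lesion_size_range must be 1 <= lo <= hi")
        if not 0.0 <= self.blend_alpha <= 1.0:
            raise ValueError("blend_alpha must be in [0, 1]")
        for name in ("vessel_contrast", "gain_amplitude", "bias_amplitude",
                     "noise_sigma", "jitter", "bump_sigma",
                     "texture_amplitude", "texture_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_vessels < 0 or self.n_lesions < 0 or self.bump_count < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class SimPair:
    """A generated pair, its exact ground-truth mask, and realization info."""

    pair: ImagePair
    truth: np.ndarray
    metadata: dict = field(repr=False, default_factory=dict)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAMS[stream]])


def _vignette(cfg: SimConfig) -> np.ndarray:
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    sigma = 0.6 * min(h, w)
    return 0.15 + 0.6 * np.exp(-((r / sigma) ** 2))


def generate_background(cfg: SimConfig) -> np.ndarray:
    """Vignetted fundus background with optic disc and vessels."""
    img, _ = generate_background_with_vessel_map(cfg)
    return img


def generate_background_with_vessel_map(cfg: SimConfig):
    """As :func:`generate_background`, also returning the vessel centerline mask.

    With ``n_vessels = 0`` all anatomical detail — the optic-disc blob (the
    vessels' root) and the choroidal mottling — is omitted, leaving a purely
    radial, monotonically non-increasing vignette.
    """
    h, w = cfg.height, cfg.width
    img = _vignette(cfg)
    centerline = np.zeros((h, w), dtype=bool)
    if cfg.n_vessels > 0:
        rng = _rng(cfg, "background")
        # optic disc sits off-center, toward one side as in real fundus photos
        disc_r = (h - 1) / 2.0 + rng.uniform(-0.1, 0.1) * h
        disc_c = (w - 1) * rng.uniform(0.2, 0.35)
        if rng.random() < 0.5:
            disc_c = (w - 1) - disc_c
        yy, xx = np.mgrid[0:h, 0:w]
        disc_sigma = 0.05 * min(h, w)
        img = img + 0.15 * np.exp(
            -((yy - disc_r) ** 2 + (xx - disc_c) ** 2) / (2 * disc_sigma**2)
        )
        canvas = np.zeros((h, w), dtype=np.float64)
        n_steps = int(0.8 * max(h, w))
        for _ in range(cfg.n_vessels):
            theta = rng.uniform(0, 2 * np.pi)
            r, c = disc_r, disc_c
            for _ in range(n_steps):
                theta += rng.normal(0.0, 0.12)
                r += np.sin(theta)
                c += np.cos(theta)
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < h and 0 <= ci < w):
                    break
                canvas[ri, ci] = 1.0
                centerline[ri, ci] = True
        vessels = ndimage.gaussian_filter(canvas, sigma=1.2)
        if vessels.max() > 0:
            vessels = vessels / vessels.max()
        img = img - cfg.vessel_contrast * vessels
        if cfg.texture_amplitude > 0:
            # choroidal-like mottling: real fundus tissue is textured
            # everywhere, which is what makes displaced anatomy (lesions)
            # locally distinguishable from the true background
            mottle = ndimage.gaussian_filter(
                rng.standard_normal((h, w)), cfg.texture_scale)
            mottle = mottle / mottle.std()
            img = img * (1.0 + cfg.texture_amplitude * mottle)
    return np.clip(img, 0.0, 1.0), centerline


def _scaled_random_poly(rng: np.random.Generator, shape: tuple[int, int],
                        order: int, amplitude: float) -> np.ndarray:
    """Random 2-D polynomial field scaled so max |field| = amplitude."""
    A = _poly_design(shape, order)
    coef = rng.normal(size=A.shape[1])
    fieldv = (A @ coef).reshape(shape)
    peak = np.abs(fieldv).max()
    if peak == 0 or amplitude == 0:
        return np.zeros(shape)
    return fieldv * (amplitude / peak)


def apply_illumination(img: np.ndarray, cfg: SimConfig,
                       which: str = "current") -> np.ndarray:
    """Apply the acquisition-specific illumination field to an image.

    ``out = img * (1 + gain) + bias`` clipped to [0, 1], where gain is a
    random polynomial of order ``gain_order`` scaled to max amplitude
    ``gain_amplitude`` plus ``bump_count`` Gaussian bumps of width
    ``bump_sigma`` and amplitude ``gain_amplitude`` (random sign), and bias
    is a random first-order polynomial of max amplitude ``bias_amplitude``.
    The reference and current draws are independent.
    """
    if which not in ("reference", "current"):
        raise ValueError("which must be 'reference' or 'current'")
    img = np.asarray(img, dtype=np.float64)
    if cfg.gain_amplitude == 0 and cfg.bias_amplitude == 0 and cfg.bump_count == 0:
        return img.copy()
    rng = _rng(cfg, which)
    h, w = img.shape
    gain = _scaled_random_poly(rng, (h, w), cfg.gain_order, cfg.gain_amplitude)
    if cfg.bump_count > 0 and cfg.gain_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(cfg.bump_count):
            br = rng.uniform(0.15 * h, 0.85 * h)
            bc = rng.uniform(0.15 * w, 0.85 * w)
            sign = rng.choice([-1.0, 1.0])
            gain = gain + sign * cfg.gain_amplitude * np.exp(
                -((yy - br) ** 2 + (xx - bc) ** 2) / (2 * cfg.bump_sigma**2)
            )
    bias = _scaled_random_poly(rng, (h, w), 1, cfg.bias_amplitude)
    return np.clip(img * (1.0 + gain) + bias, 0.0, 1.0)


def _make_lesion(rng: np.random.Generator, size: int,
                 shape: tuple[int, int], occupied: np.ndarray):
    """One elliptical lesion support placed without border or mutual overlap."""
    h, w = shape
    margin = size + 2
    if 2 * margin >= min(h, w):
        raise ValueError(f"lesion of size {size} does not fit in {shape}")
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(100):
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        a = (size / 2.0) * rng.uniform(0.7, 1.0)
        b = (size / 2.0) * rng.uniform(0.7, 1.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        support = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if support.any() and not (support & occupied).any():
            return support, {"center": (float(cy), float(cx)), "size": int(size),
                             "axes": (float(a), float(b)),
                             "angle": float(theta)}
    raise RuntimeError("could not place a lesion without overlap "
                       "after 100 attempts")


def _displacement(rng: np.random.Generator, support: np.ndarray,
                  shape: tuple[int, int]) -> tuple[int, int]:
    """Integer offset moving the support to a distinct in-bounds location."""
    h, w = shape
    ys, xs = np.where(support)
    span = max(ys.max() - ys.min(), xs.max() - xs.min()) + 1
    for _ in range(100):
        dy = int(rng.integers(-h + 1, h))
        dx = int(rng.integers(-w + 1, w))
        if max(abs(dy), abs(dx)) < span:  # too close: texture ~ background
            continue
        if (ys + dy).min() >= 0 and (ys + dy).max() < h \
                and (xs + dx).min() >= 0 and (xs + dx).max() < w:
            return dy, dx
    return 0, 0  # degenerate geometry: fall back to in-place texture


def lesion_texture(img: np.ndarray, support: np.ndarray,
                   offset: tuple[int, int], contrast: float) -> np.ndarray:
    """Texture blended into a lesion: displaced anatomy plus a brightness
    offset, with a Gaussian-smoothed (sigma = 1 px) edge profile.

    Copying image content from a distant location emulates pasting a patch
    of the same retina elsewhere: the pasted anatomy does not match the
    local reference neighborhood, which is what makes a lesion a lesion.
    The displaced content is recentered to the local brightness level
    (seamless-paste convention) before the contrast offset is added, so a
    lesion's mean intensity shift is ``blend_alpha * contrast`` by
    construction rather than depending on where the patch came from.
    Returns the full-frame texture field T with T = img outside the
    support, so the blend is out = (1 - a) * img + a * T inside.
    """
    dy, dx = offset
    displaced = np.roll(np.roll(img, -dy, axis=0), -dx, axis=1)
    if support.any():
        displaced = displaced - displaced[support].mean() + img[support].mean()
    profile = ndimage.gaussian_filter(support.astype(np.float64), 1.0)
    peak = profile.max()
    if peak > 0:
        profile = profile / peak
    return img + (displaced + contrast - img) * profile


def _inject_lesions_meta(img: np.ndarray, cfg: SimConfig):
    rng = _rng(cfg, "lesions")
    h, w = img.shape
    truth = np.zeros((h, w), dtype=bool)
    out = img.astype(np.float64).copy()
    lesions = []
    lo, hi = cfg.lesion_size_range
    for _ in range(cfg.n_lesions):
        size = int(rng.integers(lo, hi + 1))
        support, meta = _make_lesion(rng, size, (h, w), truth)
        offset = _displacement(rng, support, (h, w))
        texture = lesion_texture(out, support, offset, cfg.lesion_contrast)
        a = cfg.blend_alpha
        out = np.where(support, (1.0 - a) * out + a * texture, out)
        truth |= support
        meta["area"] = int(support.sum())
        meta["offset"] = [int(offset[0]), int(offset[1])]
        lesions.append(meta)
    return out, truth, lesions


def inject_lesions(img: np.ndarray, cfg: SimConfig):
    """Blend ``n_lesions`` elliptical lesions into ``img``.

    Returns the lesioned image and the exact binary ground-truth mask (the
    union of the elliptical supports).
    """
    out, truth, _ = _inject_lesions_meta(img, cfg)
    return out, truth


def generate_pair(cfg: SimConfig) -> SimPair:
    """Generate a full registered pair with ground truth from one seed.

    Both images share the same underlying anatomy; the current image
    additionally carries the lesions (recorded in the truth mask), an
    independent illumination draw, independent noise, and optional
    sub-pixel jitter.
    """
    background = generate_background(cfg)
    lesioned, truth, lesions = _inject_lesions_meta(background, cfg)

    if cfg.jitter > 0:
        jrng = _rng(cfg, "jitter")
        shift = jrng.uniform(-cfg.jitter, cfg.jitter, size=2)
        lesioned = ndimage.shift(lesioned, shift, order=1, mode="nearest")
    else:
        shift = np.zeros(2)

    reference = apply_illumination(background, cfg, "reference")
    current = apply_illumination(lesioned, cfg, "current")
    if cfg.noise_sigma > 0:
        reference = reference + _rng(cfg, "noise_reference").normal(
            0.0, cfg.noise_sigma, reference.shape)
        current = current + _rng(cfg, "noise_current").normal(
            0.0, cfg.noise_sigma, current.shape)
        reference = np.clip(reference, 0.0, 1.0)
        current = np.clip(current, 0.0, 1.0)

    metadata = {"config": asdict(cfg), "lesions": lesions,
                "jitter_shift": [float(s) for s in shift]}
    return SimPair(pair=ImagePair(reference=reference, current=current),
                   truth=truth, metadata=metadata)
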