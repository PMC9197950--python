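# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite demonstrates.

## Background reconstruction by local sparse representation

For a registered pair (reference I₁, current I₂) of grayscale images on the
[0, 1] scale, the detector models the *background* of I₂ — the part
explainable by local reference content — one patch at a time.  The patch
x ∈ R^p (p = s², s odd, default 25) centered at pixel P of I₂ is coded over
the dictionary D ∈ R^(p×q) of q = g² reference patches whose centers form a
uniform g×g grid (default 5×5) spanning the l×l window (default 50 px)
centered at the corresponding reference pixel P′ = P, by minimizing

    f(α) = ‖x − Dα‖²₂ + λ‖α‖₁ ,      λ = 1/m by default (m = pixels of I₂).

Atoms are used raw — not mean-centered, not ℓ₂-normalized — because
multiplicative illumination differences are meant to be absorbed by
coefficient scaling, which centering would destroy.  Coefficients are
unconstrained in sign.  The objective carries no ½ or 1/p factor; the
delegated solver (scikit-learn `LassoLars`, parameterized as
(1/(2n))‖·‖² + λ′‖·‖₁) is called with λ′ = λ/(2p), a mapping pinned by the
single-atom closed form α = sign(c)·max(|c| − λ/(2‖d‖²), 0) for x = c·d.

**Numerical robustness.** Fundus dictionaries are severely ill-conditioned:
overlapping smooth patches are near-duplicates, and windows reaching into
the zero-padded border contain exactly collinear (or zero) atoms.  LARS can
return a suboptimal or divergent path there.  `solve_lasso` therefore
evaluates the SVD least-squares solution and the zero vector alongside the
LARS solution and keeps whichever attains the lowest objective — a pure
objective-based selection among feasible points of the same convex problem;
on well-conditioned instances LARS is exact and always wins.

**Assembly.** Patch centers are placed on a stride-spaced grid (default
stride = s, a non-overlapping tiling) with final-row/column centers added
so every pixel is covered; overlapping reconstructions are averaged via a
per-pixel coverage count.  The reference is zero-padded by ⌈(l+s)/2⌉ before
dictionary extraction.  Before reconstruction the reference is affinely
normalized to the current image's mean and (population) standard deviation,
the standard inter-image intensity adjustment for registered pairs; it is
exposed as `normalize` and uses the population std so the normalized
moments are exact for any image size.

## Change maps, masks, fusion

The signed difference I₂ − B₂ is reduced to an absolute map rescaled by its
maximum, so the binarization thresholds (defaults 0.3 for the plain
detector, 0.15 for the fusion pathway) are exposure-independent.  One
guard: when the peak absolute difference is below one 8-bit quantization
step (1/255), the map is divided by that floor instead of its peak.
Rescaling a machine-noise map to full range would manufacture change out
of numerically perfect reconstructions; with the floor, identical pairs
yield empty masks, which is the behavior the identity null requires.

Masks are cleaned by opening (disk radius 1), closing (radius 3) and
removal of 8-connected components under 20 px.  These defaults target
speckle at the few-hundred-pixel image scale and are configuration keys,
not constants.

**Large lesions.** The sparse model partially explains the interior
brightness shift of a lesion larger than a patch (a plateau over a smooth
background is an affine function of the local anatomy), so plain
background subtraction marks large lesions mostly along their boundary.
The fusion pathway handles this: the cleaned detection mask is consolidated
into a region of interest — morphological closing with a disk of the patch
half-width (the detector's own spatial resolution: detections within one
patch belong to the same region) followed by hole filling — and gates an
illumination-corrected difference image, which retains the full interior
contrast.  The gated map is re-thresholded at 0.15 and cleaned.

**Illumination-corrected difference.** Each image is corrected with its own
robust homomorphic surface fit: a 2-D polynomial (default total degree 4)
fitted to log(I + ε), ε = 10⁻³, by iteratively reweighted least squares
with Tukey biweight (c = 4.685, 95% Gaussian efficiency; scale = 1.4826 ×
MAD), 5 iterations, so vessels and lesions are down-weighted and the
surface tracks illumination.  Correction removes the surface in the log
domain and rescales to preserve the mean brightness.  This is a simplified
correction: the published fundus illumination models additionally segment
anatomy before fitting, which is out of scope here; the fusion pathway only
needs *an* illumination-suppressed difference, and degree-4 polynomials
capture the smooth fields the generator produces.  Localized artifacts
narrower than the polynomial can represent (e.g. Gaussian bumps of width
~30 px) survive correction — which is precisely what the gating removes.

## Evaluation

Confusion counts are per-pixel; TPR = TP/(TP+FN), FPR = FP/(TN+FP),
precision = TP/(TP+FP), recall = TPR, with 0/0 → 0.  ROC and PR curves
sweep all distinct score values (scikit-learn, no intermediate dropping);
AUC is trapezoidal over (FPR, TPR).  The PR area is reported as
interpolated average precision (area under the precision envelope), the
standard AP definition; the raw step-curve variant is available via
`interpolated_map=False`.  IOU of two empty masks is defined as 1.  An
optional field-of-view mask excludes the extra-retinal surround from all
counts; by default every pixel counts, matching how the synthetic pairs
are generated (no hard black surround).

## Synthetic pairs

The generator composes, from one integer seed (independent substreams per
component, so each nuisance is switchable in isolation):

- **Background**: radial Gaussian vignette (bright center 0.75 falling to
  0.15), a bright optic-disc blob, and dark curvilinear vessels drawn as
  random-walk centerlines from the disc, Gaussian-smoothed (σ = 1.2 px),
  at contrast 0.25.  With `n_vessels = 0` all anatomical detail is omitted
  and the background is a pure monotone vignette.  Optional multiplicative
  mottling (`texture_amplitude`, default 0) adds choroidal-like texture.
- **Illumination** (independent draws for reference and current):
  out = img·(1+gain) + bias, where gain is a random polynomial (default
  order 2) scaled to max |gain| = 0.2 plus 2 Gaussian bumps (σ = 30 px,
  amplitude 0.2, random sign), and bias is a random first-order polynomial
  scaled to max 0.05; clipped to [0, 1].
- **Lesions**: elliptical supports (default 5 lesions of 7–15 px for the
  small-lesion condition; one 41×41 for the large-lesion condition) blended
  as out = (1−a)·background + a·texture with a = 0.5.  The texture is a
  copy of the image's own anatomy displaced from a distant location —
  emulating the pasted-patch simulation protocol — recentered to the local
  brightness level and offset by the lesion contrast (0.3), with a
  Gaussian-smoothed (σ = 1 px) edge.  Recentering makes the mean intensity
  shift exactly a·contrast regardless of where the patch came from.  The
  ground-truth mask is the exact union of supports.
- **Noise and jitter**: additive Gaussian noise (σ = 0.005) and sub-pixel
  translation of the current image (≤ 1 px, default 0.5, bilinear),
  standing in for sensor noise and residual registration error.

Defaults are 256×256 pixels — a desk-scale stand-in for the few-hundred-
pixel clinical images the method targets — and the parameter values above
are the study conditions used throughout the tests and the acceptance
script.

**What passing tests do and do not show.**  The generator's illumination is
genuinely smooth and its anatomy identical between acquisitions up to the
modeled nuisances; real longitudinal pairs add registration failures beyond
1 px, anatomical change that is not pathology (vessel caliber, disc
appearance), compression artifacts, and illumination with sharper structure
than low-order polynomials plus bumps.  Results on these fixtures
demonstrate the mechanism — illumination absorbed by local sparse coding
while unexplained content survives — not clinical performance.

## Design choices made where the design was open

- **Grayscale conversion**: BT.601 luma by default; a green-channel option
  is provided because green carries the most vascular contrast in fundus
  photography.  Conversion rule changes results only marginally and is a
  config key.
- **Atom layout**: the q patches are placed on a uniform grid including the
  window border (spacing l/(g−1), rounded per center, banker's rounding at
  ties).  For odd g the exactly corresponding patch is an atom, which is
  what makes identical pairs reconstruct exactly.
- **Stride**: default non-overlapping tiling; smaller strides overlap and
  average, trading runtime for smoother backgrounds.
- **Thresholds on rescaled maps**: the printed thresholds are only
  meaningful on a defined scale; max-rescaling (with the quantization
  floor above) makes them exposure-independent.
- **Determinism**: the solver path is deterministic; generator streams are
  seeded; repeated runs are bitwise identical.

## Known limitations

- Large-lesion detection depends on the fusion pathway; plain background
  subtraction finds boundaries only (measured IOU 0.02–0.3 versus 0.75–1.0
  with fusion on 41×41 lesions).
- The surface-fit correction assumes multiplicative smooth illumination;
  additive glare or specular highlights are not modeled.
- The detector assumes pre-registered pairs; misregistration beyond ~1 px
  produces vessel-edge residuals that the mask cleaning only partly
  removes.
- Two time points only; no longitudinal series modeling.

## Problem sizes

The test suite and acceptance script run 50 simulated pairs per scenario
(20 for the fusion comparison) at 256×256 with the default 25×25/50-px
geometry, and 200 random solver instances up to p = 625, q = 25; the full
suite completes in roughly two minutes on one CPU, the acceptance script in
about two more.
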