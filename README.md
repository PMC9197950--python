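# funduschange

Unsupervised change detection for registered retinal fundus image pairs,
built on sparse-representation background reconstruction.

## The problem

Longitudinal fundus photography compares an earlier (*reference*, I₁) and a
later (*current*, I₂) image of the same retina to find new lesions.  After
registration, the obstacle is illumination: the two acquisitions differ by
smooth, spatially varying gain and bias fields that swamp naive differencing
— most of |I₂ − I₁| is lighting, not pathology.

## The method

Each patch **x** of the current image (vectorized, s×s pixels) is
represented over a *local dictionary* **D** whose q columns are the
vectorized patches extracted on a g×g grid spanning an l×l neighborhood of
the corresponding location in the reference image.  The representation is
the lasso

```
α* = argmin_α ‖x − Dα‖²₂ + λ‖α‖₁
```

solved by LARS-lasso, with λ = 1/m (m = image pixel count) by default.
Because the coefficients are free to rescale the atoms, a smooth
illumination change between the two images is absorbed into the
representation; content that is absent from the reference neighborhood — a
lesion — is not.  The reconstruction **Dα*** therefore plays the role of
the *background* of the current image, assembled patch-by-patch into B₂,
and the residual I₂ − B₂ is the change evidence.  The absolute difference
is rescaled to [0, 1], thresholded (0.3 by default), and cleaned
morphologically to give a binary change mask.

Default geometry: 25×25-pixel patches, 25 atoms on a 5×5 grid inside a
50-pixel window.

For **large lesions**, whose interior brightness shift the local dictionary
can partially explain, a fusion pathway (`mode="fusion"`) gates an
illumination-corrected difference image (robust polynomial surface fit in
the log domain, each image corrected independently, then intensity-
normalized) with the sparse-detection mask — consolidated into a filled
region of interest — and re-thresholds at 0.15.

The package follows scikit-learn conventions: `SRCChangeDetector` is fitted
on the reference image (`fit`), scores the current image
(`decision_function`) and predicts the binary mask (`predict`);
`RobustIlluminationCorrector` is a fit/transform estimator.  A seeded
synthetic generator (`funduschange.synthetic`) produces fundus-like pairs —
vignetted background, curvilinear vessels, independent illumination fields,
alpha-blended lesions with exact ground truth — for testing and evaluation.

## Worked example

```python
import numpy as np
from funduschange import (SRCChangeDetector, SimConfig, generate_pair,
                          evaluate_masks)

cfg = SimConfig(seed=42, jitter=0.0)          # 256x256 pair, 5 small lesions
sim = generate_pair(cfg)

det = SRCChangeDetector().fit(sim.pair.reference)
mask = det.predict(sim.pair.current)
score = det.change_map_.absolute

report = evaluate_masks(mask, sim.truth, score_map=score)
print(f"mask area         : {mask.mean():.2%}")
print(f"IOU vs truth      : {report['iou']:.3f}")
print(f"pixel AUC         : {report['auc']:.3f}")
print(f"precision / recall: {report['precision']:.3f} / {report['recall']:.3f}")
```

prints

```
mask area         : 0.75%
IOU vs truth      : 0.666
pixel AUC         : 0.978
precision / recall: 0.793 / 0.806
```

i.e. on a pair whose illumination differs by a ±20% gain field plus ±0.05
bias, the detector marks 0.75% of the image, overlapping the five blended
lesions with IOU 0.67 while the soft score map ranks lesion pixels above
background with AUC 0.98.  The same pipeline is available from the shell:

```sh
funduschange simulate -o pair/ --seed 42
funduschange detect pair/reference.png pair/current.png -o out/
funduschange evaluate out/mask.png pair/truth.png
```

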