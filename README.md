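# lymphopet

Semi-automated measurement of lymphoma size on PET/CT, for researchers who
want reproducible metabolic tumor metrics and a tested implementation of the
agreement statistics used to compare automated readings with an expert's.

Treatment response in Hodgkin's and Non-Hodgkin's lymphoma is commonly
monitored on ¹⁸F-FDG PET/CT with a handful of size metrics: the metabolic
tumor maximum diameter (MTDmax, mm) and maximum area (MTAmax, mm²) on a
single transverse slice, the metabolic tumor volume (MTV, mm³) over all
slices, and the maximum standardized uptake value (SUVmax).  This package
implements the full measurement chain:

* **Adaptive-threshold PET segmentation.**  An expert supplies an ellipse
  around the lesion on the "central" transverse slice.  A 3-pixel-wide
  background ring at the ellipse border yields a reference intensity *m*;
  pixels inside the ellipse with value > *f·m* (default *f* = 0.5) form the
  tumor ROI, and the elliptical footprint is projected automatically to the
  slices above and below, each with its own ring, until the lesion
  disappears.  MTV = Σ slice ROIs × voxel volume.
* **CT segmentation** (wavelet denoising → fuzzy C-means clustering → Potts
  Markov-random-field refinement by iterated conditional modes) producing
  the anatomic counterparts Dmax/Amax/TV.
* **Response classification.**  Percent change Δ = (post − pre)/pre × 100 of
  any metric is mapped onto four ordered classes: CMR (Δ = −100, code 3),
  PMR (−100 < Δ ≤ −30, code 2), SMD (−30 < Δ < 20, code 1), PMD (Δ ≥ 20 or
  new lesions, code 0).
* **Agreement statistics.**  Bland–Altman bias and limits of agreement
  (bias ± 1.96·SD of paired differences), linearly weighted Cohen kappa
  (weights w₍ᵢⱼ₎ = 1 − |i−j|/(k−1)) with the Fleiss–Cohen–Everitt
  asymptotic 95% CI, a threshold sweep over {30, 40, 50, 60, 70}% scored by
  Dice against ground-truth outlines, and the two-sample t / chi-square
  cohort comparisons.
* **Digital phantoms.**  Ellipsoidal hot lesions with analytic ground
  truth on a 168×168, 4.06×4.06×2.5 mm PET-like grid, optional Gaussian
  PSF and noise, paired pre/post volumes with exact known Δ, and simulated
  expert-vs-CAD measurement cohorts — so every step of the chain can be
  validated end to end without patient data.

## Worked example

```python
import numpy as np
from lymphopet import (PhantomSpec, make_phantom, suggest_roi, project_and_segment,
                       measure_mask, make_pre_post_pair, percent_change, classify,
                       weighted_kappa)

spec = PhantomSpec(seed=1)                       # 15×25×20 mm ellipsoid, SUV 8
v, truth = make_phantom(spec)
mask = project_and_segment(v, suggest_roi(spec, truth))
m = measure_mask(mask, image=v)
```

prints, via the obvious format strings:

```
MTV        31648.5 mm^3   (analytic   31415.9 mm^3)
MTDmax       46.29 mm     (truth        46.29 mm)
MTAmax      1516.5 mm^2
SUVmax         8.0
slices          12
```

The segmented MTV is within 0.8% of the analytic ellipsoid volume, the
maximum diameter is exact on this grid, and the lesion spans 12 transverse
slices — inside the 5–20 slice range typical of clinical cases.  Halving
the lesion volume in a paired study and re-measuring:

```python
pre, post, _ = make_pre_post_pair(spec, volume_scale=0.5)
mtv_pre  = measure_mask(project_and_segment(pre[0],  suggest_roi(spec, pre[1]))).mtv_mm3
mtv_post = measure_mask(project_and_segment(post[0], suggest_roi(spec, post[1]))).mtv_mm3
d = percent_change(mtv_pre, mtv_post)            # -> -50.0 %
classify(d)                                      # -> PMR (code 2)

weighted_kappa(np.array([[10, 5], [5, 10]])).kappa   # -> 0.3333
```

The same operations are available from the shell via the `lymphopet` CLI
(`simulate`, `segment-pet`, `segment-ct`, `measure`, `classify`, `agree`,
`sweep`); every run writes a `run.json` with its configuration and seed.

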