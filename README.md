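# fiberbrush

A virtual imaging trial for an **end-expandable ("brush") fiber-optic
microendoscopy probe**. High-resolution microendoscopy (HRME) images
epithelium through a fused fiber bundle with a sub-millimetre field of view;
an end-expandable probe spreads its unfused fiber strands over a much wider
field, at the cost of sampling the tissue sparsely. This package simulates
that trade-off computationally — so probe geometries can be compared before
any hardware is built — and evaluates how much of the lost detail a small
super-resolution network recovers.

The pipeline, exercised entirely on synthetic phantoms:

1. **phantom** — labeled HRME-like images: bright elliptical nuclei placed
   by a spatial Poisson process on a dim background, with higher nuclear
   density and pleomorphism in the "neoplastic" class; optional fused-bundle
   comb artifact; Gaussian sensor noise.
2. **preprocess** — standardize to 960×1280 px, remove the comb pattern with
   a Gaussian filter (σ = 2 px), enhance contrast with CLAHE (clip 0.005).
3. **degrade** — the probe model. The image is tiled into s×s-px
   field-of-view (FOV) blocks; each fiber reports the mean over an m×m-px
   region of interest (ROI) centered in its block, optionally displaced by a
   random per-block offset of at most d px per axis; the block is filled
   with that mean to reconstitute the low-resolution (LR) image. Geometry is
   given in µm at 2 µm/px: m is the fiber diameter, s the inter-fiber
   distance, d the deformation offset.
4. **srcnn** — a three-layer super-resolution CNN
   (9×9×64 → 1×1×32 → 5×5×1 with leaky-ReLU, 8,129 parameters, "same"
   padding), trained with Adam on MSE over aligned random LR/HR patch pairs,
   keeping the best-validation checkpoint. Implemented in pure numpy and
   fully deterministic under a seed.
5. **iq** — PSNR (10·log₁₀(peak²/MSE)) and SSIM (11×11 Gaussian window,
   σ = 1.5, K₁ = 0.01, K₂ = 0.03), plus a one-at-a-time sweep harness over
   d, s and m.
6. **readerstats** — reader-study analytics: confusion counts,
   sensitivity/specificity/accuracy with confidence stratification, unpaired
   t-tests between viewing conditions, and equivalence sample-size planning
   for binary calls.

## Worked example

```python
import dataclasses
import numpy as np
from fiberbrush import phantom, degrade, srcnn, iq

# 50 phantoms, half "neoplastic", 128x128 px at 2 um/px
images, _ = phantom.generate_dataset(50, 0.5, seed=7,
                                     height_px=128, width_px=128)

# sparse acquisition at the baseline geometry: m=4 um, s=8 um, d=0
p = degrade.DegradationParams(m_um=4, s_um=8, d_um=0)
pairs = [(degrade.degrade(li.image,
                          dataclasses.replace(p, seed=i)).lr_image, li.image)
         for i, li in enumerate(images)]
train, test = pairs[:40], pairs[40:]

tc = srcnn.TrainConfig(learning_rate=2e-3, epochs=30, batch_size=8,
                       patches_per_image=6, patch_size_px=64, seed=3)
model = srcnn.train(srcnn.build_model(seed=3), train[8:], train[:8], tc)

for name, fn in [("PSNR", iq.psnr), ("SSIM", iq.ssim)]:
    lr = np.mean([fn(hr, lr_img) for lr_img, hr in test])
    sr = np.mean([fn(hr, srcnn.super_resolve(model, lr_img))
                  for lr_img, hr in test])
    print(f"{name}: LR {lr:.3f} -> SR {sr:.3f}")
```

prints

```
PSNR: LR 28.297 -> SR 30.413
SSIM: LR 0.680 -> SR 0.702
```

i.e. at the baseline probe geometry the network recovers about 2 dB of PSNR
and raises SSIM by ~0.02 on held-out phantoms, after a deliberately short
CPU training run. Everything is also reachable from the `fiberbrush` CLI
(`phantom`, `preprocess`, `degrade`, `train`, `superres`, `evaluate`,
`readerstats`).

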