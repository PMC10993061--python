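# Methods

## The degradation model

An end-expandable probe replaces the fused fiber bundle of a conventional
microendoscope with loose strands spread over the tissue. Each strand
integrates fluorescence over its core footprint and reports one intensity;
the tissue between strands is never sampled. We model this on the image
grid (2 µm/px): the high-resolution (HR) frame is tiled into s_px × s_px
FOV blocks anchored at pixel (0, 0) in a rectangular lattice, and each
block's fiber reports the mean over an m_px × m_px ROI. The ROI's top-left
corner sits at `floor((s_px − m_px)/2)` inside its block (deterministic,
biased by at most half a pixel when the parity is odd), is displaced by a
per-block random offset, and is intersected with the image bounds before
averaging. The block is then filled with that mean, giving the
reconstituted low-resolution (LR) frame.

Parameters, all in µm and converted by round-half-up at `pixel_size_um`
(default 2):

| parameter | meaning | default |
|---|---|---|
| `m_um` | fiber (ROI) diameter | 4 |
| `s_um` | inter-fiber distance (FOV block side) | 8 |
| `d_um` | maximum deformation offset per axis | 0 |

The offset models strand flexibility. Only its maximum is physically
specified, so each axis is independent discrete-uniform on
{−d_px, …, +d_px}, drawn per block. Offsets are resampled per image from
the parameter seed; passing an explicit offset table freezes one probe
configuration across a dataset (and is how the tests enumerate offsets
exhaustively). dx and dy share a single bound d; the per-axis
generalization would be a trivial extension but no experiment separates
them. If an offset pushes a ROI entirely outside the frame (only possible
when d_px is on the order of s_px), the fiber falls back to its unshifted
clipped ROI rather than reporting nothing; reflecting offsets inward was
rejected because it would distort the offset distribution. Edge blocks of
non-divisible frames are processed on their clipped extents — 960 and 1280
are not divisible by every s_px of interest — rather than dropped.

Structural consequences, all asserted in tests: the LR image is constant
within each block, bounded by the HR range, a fixed point on constant
images, idempotent at d = 0, and exactly mean-preserving when m = s on
divisible frames. Information loss is monotone in s at fixed m, d.

Rectangular tiling is a deliberate simplification; a radial/hexagonal
expansion geometry, optical PSF, illumination falloff and fiber cross-talk
are out of scope.

## Phantoms

The clinical counterpart of this pipeline reads stained epithelium in which
nuclear density, size and pleomorphism separate neoplastic from
non-neoplastic tissue. The phantom generator reproduces exactly that
statistical structure and nothing more: nucleus centers follow a
homogeneous spatial Poisson process with intensity
`nucleus_density_per_mm2`, each nucleus is an anti-aliased filled ellipse
(radius truncated-normal, orientation uniform, eccentricity uniform up to a
cap), overlapping nuclei combine by maximum intensity to avoid clipping
artifacts, edges are softened with a σ = 1 px Gaussian, and zero-mean
Gaussian noise is added before clipping to [0, 1]. Sensor noise is a single
additive parameter; Poisson shot noise would add a second parameter without
changing what the pipeline can test.

Class presets are free parameters, not biological claims: the neoplastic
preset uses 350 nuclei/mm² with radius 5 ± 1.6 µm, the non-neoplastic
150 nuclei/mm² with 4 ± 0.8 µm — higher density (crowding) and double the
radius SD (pleomorphism). The optional fused-bundle comb artifact (hex
lattice of 4 µm cores, cladding attenuation) exists to exercise the
de-combing filter and is off in pipeline runs, since preprocessing removes
it immediately.

What phantoms do **not** model: tissue texture, motion blur, defocus,
illumination inhomogeneity, or any quality-control failure mode. Passing
tests therefore demonstrate the pipeline's internal consistency and the
direction and rough magnitude of super-resolution benefit under controlled
degradation — not clinical performance.

## Preprocessing

Standardization to 960×1280 px uses center-crop / symmetric reflect-pad
rather than resampling, which would silently rescale the µm-per-pixel
geometry the degradation model depends on. De-combing is a normalized
Gaussian (σ = 2 px, reflect boundary, truncated at 4σ): linear and
mean-preserving. CLAHE uses the normalized clip-limit convention (fraction
of a tile's pixel count; default 0.005) with an 8×8 tile grid — the
convention under which a clip limit of 0.005 is meaningful — and is applied
before degradation, so the network trains on contrast-enhanced targets.

## SRCNN

Three convolutional layers — 9×9 with 64 filters, 1×1 with 32, 5×5 with 1 —
interspersed with leaky ReLUs (negative slope 0.2, configurable) and no
nonlinearity after the last layer; 8,129 parameters for the default shapes.
Because the LR image lives on the HR grid, no upsampling layer is needed,
and "same" zero padding keeps SR and HR directly comparable pixelwise
(the original SRCNN's valid padding would shrink the frame). Weights are
He-normal, biases zero, all seeded; inputs are [0, 1] floats with no mean
subtraction.

The implementation is pure numpy with manually derived gradients: training
convolutions run as im2col + matmul (patches are small), the backward pass
through a convolution is the same-padded correlation with the spatially
flipped, channel-transposed kernel (exact for odd kernels), and full-frame
inference loops over channels with `scipy.ndimage.correlate`, whose output
matches the im2col path to float32 precision. Adam is the standard
bias-corrected form (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Training is MSE on
aligned random patch pairs, validation once per epoch, and the returned
weights are those of the epoch with minimum validation loss. Given a seed
the whole procedure is deterministic.

The reference training protocol (learning rate 1e-4, 300 epochs, batch 8,
ten 512×512 patches per image) is the configuration default and is
config-reachable, but every tested run is scaled down to CPU desk scale.
The standard reduced-scale trial used by the test suite and
`scripts/acceptance.py` is: 128×128 phantoms, 40 training pairs (8 held for
validation) and 10 test pairs at the baseline geometry (m = 4 µm, s = 8 µm,
d = 0), six 64×64 patches per image, 30 epochs, batch 8, learning rate
2e-3. The larger learning rate compensates for the short schedule; the
assertion made of such runs is always the inequality SR > LR on both
metrics, never an exact loss, so it is robust to floating-point backend
variation.

## Image quality metrics

PSNR is `10·log₁₀(peak²/MSE)` with peak 1.0 on normalized floats
(configurable); identical images report +∞. SSIM follows the original
formulation: 11×11 Gaussian window (σ = 1.5, truncated at 3.5σ), weighted
population statistics, stabilizers K₁ = 0.01 and K₂ = 0.03 on the declared
dynamic range, averaged over the region where the window fits. Both are
authored here and cross-checked in tests against scikit-image's
implementations to 1e-6. The sweep harness varies one parameter at a time
from the baseline; infeasible points (m > s) are recorded and skipped.
Aggregates report mean, SD and a t-based 95% CI per condition.

## Reader statistics

The positive class is neoplastic throughout. Confusion counts partition
exactly across confidence strata; metrics with zero denominators are
reported as absent rather than zero so pooled summaries are never silently
biased. The HR-vs-SR comparison uses the pooled-variance Student t-test by
default ("unpaired" leaves the variant open; Welch is available via
`equal_var=False`), with the degenerate all-equal case defined as p = 1.

Equivalence sample size uses the two-proportion, equal-variance normal
approximation without continuity correction,
`n ≥ (z₁₋α/₂ + z₁₋β)² · 2p(1−p) / limit²`, with the assumed proportion an
explicit argument: published studies rarely print the variance estimate
behind their quoted n, so no particular published value is claimed as
reproducible. The bundled demonstration gold set fixes the 120-image,
78/42 class mix used by the reader-study tooling.

## Known limitations

- Phantoms are statistically, not visually, HRME-like; absolute PSNR/SSIM
  values are not comparable to clinical data.
- The reduced-scale SRCNN runs establish direction of improvement, not the
  ceiling of a full 300-epoch GPU training.
- The degradation lattice is rectangular; expanding probes are likely
  radial.
- Reader simulation draws independent Bernoulli calls and cannot model
  reader bias, case difficulty correlation, or learning effects.
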