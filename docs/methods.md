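# Methods

## Model and estimators

A magnitude MR image v is modelled pixelwise as the modulus of a complex
signal with independent Gaussian noise in both channels,
v(i) = √((u(i)+n₁(i))² + n₂(i)²), n₁, n₂ ~ N(0, σ), so the noise is Rician
and the squared magnitude is biased: E[v²] = u² + 2σ².

All four filters estimate u(i) as a convex combination of window
intensities, û(i) = Σ_{j∈Sᵢ} w(i,j)v(j).  The weight of candidate j is a
Gaussian kernel in a squared patch distance D²(i,j):

* **nlm / unlm** — D² is the plain squared Euclidean distance between the
  r×r patches around i and j;
* **nlm-dct / unlm-dct** — D² is the squared distance between the first d
  zigzag-ordered coefficients of the patches' orthonormal 2-D DCT.

The distance is **not** divided by the patch size M = r², so h is large in
absolute terms; for two patches of the same tissue, D² concentrates around
2σ²k with k the distance dimension (M full space, d subspace), which is
why useful h values scale like σ√(2k).  The DCT is the type-II transform
with orthonormal scaling (`scipy.fft.dctn(..., norm="ortho")`), under which
Parseval's identity makes the d = M subspace distance equal the full patch
distance exactly — NLM-DCT with d = M *is* NLM, and the tests assert this
pixelwise to 1e−9.

The self-weight keeps its literal value (D² = 0 ⇒ pre-normalisation weight
1).  Replacing it by the maximal off-centre weight is a known variance
reduction heuristic but changes the estimator; it is available as
`center_weight="max"` and off by default.

The unbiased variants filter the magnitude image first, then correct each
output pixel as û ← √(max(û² − 2σ², 0)).  The subtraction removes the
2σ² bias of the squared magnitude; the clamp keeps the argument
nonnegative (dark regions where û² < 2σ² map to 0); the final square root
returns the value to intensity units so the output is an image comparable
to the input.  The residual is always `noisy − denoised`, computed after
the bias correction.

## Zigzag order and subspace dimension

Coefficients are ordered by the JPEG zigzag scan: anti-diagonals
m + n = s for increasing s, alternating direction, first step to (0, 1).
The scan direction within an anti-diagonal matters only for d values that
split a diagonal; whole-diagonal d values are direction-invariant.  The
recommended default when no ground truth is available to tune d is
`default_d`, round(fraction·M) with fraction defaulting to 0.4 — i.e.
d = 10 of 25 for the standard 5×5 patch, the setting used in the original
real-data experiments.  When tuning is possible, the d-sweep harness
locates d_opt; at high noise the optimum is well below M (the
low-frequency coefficients carry the tissue contrast, the discarded
dimensions mostly noise), while at low noise the curve is flat.

## Defaults and units

| parameter | default | units / rationale |
|---|---|---|
| patch side r | 5 | pixels; M = 25 |
| search side S | 11 | pixels; 121 candidates per pixel |
| h | tuned | intensity units; grid σ√(2k)·{0.5, 0.8, 1.25, 2.0, 3.2, 5.0} |
| d | 10 (r = 5) | leading zigzag coefficients |
| σ | user/estimated | intensity units; level L% of brightest tissue t ⇒ σ = L·t/100 |

Border handling: the image is mirror-reflect padded by (S−1)/2 + (r−1)/2
(edge pixel not repeated) so every pixel, including borders, has a full
window of full patches and the weight normalisation is uniform.  This is a
package choice — border conventions are rarely stated in the literature and
results within a patch-width of the border depend on it.  Coordinates are
0-based (row, col); pixels are float64 regardless of file depth.

## Noise simulation and σ estimation

`add_rician` draws the real-channel field before the imaginary one, each
row-major from a single seeded NumPy generator, making noisy images
bit-reproducible per seed.  `estimate_sigma_background` inverts
E[v²] = 2σ² on user-supplied signal-free pixels (σ̂ = √(mean v²/2)); it is
the plain second-moment estimator and assumes the mask truly contains no
signal — a convenience border-frame mask with an intensity gate is
provided, and the phantom module supplies exact masks.  At 10⁴ background
pixels the estimate is within 2% of the true σ (tested).

## Evaluation conventions

PSNR = 10·log₁₀(Max²/MSE) with Max taken over the union of the clean and
noisy images, not a fixed 255; this is the convention the benchmark tables
here follow, and a fixed `max_value` can be passed for cross-tool
comparison.  Max is fixed once per noise level from (clean, noisy) and
reused for every method's row, so PSNR differences between methods reflect
MSE only.  A zero-MSE estimate reports infinite PSNR rather than raising.

## The phantom generator

`make_phantom` paints analytic ellipses and rectangles (painter's
z-order) on an exactly zero background: a head outline, nested tissue
regions at fixed fractions of the brightest value t, ventricle-like dark
structures and small lesions.  Presets named T1/T2/PD use t = 150/250/255
on a 181×217 canvas.  The phantom reproduces the features the filters care
about — piecewise-constant tissue classes, sharp boundaries, a signal-free
background for σ estimation, a known brightest tissue anchoring the noise
level — and deliberately omits partial-volume effects, bias fields,
texture and anatomical realism.  Tests passing on the phantom therefore
validate the estimator mechanics and the bias correction, not performance
on textured anatomy; the benchmark harness accepts real or simulated
brain slices for that purpose.

On this phantom, plain NLM at moderate noise is limited mainly by the
Rician bias (its PSNR gain over the noisy input is small because the bias
dominates MSE in the background), so the bias-corrected variants dominate
the comparison; the DCT subspace then adds a further margin that grows
with the noise level.

## Residuals and the "no anatomy removed" check

The residual noisy − denoised of an *unbiased* filter necessarily
correlates with the clean image: the Rician bias it removes is itself
signal-dependent (≈ σ√(π/2) in background, ≈ σ²/2u in bright tissue).  A
correlation-based check of how much anatomy a filter smooths away is
therefore run between the two *biased* estimators: the NLM-DCT residual
correlates less with the clean phantom than the NLM residual at matched,
tuned h, reflecting the more accurate subspace weights.

## Numerical choices

* The production filter vectorises over window offsets: per displacement
  t, the patch distance map is the r×r box-sum of the shifted squared
  difference image (via `scipy.ndimage.correlate` with a ones kernel), and
  DCT coefficient maps are correlations with the orthonormal basis
  patches.  A quadruple-loop direct-sum reference implementation lives in
  `nlmdct.reference` and the two agree to 1e−12 on test images.
* Degenerate inputs need no special casing: on a constant image all
  distances are zero and the weights are uniform by construction; constant
  images are exact fixed points of the biased filters.
* `reconstruct_topk` keeps round(fraction·Q) whole-image DCT coefficients
  in zigzag order (rounding half up), zeroing the rest.
* Problem sizes in the shipped checks (128×128 phantom runs, 10⁶-sample
  moment checks, 16×16 oracle comparisons) were chosen so the full suite
  and the acceptance script each run in well under a minute on one core
  while keeping every statistical check at ≥ 3-standard-error resolution.

## Known limitations

* Strictly 2-D; volumes are filtered slice by slice at the caller's
  discretion (a NIfTI slice index is required, never guessed).
* h is global; spatially adaptive bandwidths are out of scope.
* The σ estimator assumes single-coil Rician statistics; non-central chi
  noise from multi-coil reconstruction is not modelled.
* The patch distance is unweighted (no Gaussian spatial taper over the
  patch), matching the estimator definition used throughout.
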