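# Methods

This note records the model, the estimators, the numerical choices, and
what the synthetic benchmarks do and do not establish.

## Model

**Causal factorization.** Images are treated as realizations of a
stationary 2-D process and factorized pixel-by-pixel in raster order; the
conditioning set ("causal neighborhood") contains only pixels above the
target or left of it in the same row.  The default single-scale
neighborhood is the upper half of a 7×7 window — 24 pixels — configurable
via the window size.  Stationarity means one shared conditional density
for all interior pixels; boundary pixels (whose neighborhood leaves the
image) are excluded from likelihoods and their count reported, so rates
are comparable across image sizes.

**Pixel conditional (MCGSM).** The conditional density is a mixture of
experts whose gates and experts are indexed by (component c, scale s):

- gate energy: `(m/2)·log α_cs + ½·log|K_c| − ½·α_cs·yᵀK_c y`, softmax-normalized;
- expert: `N(x; A_c y, Σ_c/α_cs)`.

The expert covariance scales with the same `α_cs` as the gate.  This is
the form obtained by conditioning an equal-weight, zero-mean mixture of
finite Gaussian scale mixtures over the joint `(y, x)` vector — the
construction `from_joint` implements via Schur complements — and we adopt
it because it keeps the conditional and joint views exactly consistent
(the package tests this identity to 1e-10).  Zero means and uniform prior
weights over (c, s) are model assumptions throughout; per-component mean
offsets are deliberately out of scope, so our "MCG" special case is the
zero-mean variant.

**Gauge.** Scaling `K_c → tK_c, α_c· → α_c·/t, Σ_c → Σ_c/t` leaves the
density invariant.  The canonical form fixes `Σ_s log α_cs = 0` per
component; EM renormalizes into this gauge each iteration and the flat
parametrization enforces it by subtracting the per-component mean of the
log-scales on decode, which removes the flat direction from optimization.

**Multiscale factorization.** The 2×2 orthonormal Haar basis (coefficients
±1/2) maps an image to four half-resolution channels: DC ~ block-average
×2, and horizontal/vertical/diagonal AC details.  The generative order is
coarse-to-fine: a single-scale MCGSM generates the coarsest DC image, and
at each level one MCGSM with 3-dimensional output predicts the AC triple
at a location from (a) the DC channel over the *full* N×N superpixel
window — legitimately non-causal, because the entire low-resolution image
precedes all details in generative order — and (b) the three AC channels
over the causal half of the window.  Input dimension is
`N² + 3·(N²−1)/2`, i.e. 21 for the default N = 3.  The orthonormal
normalization is chosen precisely so the transform's Jacobian is 1 and
log-likelihoods in coefficient space equal log-likelihoods in pixel
space; the per-level decomposition is additive bit-for-bit.

## Training

1. **EM initialization.**  An equal-weight zero-mean mixture of GSMs is
   fitted to the joint `(y, x)` vectors.  The M-step is a conditional
   cycle — scales first (`α_cs = dim·Σr / Σ r·xᵀΣ_c⁻¹x`), then covariances
   with the new scales — which keeps the average log-likelihood trace
   non-decreasing.  Initialization: covariances = data second moment plus
   seeded diagonal jitter; scales log-spaced over [1/4, 4] with seeded
   jitter.  Defaults: 50 iterations, relative tolerance 1e-6.
2. **Conditionalization** via `from_joint` (Schur complements), re-gauged.
3. **BFGS** on the exact mean negative conditional log-likelihood, with
   analytic gradients through the Cholesky/log-scale reparametrization
   (validated against central finite differences to 1e-5 relative).
   Full-batch; gradient-norm tolerance 1e-6; 500 iterations default.  On
   heavy-tailed objectives scipy's BFGS occasionally aborts with
   "precision loss" far from a stationary point; we restart with a fresh
   Hessian approximation (up to 2 times) while the objective improves.

**Degenerate optima and multi-start.**  Mixture likelihoods are unbounded:
on data with near-noiseless structure (e.g. flat occlusion regions plus
σ = 0.01 noise) a component can collapse onto a thin manifold, driving the
training likelihood up while held-out likelihood collapses.  `train`
therefore supports multi-start (`n_init`): candidates from different EM
seeds are compared on a held-out validation split (10% default), and
selection is *always* by validation likelihood, never training likelihood.
The nested-family comparison uses `n_init=2`.  Decoded precision/covariance
matrices whose Cholesky fails numerically (underflowed factor diagonals)
receive escalating diagonal jitter starting at 1e-9 of the mean diagonal,
logged.

## Evaluation

- **Conditional cross-entropy rate**: mean −log₂ model density on held-out
  pairs; the quoted SEM is one standard deviation of per-split means
  (10 contiguous splits by default), i.e. the spread across test sets.
- **Marginal entropy**: Vasicek m-spacing estimator
  (`scipy.stats.differential_entropy`, window √n), in bits.  Accurate to
  ~0.02 bits at n = 1e5 for smooth densities.
- **cross-MIR** = marginal entropy − cross-entropy rate.  A lower bound on
  the multi-information rate; negative values are possible for bad models
  and are reported as-is.
- **Rate combination** across levels: `Σ_{s=1..L} (3/4^s)·h_AC(s) +
  h_coarse/4^L` (convex weights; equal inputs pass through unchanged).
- **Scale-invariance profile**: per-scale cross-MIR of
  identical-architecture models on the block-averaged (Haar DC) chain,
  plus per-scale AC conditional entropies with a variance correction
  `3·log₂ κ_s`, κ_s equalizing the per-coefficient standard deviation to
  the finest scale.  For an exactly self-similar process the corrected
  entropies coincide.
- **Phase scrambling**: Fourier amplitudes kept, phases replaced by those
  of a seeded white-noise image (Hermitian by construction, so the output
  is real); the DC coefficient is retained.  Preserves the autocorrelation
  exactly, destroys all higher-order structure.
- **Lp filter statistic**: vertical derivative-of-Gaussian filter
  (σ = 1.5 px, truncated at 4σ, zero-sum, unit L2 norm); response pairs at
  vertical offset d are whitened with the symmetric inverse square root of
  their 2×2 covariance and fitted with a 2-D Lp-spherical density
  `f(x) = g(‖x‖_p)/(2·V_p·‖x‖_p)`, `V_p = 4Γ(1+1/p)²/Γ(1+2/p)`, with a
  Gamma radial density g.  The Gamma shape/scale MLE (Newton on the shape,
  closed-form initialization) is profiled inside a bounded search over
  p ∈ [0.1, 4].  Whitened Gaussian responses give p ≈ 2; heavy-tailed,
  increasingly independent responses drive p below 1.5 ("star-shaped"
  histograms).

## Synthetic data — what it emulates, and what it does not

- **Dead leaves**: disks with radius density ∝ r⁻³ on [1, 32] px
  (inverse-CDF sampling; median radius √2 when r_max → ∞), i.i.d.
  uniform(0,1) intensities, centers on a canvas extended by r_max so the
  visible region is stationary, painted front-to-back onto not-yet-covered
  pixels until full coverage.  White Gaussian noise σ = 0.01 (1% of the
  intensity range) is added so differential rates are finite.  This
  reproduces occlusion structure, approximate scale invariance, and
  natural-image-like marginal/second-order statistics — but not textures,
  shading, or photometric nonlinearities of real photographs.  Passing the
  ranking experiment on dead leaves shows the pipeline orders model
  families correctly under occlusion statistics; it does not by itself
  establish performance on photographs.
- **Row-AR(1) images**: independent stationary AR(1) rows, unit
  innovations; per-pixel MIR is −½·log₂(1−ρ²) exactly, giving closed-form
  ground truth for the whole rate pipeline.
- **Known-model corpora**: raster samples from fixed MCGSM or multiscale
  models, for recovery experiments.
- **Lp pairs**: Gamma radius × uniform (cone-measure) direction on the
  2-D Lp sphere, the exact generative dual of the fitted density.

## Problem sizes

The shipped experiments are deliberately desk-scale: the nested-family
comparison uses 32 dead-leaves images of 128×128 (24 train / 8 test),
a 5×5 causal window (12-pixel neighborhood), 40k training pairs, and
small mixtures (CG 1×1, MCG 3×1, CGSM 1×3, MCGSM 3×2, multiscale L=2,
N=3); recovery uses 1e5 pairs.  At this scale the cross-MIR SEM across
test images is ~0.1–0.2 bits, and the ranking assertions use three
combined standard errors.  The multiscale model's advantage over the
single-scale MCGSM is not resolved at this corpus size — its coarse model
sees only 32×32 DC images — so its cross-MIR may fall on either side of
the single-scale value within error bars, and the comparison asserts
non-inferiority, not strict improvement.  Larger neighborhoods (7×7),
8 components × 4 scales, and 1e6-pair budgets are the intended
full-scale configuration and are exposed as defaults in the CLI.

## Known limitations

- Zero-mean experts: families requiring mean offsets are approximated by
  their zero-mean variants.
- Boundary handling is exclusion (likelihood) and white-noise
  initialization with burn-in cropping (sampling); no toroidal schemes.
- The Gamma radial family in the Lp fit is a modeling choice; for exactly
  Gaussian data the radial law is chi, and the profile fit still returns
  p = 2.00 ± 0.01 at n = 1e5, but radial-shape estimates are not
  interpretable under misspecification.
- The sampler is sequential per pixel (O(HW) conditional draws); no
  parallel multi-row scheme.
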