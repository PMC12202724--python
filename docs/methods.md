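# Methods

## The forward model

MRI phase data measure voxel-average shifts of the Larmor frequency. In a
homogeneous, isotropic medium the shift caused by a susceptibility
distribution χ (in ppm) is the 3D convolution of χ with the unit dipole
response `d`, which in k-space is

    D(k) = 1/3 − (k·b̂₀)² / ‖k‖²,        D(0) = 0,

where b̂₀ is the main-field direction. The Lorentz-sphere correction fixes
the DC bin at zero and makes the shift inside a uniform sphere vanish.
`D` spans [−2/3, 1/3] and vanishes on the magic-angle cone
cos²θ = 1/3, which is what makes the inverse problem ill-posed.

Real tissue also produces frequency shifts that do not follow this
macroscopic dipole pattern — from microstructure (compartmentalized,
anisotropic myelinated tissue), off-diagonal susceptibility-tensor terms,
chemical exchange, and imaging artifacts. The extended forward model adds
them as a voxelwise term:

    f = d * χ + f_ρ.

The inverse problem of recovering χ from f alone is underdetermined
(f_ρ = f, χ = 0 is always a solution), so any solver must bring prior
structure. This package provides the forward models, generators of
synthetic data with the right second-order statistics, classical
closed-form inversions, a learned inversion trained under either the
standard or the extended model, and the evaluation metrics to compare
them on phantoms with known truth.

Frequency shifts are stored as dimensionless ppm of the Larmor frequency,
so χ in ppm maps to f in ppm with no TE/γ/B₀ factors. FFT convolutions
assume periodic boundaries; free-space simulations (the sphere oracle)
zero-pad ×2 per axis and crop.

## Validation oracle

The FFT forward model is validated against the analytic field of a
uniformly magnetized sphere: exterior shift (Δχ/3)(a/r)³(3cos²θ − 1),
interior shift 0. Spheres are rasterized with 3× supersampled partial
coverage at the boundary; at 128³ with a = 8 voxels the shell (1.5a–3a)
relative RMS error is ≈ 0.3% and the mean absolute interior shift is
≈ 0.002 ppm (interior = voxels fully inside the sphere; partially covered
boundary voxels belong to neither closed-form branch).

## Synthetic training data

Learned inversion does not require anatomical images — it requires fields
whose second-order statistics resemble those of natural images. Each
sample is composed as:

* **χ and f_ρ**: a sum of organic blob shapes (largest connected
  component of a thresholded, isotropically low-pass-filtered Gaussian
  random field, soft edges) and a power-law spectral texture
  (P(k) ∝ ‖k‖^−β, β ~ U(1.5, 3)). Peak amplitude is drawn uniformly from
  (0.05, 0.2) ppm for χ and (0.01, 0.05) ppm for f_ρ — order-of-magnitude
  plausible for brain tissue. The two fields draw from independent
  streams.
* **magnitude**: a smooth field rank-mapped into (0.05, 1] with a squared
  profile so a substantial dark fraction (< 0.2) exists.
* **mask**: a smooth random blob covering 50% of the volume.
* **f_total** = d*χ + f_ρ + n, with n zero-mean Gaussian of per-voxel
  std σ₀ / (SNR · magnitude), σ₀ the std of the clean field, SNR = 100
  (matching the evaluation setting). Noise is zeroed outside the mask.

Two implementation details exist purely to protect the spectral
contracts: all smoothing of compact indicators uses an exactly isotropic
Fourier-domain Gaussian (separable truncated FIR filters leave an
axis-aligned ripple floor), and blob supports keep a margin from the
volume faces (edge truncation or periodic wrap-around would imprint
axis-aligned energy). With that, the nondipolar generator's polar/equatorial
spectral-energy ratio is ≈ 1.0 while dipole-convolved fields show ≈ 4.

The anisotropy statistic whitens each k-bin by the finely binned
isotropic radial profile before comparing polar caps (within 10° of the
b₀ axis) against the equatorial belt; without the whitening, red spectra
bias the comparison on a discrete grid. Generator isotropy is a
statistical property, so the contract is checked on power spectra
ensemble-averaged over several draws.

## Phantoms

* **Three-sphere scene**: one sphere with χ only, one with f_ρ only, one
  with both — the minimal demonstration that a dipole-only inversion
  misattributes nondipolar shifts to susceptibility.
* **Brain-like model**: nested smooth surrogates — brain ellipsoid,
  cortical ribbon, bilateral WM lobes, central CSF cavities (χ = −0.045
  ppm), and six bilateral deep-gray nuclei with a ladder of construction
  susceptibilities (0.02–0.16 ppm; caudate 0.048, globus pallidus 0.160,
  putamen 0.076, red nucleus 0.104, dentate 0.132, thalamus 0.020),
  plus a mild smooth texture (±0.004 ppm) so regions are not perfectly
  flat. The model is generated procedurally; it stands in for a realistic
  digital brain and therefore lacks realistic tissue interfaces, vessels,
  and k-space sampling artifacts.
* **Microstructure variant**: a nondipolar field confined to the WM
  label: band-limited random texture under a smooth "tract density"
  envelope with a positive floor, peak 0.02 ppm. The positive mean is
  deliberate — microstructure raises the voxel-average WM frequency,
  which is what makes dipole-only inversions read WM as more paramagnetic
  than it is; a zero-mean surrogate would make the systematic part of the
  effect vanish by construction. The two variants share bit-identical χ
  truth, labels and mask (the flag only switches f_ρ), enabling paired
  comparisons.
* **Measurement**: f = (d*χ + f_ρ + noise)·mask at SNR 100, with
  magnitude 1 inside the brain and 0.05 outside.

## Inversions

* **TKD (thresholded k-space division)**: D̃ = D where |D| ≥ t, else
  sign(D)·t (sign(0) → +1), χ̂ = IFFT(FFT(f)/D̃); t = 0.15 by default.
  Optionally the map is rescaled by 1/mean(D/D̃) — the central value of
  the reconstruction point-spread function — which undoes the filter's
  systematic underestimation of regional means (the study pipeline
  enables this; the raw operator is the default so that the filter
  definition round-trips exactly).
* **Tikhonov**: χ̂ = IFFT(D·FFT(f)/(D² + λ)), λ = 0.01 default, with the
  analogous mean-response correction available.
* **Learned inversion**: the frequency map first passes through the TKD
  filter (a fixed, differentiable physics layer), and a 3D U-Net learns a
  residual correction on top: χ̂ = x + net(x), x the filtered map
  normalized by its robust scale (1.4826·MAD within the mask). Seeding
  the network with the physics solution is what makes small training
  budgets productive; an untrained model reproduces the direct filter.
  The U-Net (depth 3, 8 base filters, 3³ kernels, leaky-ReLU slope 0.1,
  2× average pooling / nearest upsampling, skip concatenation, 1×1×1
  linear head) runs on a small numpy engine with manual backpropagation
  and Adam; everything is float32 and deterministic given the seeds.
* **Modes**: `deepole` trains on extended-model data (f_ρ present);
  `dlqsm` on standard-model data (f_ρ amplitude forced to zero). Both
  modes consume identical χ streams sample-for-sample, so their
  difference isolates the training model. The loss is masked L1 (L2
  available): voxels outside the sample mask contribute nothing.

## Desk-scale training budget

Defaults train on 48 streamed 32³ samples for 6 epochs — a deliberate
desk-scale budget (about 90 s per model on one CPU core) that is
sufficient to reproduce the qualitative phenomenon: the deepole-mode
model attains lower mean masked dNRMSE on microstructure-on phantoms than
the dlqsm sibling, while classical filters remain better on
microstructure-free phantoms. A larger budget (64 samples × 8 epochs) was
tested and *worsened* phantom transfer for both modes — the network
overfits the synthetic training domain — so the smaller default is the
better-generalizing point, not a shortcut.

Two biases of the desk-scale networks should be kept in mind when
reading slope metrics. First, the learned residual over-smooths, and
deepole (whose correction task is hardest) trades clean-case accuracy and
DGM slope for nondipolar robustness. Second, both modes show a
seed-dependent negative bias of eroded regional means on the phantom
(DGM slopes around 0.8–1.0 for dlqsm) that is absent on their own
training distribution; scalar output-gain calibration on training data
cannot remove this domain-shift effect and is therefore not applied.
Because that bias is larger than the (consistently positive) slope shift
that white-matter nondipolar contamination induces, the |slope−1|
degradation that classical filters show under microstructure is masked
for the learned standard-model inversion at this budget. Absolute
numbers should not be compared with fully trained published models; all
knobs (depth, filters, samples, epochs) scale up through `NetConfig`.

## Metrics

* **dNRMSE** (%): 100·‖(est−⟨est⟩) − (ref−⟨ref⟩)‖/‖ref−⟨ref⟩‖ over the
  mask; invariant to global offsets, which are physically meaningless.
* **XSIM**: Gaussian-windowed structural similarity (σ = 1.5 voxels,
  computed with scikit-image) averaged over the mask, with
  C1 = (0.01·L)², C2 = (0.001·L)², L the reference range in the mask.
  The contrast-stability constant is an order of magnitude below the
  classic SSIM choice, sharpening the penalty on contrast differences.
* **ROI statistics**: per-label mean/std/count after erosion with a
  6-connected structuring element (1 voxel by default) to reduce
  partial-volume contamination; regions that vanish are flagged and
  excluded from fits.
* **DGM slope**: ordinary least squares of estimated on true regional
  means over the six nuclei; slope < 1 reads as underestimation.
* **ODR**: total least squares via the principal axis of the centered
  point cloud (equal error weights), for comparing two estimates that
  both carry errors; reciprocal by construction.
* **Referencing**: subtracting the mean over a reference mask (whole
  brain); idempotent, difference-preserving.

## Numerical choices and degenerate inputs

* float64 for all FFT physics; float32 for network training and on-disk
  volumes.
* The kernel's singular DC bin is set to 0 exactly; TKD treats sign(0)
  as +1; Tikhonov with λ = 0 zeroes the D = 0 bins.
* dnrmse raises on a reference constant over the mask; xsim on volumes
  smaller than the window; slope fits on fewer than 3 points or zero
  reference variance; ODR on isotropic point clouds.
* Erosion connectivity is fixed at 6 (face-adjacent).
* Seeds: a single global seed expands into per-stage seeds through
  `numpy.random.SeedSequence`; every generator draws from an independent
  child stream so switching one component off never perturbs another.

## Known limitations

* The brain phantom is a geometric surrogate: no realistic interfaces,
  no vessels, no sampling artifacts; its WM nondipolar field emulates
  fiber-architecture contrast statistically, not biophysically (no
  diffusion-derived orientations).
* The learned inversion at default budget is far from converged; it
  demonstrates the training-model contrast, not state-of-the-art map
  quality.
* Susceptibility-tensor effects enter only conceptually through f_ρ; no
  tensor kernels are implemented.
* In vivo preprocessing (unwrapping, background-field removal,
  registration, segmentation) is out of scope; inputs are assumed to be
  clean frequency maps.
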