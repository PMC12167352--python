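# Methods

## Pipeline and model

The pipeline operates on a 2D+time DSA series: a `(T, H, W)` stack of
intensities in [0, 1] at a uniform frame rate (first frame at t = 0,
frame t at t/fps).  Stages:

1. **Preprocessing** (`dsa_io`): bilinear resize of frames to a common
   grid, per-series min-max intensity normalization, and — when series
   were acquired at varying rates — per-pixel linear resampling onto a
   uniform temporal grid.  Normalization is per-series rather than
   per-frame so that the relative temporal contrast dynamics, which the
   time-intensity curves encode, are preserved.
2. **MinIP + input-artery segmentation** (`dsa_io.minip`,
   `segmentation`): the minimum-intensity projection collapses the series
   into one image in which contrast-filled vessels are darkest; a UNet
   predicts the input-artery mask from it.  A user-supplied mask can be
   used everywhere instead.
3. **AIF extraction** (`aif`): per-pixel concentration is the intensity
   drop below a baseline, floored at 0.  The baseline is the pixel's
   first-frame intensity by default (a subtracted series opens
   pre-contrast); a fixed baseline of 1.0 is available for series whose
   first frame already carries contrast.  The AIF is the unweighted mean
   concentration curve over the mask.
4. **Deconvolution** (`deconv`): indicator-dilution model
   `C_voi = CBF·ρ·(C_art ∗ r)`, discretized as the lower-triangular
   Toeplitz operator `A[i,j] = Δt·C_art[i−j]`.  One SVD of `A` is
   computed per series and its regularized pseudo-inverse applied to all
   tissue pixels.
5. **Parameters** (`deconv`, `maps`): Tmax = arg max k · Δt;
   CBF = k(Tmax)/ρ; CBV = trapezoidal ∫C_voi / ∫C_art over the acquired
   window; MTT = CBV/CBF.  Maps are rendered through perceptually uniform
   colormaps with robust (2nd–98th percentile) default display ranges, and
   territory means feed the outcome analysis.

## Numerical choices

* **Solver**: truncated SVD (singular values below `lambda_frac · σ_max`
  dropped) on the non-circulant triangular operator; Tikhonov available.
  The delay-sensitive formulation is deliberate: a circulant/oscillation-
  corrected variant would discard the bolus-delay information that Tmax is
  meant to carry.
* **`lambda_frac`** default 0.2, appropriate for noisy clinical-grade
  curves; noiseless phantom validation uses 1e-4 (effectively
  unregularized), since with zero noise there is nothing to regularize
  against and regularization only biases the recovered peak.
* **Tie-breaking at the residue maximum**: the Tmax index is the first
  sample within a 1e-9 *relative* tolerance of the maximum.  A plug-flow
  (boxcar) residue yields an exactly flat plateau in k; bit-level noise in
  the SVD solve would otherwise place the argmax arbitrarily within the
  plateau, breaking injection-profile invariance and misreporting the
  delay.  CBF is read at that same index (identical to the maximum within
  1e-9), which keeps `r(Tmax) = 1` exact after normalization.
* **Negative lobes**: regularization oscillations below zero are
  non-physical; k is clipped at 0 before parameter extraction
  (configurable off for oracle comparisons against plain least squares).
* **CBV** is computed from the integral ratio, not from `CBF·∫r`: the
  ratio needs no deconvolution and is therefore robust to solver error.
  The identity between the two forms holds with *rectangle-rule*
  quadrature of r (the sampled convolution embeds rectangle weights) and
  is enforced as a test property.  The same discretization gives the
  known `≈ Δt/2` positive bias on the residue integral, visible as a ~3%
  CBV/MTT excess at Δt = 0.25 s, MTT = 4 s.
* **Degenerate pixels**: pixels whose peak concentration is below
  `tissue_threshold` (default 0.02) are not deconvolved; zero-flow or
  zero-volume pixels are excluded from the valid mask and their map
  values stored as 0.  Division by zero flow is guarded (MTT undefined →
  excluded).
* **Constant curves**: the Pearson correlation of a constant curve is
  undefined and reported as missing, never as 0.

## Phantom generator

The phantom realizes exactly the statistical structure the method assumes:

* a **gamma-variate bolus** `A·((t−t0)/(αβ))^α · exp(α−(t−t0)/β)`
  (peak-normalized: maximum = A at t = t0 + αβ) in an input-artery
  region; defaults t0 = 1 s, α = 3, β = 0.7 s, A = 0.4 — a ~2 s rise
  resembling an intra-arterial injection.  A ≤ 0.45 guarantees that
  doubling the amplitude in invariance experiments never clips;
* **tissue regions** with exponential or boxcar residues.  Both families
  have closed-form truth: max r = 1, ∫r = MTT, hence CBV = CBF·MTT and
  Tmax = delay exactly;
* **polarity**: concentration is rendered as `I = clip(1 − c, 0, 1)` —
  contrast darkens the image as in subtraction angiography — with
  background at 1 and optional seeded Gaussian noise added before
  clipping.  ρ is fixed to 1, so phantom parameters are relative units.

Default study conditions for recovery experiments: 4 frames/s for 60 s
(Δt = 0.25 s), CBF = 0.5/s, MTT = 4 s, delay = 2 s — a well-sampled bolus
with the residue tail fully inside the acquisition window.  Clinical series
run 2–4 fps over 10–50 frames; the longer synthetic window isolates solver
error from window-truncation error.

What the phantom does **not** emulate: anatomy (vessel trees, overlapping
projections), X-ray physics (beam hardening, scatter), motion and
pixel-shift artifacts, recirculation, and contrast stasis.  Passing the
phantom suite therefore demonstrates correctness of the mathematics and
the implementation, not clinical-grade robustness.

## Segmentation module

The UNet follows the classic layout: encoder levels of two 3×3 stride-1
convolutions (instance normalization + ReLU each) with 2×2 max-pooling
between levels, channels doubling from `base_channels` to `max_channels`
(64→512 default, i.e. four levels and eight encoder convolutions — the
canonical reading of that channel ladder), a mirrored decoder with nearest
2× upsampling and concatenation skips, and a 1×1 sigmoid head binarized at
0.5.  Arbitrary input sizes are handled by reflect-padding to the pooling
depth and cropping back.

The network, RMSprop, the reduce-on-plateau schedule (patience 10, factor
0.5) and early stopping (patience 50, max 1000 epochs) are implemented
directly in numpy with manual backpropagation (im2col matmuls), one image
per step; instance normalization makes single-sample training well-posed.
Gradients are verified against finite differences in the test suite; the
max-pool subgradient at exact ties (common at ReLU zeros) splits evenly.

Loss: soft Dice `1 − 2Σpg/(Σp+Σg+1)` plus mean binary cross-entropy.  The
unit smoothing term sits in the denominator only, so a perfect binary
prediction of S foreground pixels scores `1 − 2S/(2S+1)`.

Training defaults keep the clinical recipe (lr 1e-6, augmentation:
horizontal flip, ±5% translation and scaling, ±10° rotation, each with
probability 0.5, identical transform on image and mask, nearest-neighbor
for the mask).  Desk-scale smoke runs use a scaled-down channel ladder
(8→32), lr 1e-3 and ≤10 epochs on 128×128 synthetic MinIPs — the 1e-6 rate
is matched to thousand-epoch GPU runs on 1024×1024 images and makes no
progress in a few CPU epochs.  The synthetic segmentation task (darkest
elongated structure vs. lighter tissue disks) is far easier than locating
the supraclinoid ICA on a clinical angiogram; held-out Dice ≈ 1 here says
the trainer works, not that clinical Dice would be high.

## Outcome association

Each series contributes eight territory-mean features ({ICA, MCA} ×
{CBV, CBF, MTT, Tmax}) and a binary favorable/unfavorable label.  Features
are z-scored before the joint maximum-likelihood logistic fit, so odds
ratios are per standard deviation — the parameters are relative units and
unstandardized odds ratios would be scale-dependent.  The report carries
Wald z and p per feature, the likelihood-ratio p, and the in-sample AUC
(no cross-validation; proof-of-concept framing).  Perfect separation is
flagged (`separation_flag`, with a weakly ridge-regularized fallback fit)
rather than raised.  Cohort simulation draws standard-normal features and
Bernoulli outcomes from a specified logistic model; n = 500 null and
planted-effect checks and n = 2000 coefficient recovery define the
module's statistical sanity suite.

## Validation problem sizes

Phantom validation uses 32×32–64×64 series (the deconvolution is
per-pixel, so spatial size only multiplies runtime); segmentation smoke
training uses 64 training + 16 held-out 128×128 phantoms for 8 epochs;
cohort simulations use n = 500–2000.  These sizes make the full validation
run in a couple of minutes on one CPU while keeping every estimate well
inside its tolerance.

## Known limitations

* Relative units throughout; no absolute quantification (mL/100 g/min),
  no hematocrit or partial-volume correction.
* No motion correction or re-subtraction; input series are assumed
  subtracted and aligned.
* The triangular-Toeplitz deconvolution is delay-sensitive by design; it
  slightly underestimates CBF when regularization is strong (documented
  behavior of truncated-SVD bolus tracking).
* DICOM support covers multi-frame XA with CineRate/FrameTime timing;
  anything else needs an explicit frame-rate override.
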