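# Methods

This note documents the models, parameter choices and limitations behind
`fastdat`: a pipeline that restores short-acquisition (single-cycle)
dopamine-transporter SPECT slices to virtual full-acquisition quality and
evaluates the restoration with image-quality and reader-agreement
statistics on synthetic phantom cohorts.

## 1. The phantom and the acquisition model

Real DaT-SPECT validation data are patient studies that cannot be shared,
so the package generates a digital stand-in whose *statistical* structure —
not its anatomy — matches the clinical setting.

**Geometry.** Each case is a `(n_slices, 128, 128)` activity grid at
3.29 mm pixels.  An elliptical brain carries diffuse background uptake
(activity 1 by convention).  Two mirror-image comma-shaped striata (caudate
head + slanted putamen, split into anterior/posterior halves) occupy the
central five slices with axial taper 0.6/0.9/1.0/0.9/0.6.  The four-point
visual pattern scale maps onto sub-region activity:

| score | pattern | realisation |
| --- | --- | --- |
| 4 | normal | caudate + both putamen parts at striatal activity (default 8× background) |
| 3 | eagle wing | posterior putamen excess halved |
| 2 | egg shape | putamen at background, caudate preserved |
| 1 | burst striatum | whole striatum at background |

Per-hemisphere stochastic variation (position jitter ≤ 1 px, intensity
gain ± 10%) uses random streams keyed by `(seed, hemisphere)`, so editing
one hemisphere's pattern never perturbs the other — a property the tests
rely on.

**Background texture.** Uniform backgrounds make plain Gaussian smoothing a
near-optimal restorer, which contradicts the clinical finding that a
learned model clearly beats it.  Real FP-CIT backgrounds carry anatomical
structure (grey/white matter contrast, sulci) at the scanner's resolution
limit.  The phantom therefore multiplies the background by a smooth
per-case random field (relative SD 0.40, correlation length 1 px before
PSF blur, i.e. structure at the PSF scale after blurring).  The field has
its own random stream, independent of the pattern labels.  With texture
disabled (`jitter=False`) the construction is exactly mirror-symmetric,
which the geometry tests exploit.

**Acquisition.** Tomographic reconstruction is replaced by an image-domain
model: the activity is blurred in-plane by an isotropic Gaussian PSF
(default FWHM 10 mm, the general-purpose-collimator resolution class), each
slice is scaled to a fixed expected total of `counts_per_cycle`, and each
cycle is an independent Poisson draw.  The short image is cycle 1; the long
reference is the pixel-wise sum of 5 cycles.  This preserves the one
property the analysis depends on — count-limited noise scaling with
acquisition time — while skipping vendor-specific reconstruction.

**Count calibration.** Absolute counts in reconstructed slices are
conventional, so `counts_per_cycle` is calibrated against the clinical
baseline: at 300 000 expected counts/slice/cycle the phantom's short images
score ~31 dB PSNR against the long reference, matching the reported
quality of clinical 5-min images (~30.8 dB).  The phantom's SSIM baseline
(~0.85) is higher than clinical (~0.71) because simple shapes are
structurally easier; both cannot be matched simultaneously and PSNR, a pure
count-statistics quantity, is the physically meaningful anchor.

**Cohorts.** Per-hemisphere pattern prevalence defaults to
(0.17, 0.29, 0.28, 0.26) for scores 1–4, the gold-standard score
distribution of the clinical test set.  Per-case seeds derive from the
master seed by case index (`SeedSequence(master, spawn_key=(i,))`), so
enlarging a cohort never reshuffles existing cases.

## 2. Preprocessing

Mirrors the clinical chain: the long stack is normalised per case and the
slice with the highest maximum pixel value is the analysis centre (ties
break to the lowest index); the five slices centred on it are analysed and
the central three kept for reader display; windows clamp by shifting at
stack boundaries.  Each slice is cropped to the central 64 × 64 pixels
(rows/cols [32, 96) in 0-based half-open convention).  Short and long
stacks are each normalised by their own per-case global maximum, so both
live on [0, 1] at comparable scale.

Each case contributes five training samples: for each window slice, the
input is the five short-time slices centred on it (replicate-padded at the
window edge) and the target is the matching long-time slice.  A 207-case
cohort thus yields exactly 1035 samples, and the 120/37/50-case split
yields 600/185/250.  Splits are by case — never by slice — to avoid
leakage between partitions; counts follow floor(train), floor(val),
remainder to test.

Metrics are computed on the floating [0, 1] images.  8-bit quantisation
(round half away from zero) is used only for disk export, so model
differences are not buried under quantisation noise.  Reader display
images use the cyan→magenta "Cool" colormap over the full intensity range
and are written as 8-bit RGB PNG (visually lossless for display; the
stored analysis images remain the quantitative source).

## 3. The restorer and its baselines

The U-Net family has 1–5 resolution levels with filters 16·2^level, two
same-padded 3×3 conv + ReLU per block, 2× max-pooling, nearest-neighbour
upsampling followed by a 3×3 conv, concatenated skips, and a linear 1×1
output head.  Training: MSE loss, Adam, batch 8, 200 epochs with LR 10⁻³
stepping to 10⁻⁵ strictly after epoch 150 (the boundary epoch itself keeps
the high rate).  No early stopping: final-epoch weights are kept.  No
batch normalisation or data augmentation.  Outputs are clipped to [0, 1]
at inference only.

Design points that were genuinely open and decided here: "same" padding
(so 64 × 64 survives all depths), ReLU activations, He initialisation,
nearest-upsample decoding, and the LR boundary convention.

The engine is pure NumPy with hand-written backprop (convolutions as nine
offset GEMMs via `tensordot`, channels-last float32), which makes training
bit-reproducible under a fixed seed on one CPU; backprop is verified
against float64 finite differences in the tests.

Baselines are an isotropic Gaussian filter (σ = 1 px, reflect boundaries)
and a bilateral filter (σ_spatial = 2 px, σ_range = 0.1, spatial kernel
truncated at the same 4σ radius scipy uses, so the σ_range → ∞ limit
reproduces the Gaussian filter exactly).  No filter parameters are stated
for the clinical comparison, so these defaults are conventional and
exposed in config.

A string-keyed registry (`unet_l1`…`unet_l5`, `short`, `gaussian`,
`bilateral`) keeps the method list extensible to further architectures.

## 4. Statistics

**PSNR** is 10·log₁₀(MAX²/MSE) with MAX = 1 on normalised floats; identical
images report +∞ and are excluded from means with a count.  **SSIM** uses
the canonical Gaussian-window form (11 × 11, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, population local statistics, averaged over positions where the
full window fits), delegated to scikit-image and verified against a direct
local-statistics implementation in the tests.

Method comparison is paired by slice: the **Friedman** test on within-slice
ranks (average ranks for ties, tie-corrected χ² with k − 1 df), then
**Dunn z-tests** on pooled tie-corrected ranks for the reference method
against each other method only (m = k − 1 comparisons, matching the
clinical analysis family), with **Holm** step-down adjustment capped at 1.
Summaries are mean ± sample SD (n − 1).

**Weighted κ** uses quadratic weights w_ij = 1 − (i−j)²/9 on the fixed
4-category scale; unobserved categories are retained so values are
comparable across methods; two constant, identical raters define κ = 1.
**ICC** is the two-way random-effects, absolute-agreement, single-measure
form ICC(2,1) — the clinical report does not state its variant, and
absolute agreement is the stricter, more common choice for ordinal
reliability.  Intra-rater ICC compares sessions within reader; inter-rater
ICC compares reader pairs over all methods' scores pooled.

## 5. The simulated reader study

Readers are simulated, not trained on images: each true score is passed
through confusion matrices whose noise level depends on the method,
encoding "enhanced images are easier to read".  The model has two layers:

1. a **displayed pattern** per (case, hemisphere, method) — a graded
   confusion of the truth (error mass decaying geometrically with category
   distance; rates 0.70 / 0.60 / 0.55 / 0.30 for short / Gaussian /
   bilateral / enhanced) drawn once and shared by all readers, representing
   restoration errors in the image itself;
2. **personal reader noise** — adjacent-category errors at rate 0.20 per
   reader (0.15 on the wash-out second reading of the same displayed
   image).

A single-layer independent-noise model cannot jointly reproduce the
clinical magnitudes: noise strong enough to bring κ vs gold to ~0.36
drives inter-rater ICC far below the reported ~0.73, because clinical
readers disagree with the gold standard *together* (the image misleads
them all).  With the two-layer defaults, simulated mean κ is ~0.35 on
short images and ~0.65 on U-Net images, intra-rater ICC ~0.82–0.90 and
inter-rater ICC ~0.8 at large n — the same Landis–Koch bands (fair →
substantial) as the clinical study.  In the synthetic pipeline the gold
standard is the phantom's ground-truth pattern labels, since a consensus
reading has no synthetic analogue.

## 6. Problem sizes and reproducibility

Two profiles ship with the package.  The **clinical-scale** profile mirrors
the clinical design (207 cases, 120/37/50 split, all five U-Net depths,
200 epochs).  The **fast** profile — used by the test suite and the
acceptance script — keeps the full pipeline but scales it down: 35 cases
(20/6/9 after the split), the depth-4 U-Net only, 60 epochs with the LR
step at epoch 45 (the full schedule's 0.75 proportion).  Sixty epochs is
where the depth-4 network reaches the MSE floor of the reduced task; at 30
epochs it is still ~70% above it and its SSIM has not yet overtaken
Gaussian smoothing.  The fast profile runs in ~6 minutes on one CPU.

A single master seed is fanned out to the phantom, split, training and
reader stages via `SeedSequence` spawn keys; identical config + seed
reproduces every CSV bit-identically.

## 7. What the synthetic results do and do not show

The phantom reproduces the *mechanics* of the clinical study — count
statistics, paired short/long acquisitions, the pattern taxonomy, the
evaluation battery — but not clinical anatomy, pathology spectra, or human
perception.  Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative conclusions (learned
restoration beats classical filtering; enhanced images read more reliably)
hold under a controlled generative model.  They do not validate diagnostic
performance on patients.  Specific limitations:

* no projection-space physics: attenuation, scatter and reconstruction
  artifacts are absent; noise is exactly Poisson in image domain;
* the phantom's SSIM baseline is optimistic relative to clinical data
  (simple shapes), so absolute SSIM values are not comparable to the
  clinical report — only orderings are;
* simulated readers are confusion-matrix constructs calibrated to the
  clinical agreement bands; κ and ICC magnitudes follow from that
  calibration and carry no independent evidential weight;
* reduced-scale PSNR/SSIM gains (≈ +4.3 dB, +0.07 at seed 1) are larger
  than the clinical gains (+1.8 dB, +0.13 SSIM on a harder baseline):
  an easy phantom task trains to a cleaner optimum;
* quantitative clinical indices (specific binding ratio, asymmetry index)
  are out of scope, as in the clinical validation.
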