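# fastdat

**Deep-learning acceleration of dopamine-transporter (¹²³I-ioflupane) SPECT.**

Conventional DaT-SPECT needs ~25 minutes of acquisition; a single 5-minute
cycle gives images too noisy for confident visual grading of striatal uptake.
`fastdat` trains a compact U-Net to translate single-cycle ("5-min") striatal
slices into virtual full-acquisition ("25-min") images, and evaluates the
restoration the way a clinical validation study would:

* **quantitative image quality** — per-slice PSNR and SSIM against the
  long-acquisition reference, summarised as mean ± SD, compared across
  methods with the Friedman omnibus test and Dunn post-hoc z-tests
  (Holm-corrected) against the reference U-Net;
* **reader agreement** — simulated readers grade each hemisphere on the
  four-point striatal pattern scale (1 = burst striatum, 2 = egg shape,
  3 = eagle wing, 4 = normal); agreement with the gold standard is measured
  by quadratic weighted Cohen's κ, and reader reliability by intra- and
  inter-rater ICC(2,1).

Because clinical DaT-SPECT cohorts are rarely shareable, the package ships a
**synthetic phantom cohort generator**: 3-D activity maps with comma-shaped
striata realising a known pattern per hemisphere, diffuse textured
background uptake, Gaussian collimator blur, and per-cycle Poisson counting
noise such that the long image is the sum of 5 independent cycles and the
short image is cycle 1 alone.  Every stage is seeded and bit-reproducible.

It is aimed at researchers prototyping low-count restoration pipelines for
nuclear-medicine imaging who want the full statistics battery and a
controllable ground truth.

## The core model

The restorer is an encoder–decoder U-Net with 1–5 resolution levels
(filters 16, 32, 64, 128, 256), two 3×3 same-padded conv + ReLU per block,
2× max-pool down / nearest-upsample up, channel-concatenated skips and a
linear 1×1 output head.  Input is a 5-slice window of the short-time stack,
output the matching single long-time slice; training minimises pixel MSE
with Adam (batch 8, LR 10⁻³ stepping to 10⁻⁵ late in training).  The network
and its training loop are implemented in NumPy (`fastdat.nn`), so runs are
deterministic on a single CPU.  Gaussian and bilateral filters of the short
image serve as non-learned baselines.

Metrics: PSNR = 10·log₁₀(MAX²/MSE) dB; SSIM with the canonical 11×11
Gaussian window (σ = 1.5, K₁ = 0.01, K₂ = 0.03);
κ_w = (p_o,w − p_e,w)/(1 − p_e,w) with quadratic weights
w_ij = 1 − (i−j)²/9; ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n).

## Worked example

Run the reduced-scale experiment (35 synthetic cases, depth-4 U-Net vs
short / Gaussian / bilateral, 60 epochs — about 6 minutes on one CPU):

```bash
fastdat all --profile fast --seed 1 --output out/
```

which prints (seed 1):

```
Peak signal-to-noise ratio (dB)
Method                Mean ± SD           P-value (vs unet_l4)
short                 32.377 ± 0.980      <0.001
gaussian              33.082 ± 1.663      <0.001
bilateral             32.543 ± 1.234      <0.001
unet_l4               36.668 ± 0.666
Friedman chi2 = 91.320, p = <0.001

Structural similarity index
Method                Mean ± SD           P-value (vs unet_l4)
short                 0.865 ± 0.007       <0.001
gaussian              0.926 ± 0.006       0.002
bilateral             0.880 ± 0.012       <0.001
unet_l4               0.936 ± 0.004
Friedman chi2 = 127.587, p = <0.001
```

The U-Net gains ~4.3 dB PSNR and ~0.07 SSIM over the raw short images and
beats both classical filters; the Friedman test confirms the differences are
not rank noise, and the Dunn–Holm column gives each method's p-value against
the reference U-Net.  The run also writes the reader-study tables
(`kappa_table.csv`, `icc_table.csv`): with the default simulated readers,
mean κ vs truth rises from ~0.40 on short images to ~0.56 with the U-Net,
while intra-rater ICC stays ~0.90 — enhanced images are both easier to read
and read consistently.

All artifacts (manifest, samples, train logs, checkpoints, metric and stat
CSVs, report) land under `--output`; re-running the same config and seed
reproduces every CSV bit-identically.  A YAML config can replace the profile
(`fastdat all --config my.yaml`); see `fastdat.pipeline.ExperimentConfig`
for the fields.

## Layout

| module | contents |
| --- | --- |
| `fastdat.phantom` | phantom spec, activity volumes, Poisson acquisition pairs, cohorts, simulated readers, ScoreTable |
| `fastdat.preprocess` | max-count slice selection, central 64×64 crop, per-case normalisation, sample assembly, case-level splits, PNG export |
| `fastdat.nn` | NumPy CNN engine (conv/pool/upsample with backprop, Adam) |
| `fastdat.models` | U-Net depth family L1–L5, trainer, Gaussian/bilateral baselines, registry, checkpoints |
| `fastdat.metrics` | PSNR, SSIM, mean ± SD summaries, Friedman, Dunn–Holm |
| `fastdat.agreement` | weighted κ, ICC(2,1), intra/inter-rater and κ report tables |
| `fastdat.pipeline` / `fastdat.cli` | end-to-end orchestration, YAML config, `fastdat` CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
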