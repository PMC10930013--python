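# Methods

## Problem

Coronary artery calcium (CAC) scoring is read on 3-mm CT reconstructions;
thinner slices (0.5/1.0/1.5 mm) resolve small calcifications better but
carry proportionally more quantum noise, since FBP noise SD grows as
`1/sqrt(slice_thickness x mAs)`. This package implements a residual-noise
denoising scheme: a convolutional network is trained to predict the
*quantum-noise map* of a thin-slice image, and denoising is the plain
subtraction `I_denoise = I_thin - sigma_CNN`. The training signal comes
entirely from calibration-phantom scans, so no patient data and no
anthropomorphic phantom are needed:

* label: the **real noise map** `sigma_real = I_thin - I_3mm`, where the
  3-mm image of the same anatomy acts as the low-noise reference;
* input: the **pseudo noise map** `sigma_pseudo = I_thin - S(I_thin)`,
  where `S` is 2x2 block averaging (512 -> 256) followed by 2x bicubic
  upsampling (256 -> 512). `sigma_pseudo` needs no paired scan, which is
  what makes the trained model applicable to any thin-slice image.

Because both maps are approximately anatomy-free, the network learns a
noise-to-noise mapping rather than an image prior, which limits the
over-smoothing typical of image-domain CNN denoisers.

## Phantom simulator

The package replaces physical phantoms with a parametric simulator.

**Geometry.** Electron-density phantoms `CIRS_S/M/L` (bodies 180 mm,
230 mm, 320x270 mm) carry nine 30-mm rods: lung inhale/exhale, adipose,
breast, muscle, liver, and hydroxyapatite bone at 200/800/1250 mg/cc,
one rod central and eight on a 55-mm ring. Thorax phantoms `QRM_S/M/L`
(bodies 300x200 / 350x250 / 400x300 mm) carry a 100-mm calibration
insert with nine cylindrical calcifications: {1, 3, 5} mm diameter x
{200, 400, 800} mg HA/cm^3 on a 25-mm ring. Rasterization is
area-weighted at 4x supersampling, so small calcifications acquire
realistic in-plane partial-volume boundaries. Air is -1000 HU. The grid
is the routine CAC geometry: 512x512 over a 22-cm FOV (0.4297 mm/px).

**HU and noise calibration.** Each material's mean HU and its noise SD
at the 3-mm anchor are set to reference measurements taken per phantom
size (larger bodies: slightly different means, larger SD). Tube currents
are fixed per phantom (40/80/300 mA CIRS, 40/50/140 mA QRM) and folded
into the SD scaling `sd_3mm_ref * sqrt(3 * mA_ref / (z * mA))`.

**Noise texture.** Quantum noise is zero-mean correlated Gaussian:
white noise low-pass filtered with an isotropic Gaussian kernel
(FWHM = 2 px), renormalized to unit pointwise variance, then scaled by
the per-material SD map. This emulates smooth soft-kernel FBP mottle
without sinogram-domain simulation; it does not reproduce a specific
reconstruction kernel's noise power spectrum, streaks, or
tube-current-modulation dynamics.

**Thin/3-mm pairing.** A scan pair at thickness z consists of n = 3/z
thin-slice noise realizations of the same noise-free content; the thin
image is the first realization and the 3-mm image is their pixelwise
mean (exact, at bit level, in the float64 accumulation of the float32
stack). Realizations share a common noise component:
`field_i = sqrt(rho) * shared + sqrt(1 - rho) * independent_i`.
With `rho = 0` the 3-mm SD is `1/sqrt(n)` of the thin SD (pure
averaging); the default `rho = 0.10` is calibrated once so that the
thin/3-mm SD ratio at z = 1.5 mm is ~1.35, the ratio observed in
soft-tissue ROIs of measured reconstructions (independent slices would
give sqrt(2) ~ 1.41). All randomness flows through explicit seeds;
dataset i of an acquisition protocol uses `base_seed + i`.

**What the simulator does not model.** No sinogram/FBP chain, beam
hardening, ECG gating or cardiac motion; no through-plane (z) partial
volume — thin and 3-mm images share in-plane content exactly, by
construction. The last point matters for interpretation: measured
thin-vs-3-mm calcification masks differ only through noise, so their
Dice overlap is higher (~0.97-0.99) than on real scanner data, where
3-mm partial volume also changes the reference mask. Passing tests on
simulated pairs therefore demonstrate the algebra and the noise
behaviour of the pipeline, not clinical performance.

## Network and training

The regressor is a compact DenseNet-style fully convolutional network:
a 3x3 input convolution (8 features), 4 dense blocks x 2 layers with
growth rate 6 (each 3x3 layer sees the concatenation of all previous
features), and a linear 3x3 reconstruction layer over the full
concatenation — a skip path from every depth to the output. Zero
padding keeps spatial size, so the model trains on 25x25 patches and
runs seamlessly on whole 512x512 maps (receptive field 21 px,
~13k parameters). Weights are MSRA-initialized (variance `2/fan_in`),
biases zero.

This topology is an order of magnitude smaller than the published
DenseNet regressors it imitates; it was chosen so that a training run
completes in minutes on one CPU in pure numpy. Among desk-scale
variants we selected the one with the smallest spurious response to
noise-free edges (measured on rasterized phantoms), since that response
bounds the systematic error the subtraction injects at calcification
boundaries; depth (receptive field) mattered more than width.

Training minimizes batch RMSE in HU with Adam (batch 32, learning rate
1e-4, beta1 = 0.9 — the "momentum" of the adaptive optimizer — beta2 =
0.999) and decoupled L2 weight decay 1e-4 on convolution weights only.
Patches are fed in raw HU without normalization. The minibatch schedule
is a pure function of (seed, iteration) — per-epoch permutations of a
virtual sample stream — so checkpoint resumption is bit-exact.
Training arithmetic defaults to float32 (float64 available via
`TrainConfig.precision` for numerical audits). The desk-scale profile
runs 2000 iterations (~10 min on one CPU); the published-scale setting
of 1e5 iterations is plain configuration. One model is trained per
slice thickness; `denoise` refuses a model/image thickness mismatch.

## What the scaled-down study shows

On the desk profile (train: CIRS_S at z = 1.5 mm, 5 rod configurations,
2000 patch pairs; validate: a held-out simulated QRM_S series) the
trained model cuts the training RMSE to ~0.4 of its initial value,
reduces flat-ROI SD from ~31 to ~23 HU against ~24 HU in the 3-mm
reference, and shifts ROI means by well under 1 HU. These are the
package's own measured numbers (see the acceptance tests), not claims
about scanner data.

Two ceilings are worth naming. First, the pseudo map only carries the
noise frequencies above the block-average/bicubic cutoff; with the
simulator's smooth mottle that bounds the achievable training RMSE at
~21 HU regardless of model size (the optimal linear filter reaches
about the same). Second, the model inevitably retains a small
systematic response at high-contrast edges of *small* objects it never
saw in training (CIRS rods are 30 mm; calcifications are 1-5 mm), which
perturbs a few boundary pixels of the densest calcifications. Because
simulated thin/3-mm Dice starts at 0.97-0.99 with seed-to-seed
fluctuations of about +-0.01, the ordering "denoised Dice >= thin
Dice" holds for most but not all noise seeds and densities; the same
training-domain gap is a known limitation of training such denoisers on
electron-density phantoms only.

## Numerical conventions

* CT pixels are float32 HU; noise maps are float64. The difference of
  two float32 images is exact in float64, making the closure
  `thin - sigma_real == thick` bit-exact, and the oracle substitution
  (real map in place of the CNN output) reproduces the 3-mm image
  exactly.
* Bicubic upsampling uses the Keys kernel (a = -0.5) with
  half-pixel-centre alignment (each 2x2 output block centred on its
  source pixel) and edge replication at borders; constants and linear
  ramps are reproduced to rounding.
* Patch tiling starts at the origin with stride 25; the 12-px
  right/bottom margin of a 512 grid is discarded (20x20 = 400 patches
  per map).
* PSNR is `20*log10(HU_max / RMSE)` with `HU_max` from the reference
  image, so different candidates share one ceiling; identical images
  report +inf.
* Calcium threshold: HU >= 130 included. Agatston bins are half-open
  (130-199 -> 1, 200-299 -> 2, 300-399 -> 3, >= 400 -> 4).
* ROI t-tests are Welch (unequal variance), two-sided, significance at
  p < 0.01; identical samples report p = 1. Rod ROIs are concentric
  circles at 2/3 of the rod radius (clear of boundary partial volume);
  the thorax background ROI is a 15-mm circle at the calibration-insert
  centre, inside the calcification ring.
* `dice(empty, empty) = 1` (perfect agreement on absence). Calcification
  Dice is reported per calcification and pooled per HA density over the
  3- and 5-mm sizes; 1-mm calcifications are excluded from Dice
  analysis (not reliably detectable at 3 mm).
* DICOM export quantizes HU to signed 16-bit with round-half-to-even,
  slope 1 / intercept 0; the array backend round-trips float32 exactly.
  Pixel (0,0) is top-left, x = column, y = row, geometry in mm with the
  origin at the grid centre.

## Open choices made here

* Rod-removal order (which pairs leave at each configuration) is not
  canonical; the default removes lung/bone pairs first and never
  removes the central muscle rod, so every configuration keeps a
  soft-tissue reference. It is configurable.
* The sign of the noise maps is fixed by requiring that the denoising
  subtraction reduce noise: `sigma = thin - thick`.
* One model per slice thickness (the per-z notation of the noise maps
  suggests per-z models); no interpolation between models.
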