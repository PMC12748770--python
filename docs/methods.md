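# Methods

`hepachrom` simulates and analyses a smartphone-based colorimetric
liver-function analyzer: a microfluidic flow cell holding a reacted
chromogenic sample is imaged under controlled LED illumination, and a
convolutional neural network regresses the biomarker concentration directly
from the RGB image. This note documents the models, the parameters that
matter, and the design choices made where the underlying system left them
open.

## The phantom image model

Real captures are photographs of an optically clear chamber (the flow cell)
surrounded by a dark enclosure. The synthetic renderer reproduces the
statistical structure that matters for regression, not the optics of the
device:

1. **Chamber colour.** Per-channel Beer–Lambert transmission with a
   saturating effective concentration:

   c_eff = s·(1 − e^(−c/s)),   rgb(c) = blank_rgb · 10^(−ε · c_eff)

   where ε is the per-channel absorptivity and s (`saturation_conc`) the
   concentration scale at which the colour change flattens. At low c the
   intensity change is proportional to concentration (the regime the assay
   chemistry is designed for); at the top of the range it saturates, which
   is what makes naive single-channel inversion inaccurate and motivates a
   learned regressor. Colour directions follow the chemistry: the
   azobilirubin chromophore (pinkish) absorbs green strongest; the
   2,4-DNPH hydrazone (brownish red) absorbs blue/green. Absorptivities are
   scaled so the six calibration levels of each assay are widely separated
   in chamber mean colour.
2. **Geometry.** The chamber fills the central 80% of each axis (64% of
   pixels) over a dark background (the acrylic support block); nothing else
   about the real framing is modelled.
3. **Illumination.** A radially symmetric field
   I(r) = I₀·(1 − v·r²) with centre intensity I₀ ≤ 1 and vignette strength
   v (default 0.12). Each captured original draws I₀ from a small uniform
   jitter (2% by default), emulating session-to-session LED drift.
4. **Device rendition.** Channel-wise
   clip((gain·x + offset)^γ, 0, 1) followed by additive Gaussian sensor
   noise (σ = 0.008–0.012 on the [0,1] scale). The `reference` profile is
   the identity; the regressor is always trained on it.
5. **Augmentation.** A seeded random subset of {horizontal flip, vertical
   flip, rotation within ±10°, brightness shift within ±5%, contrast scale
   within ±5%}, two augmented copies per original (a 2:1 augmented:original
   ratio). Labels are untouched.

Every image carries its own seed derived from a master seed via
`numpy.random.SeedSequence([master, level, replicate, ...])`, so datasets
are bit-reproducible and parallel-safe.

**What the phantom does not emulate:** real chromogen spectra and
inter-batch reagent variation, bubbles/debris in the chamber, focus and
demosaicing artefacts, JPEG compression, and spatial chemistry gradients.
Passing the synthetic suite therefore shows the pipeline is correct and
well-conditioned under the stated noise model — not that the trained
network would transfer to real photographs.

## The regressor

Fixed conv stack 32→64→128→128 (3×3 kernels, same padding, ReLU, 2×2 max
pool after each block), dense 512 + ReLU, linear single-output head. At the
full 128×128 input the spatial trace is 128→64→32→16→8 (flatten length
8192, 4,436,161 parameters). Training: Adam (lr 10⁻³), MSE in native assay
units, batch 32, up to 40 epochs (best observed epoch in the full-scale
system; realised here as checkpoint-on-lowest-validation-MSE rather than a
hard stop), validation = a seeded 10% carve-out of the training partition.
Predictions are clipped at 0. The network is implemented directly in NumPy
(im2col convolutions + BLAS matmuls, float64): at the problem sizes used
the models train in minutes on one CPU and runs are bit-reproducible for a
fixed seed, which the test suite exploits.

Reduced problem sizes used throughout: 900 images per biomarker (6 levels ×
50 originals × (1+2 augmented)) — the same dataset size the full-scale
system reports for its classification study — at 48×48 for the acceptance
runs and 32×32 for the test-suite fixture; the full-scale configuration
(250 originals/level at 128×128) is available through the same API.

## Two-point cross-device recalibration

A regressor trained on the reference device drifts on another handset. With
captures made inside a light-isolated enclosure at fixed manual
ISO/shutter/white-balance, the residual inter-device differences are
percent-level responsivity (gain), tone-curve (γ) and black-level (offset)
shifts; their effect on the prediction scale is then approximately affine.
The correction is the unique affine map sending the predicted blank to 0
and the predicted mid-range standard (10 mg/dL for bilirubin; 150 U/L
default for the enzyme assays, configurable) to its known value:

slope = c_mid/(p_mid − p_blank), intercept = −slope·p_blank.

For an exactly affine distortion the recovery is exact (tested to machine
precision). For the rendered gamma distortions a curvature residual
survives two-point anchoring — largest at the edges of the range, a few
percent at 5 mg/dL — which is why deviations are reported as the mean over
devices and concentrations, each measured as the mean of several replicate
captures. Both pre- and post-recalibration deviations are reported, against
ground-truth expected concentrations.

## Repeatability contexts

The three precision contexts are modelled as nested common-mode
perturbations on top of per-capture sensor noise: *same-day* — noise only;
*different-day* — LED intensity jitter (σ = 0.5%); *different-user* —
larger illumination jitter (σ = 1%) plus a common-mode optical-gain jitter
(σ = 0.3%) for handling/positioning. Jitters are common-mode because the
handset and its manual settings are unchanged across users — a user cannot
alter per-channel sensor gains. All scales are configuration knobs on
`run_repeatability`. %CV uses the sample (n−1) standard deviation, 10
replicates per concentration per context.

## Validation statistics

- **Agreement**: Pearson r (scipy), % variation = 100·|y−x|/x with the
  commercial reading x as denominator, and the CLIA total-allowable-error
  check (±10%, boundary inclusive). A bundled example panel of paired
  commercial-vs-developed readings (five serum samples per analyte) ships
  with the package for the worked example.
- **Regression**: MAE, RMSE, R² (scikit-learn), cross-checked in tests
  against direct-summation oracles.
- **Classification**: regression outputs are binned into five clinical
  categories (Very Low … Very High; left-closed/right-open bins). Default
  edges — bilirubin (0.5, 3, 7.5, 12.5) mg/dL, ALT/AST (30, 75, 125, 250)
  U/L — separate the six calibration levels across the five names and are
  fully configurable. One-vs-rest accuracy/sensitivity/specificity with
  unweighted macro averages (classes are balanced by construction; ratios
  with zero denominators are excluded). ROC AUC uses the negative absolute
  distance from the predicted concentration to each bin's midpoint as the
  class score (the open top bin's midpoint is its lower edge plus half the
  width of the bin below); AUC is cross-checked against a Mann–Whitney
  pair-counting oracle.
- **LOD**: 3·SD(blank replicates)/low-range calibration slope (n = 5
  convention; the multiplier is a parameter).
- **Dilution advice**: readings above the validated range trigger a 1:5
  dilution prompt; the corrected value is the re-measured value times the
  factor.

## Numerical and degenerate-input conventions

Bins are right-open, so a concentration exactly on an edge belongs to the
upper category. Stratified splitting rounds `train_fraction·n` per stratum
and refuses strata with fewer than two members or an empty partition,
naming the stratum. Pearson r and R² raise on constant sequences rather
than returning NaN; %CV raises on zero mean; percentage deviations raise on
zero reference. Max-pool gradient ties share the gradient equally (ties are
measure-zero for continuous inputs). PNG round-trips quantise to 8 bits;
tests compare at half-a-grey-level tolerance.

## Known limitations

- The synthetic R², deviation and %CV figures characterise the pipeline
  under the stated noise model; they are not evidence about real serum
  measurements.
- The two-point correction degrades if a device's distortion is strongly
  nonlinear over the calibration range; a multi-point curve (out of scope)
  would be needed.
- Category classification is binned regression; no separate classifier
  head is trained.
- Enzyme-assay recalibration uses a 150 U/L mid-range standard by default;
  the real protocol specifies a standard only for bilirubin.
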