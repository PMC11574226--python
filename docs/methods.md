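# Methods

## Problem and pipeline

Motion blur — from compression-paddle relaxation or patient movement —
degrades mammograms locally and is normally caught, inconsistently, by
human readers. `mammoblur` implements an automated detector built on a
classical image-quality statistic, the normalized Wiener spectrum (nWS),
coupled to a compact learned classifier:

1. **Preprocess**: pad the mammogram with zeros onto a square canvas
   (columns added on the side away from the chest wall, rows at the
   bottom), normalize intensities to [0, 1], and segment the breast
   interior (Otsu threshold → largest connected foreground → hole filling
   → inward erosion that strips the skin line → optional pectoralis
   subtraction).
2. **Windowing**: slide a 200 × 200 px window (1 × 1 cm at 0.05 mm pitch)
   over the canvas on a non-overlapping lattice; keep windows ≥ 90% inside
   the analysis mask.
3. **nWS**: per window, detrend, taper, Fourier transform, radially
   average, normalize (details below).
4. **Classify**: a 1-D CNN maps each spectrum to a blur probability.
5. **Decide**: threshold the probability map at 0.45, keep 8-connected
   components of at least ten windows with mean probability ≥ 0.65; the
   image is *blurred* iff a component survives.

## The nWS estimator

For a square ROI of side *N* and pixel pitch Δx (mm):

- **Detrend**: subtract the mean (default) or a least-squares 2nd-order
  polynomial surface (`poly2`, for breast-thickness gradients).
- **Taper**: multiply by a separable Hann window (Hamming and Tukey are
  offered). Tapering suppresses the edge-discontinuity ringing that would
  otherwise contaminate the spectrum.
- **Transform and scale**: the 2-D power is |FFT|² · Δx² / (N² · mean(W²)),
  where W is the 2-D taper. With this scaling the discrete spectral
  integral Σ P · Δf² equals the variance of the detrended, tapered ROI
  divided by the mean squared taper — an exact Parseval identity that the
  test suite asserts for every offered taper, and which makes the white-
  noise integral an unbiased estimate of the noise variance.
- **Radial average**: each sample at (u, v) goes to the bin whose center
  k · Δf is nearest to √(u² + v²); Δf defaults to the native resolution
  1/(N·Δx) (0.1 mm⁻¹ for a 200-px window at 0.05 mm). The DC bin is
  excluded (it carries only detrend residual), and bins above the axis
  Nyquist 1/(2Δx) are dropped, discarding the anisotropically sampled
  corner frequencies. An empty interior bin (possible only with
  non-native bin widths) is filled by linear interpolation with a warning.
- **Normalize**: `unit_area` (default) divides by Σ v · Δf so every
  spectrum integrates to exactly 1. This makes the spectrum invariant to
  any global intensity rescaling of the ROI — the property that lets one
  model serve detectors with different gains and doses. `mean_square`
  (division by the squared mean ROI signal) is retained for comparison
  with the classical normalized-NPS convention.

Exact floating-point ties at bin edges are resolved deterministically by
`floor(r/Δf + 0.5)`; the radial average is checked bin-for-bin against a
brute-force double-loop oracle.

## Classifier

Architecture: 1-D convolution (128 filters, kernel 3, stride 1) over the
100-bin spectrum → batch normalization → ReLU → dropout 0.3 → flatten →
dense layer to 2 logits → softmax. Training uses Adam (learning rate
1e-5), batch size 50, class-weighted cross-entropy (weights inversely
proportional to class frequency, normalized to mean 1), early stopping on
validation loss with patience 10 and a 200-epoch cap; the best-validation
parameters are returned.

Two design choices where the architecture description leaves room:

- **ReLU after batch normalization.** Without a nonlinearity the
  conv/BN/dense stack collapses to an affine map; the conventional reading
  of a convolutional layer includes its activation.
- **Input standardization.** nWS densities span roughly five orders of
  magnitude from the lowest to the highest frequency bin. A per-bin
  z-scoring layer, fitted on the training set and stored with the model,
  precedes the convolution. Without it, gradient descent at this learning
  rate cannot balance bins of such disparate scale; with it the training
  dynamics are well-conditioned. The transform is affine and per-bin, so
  it does not alter what the network can express, only how fast it gets
  there.

The network is implemented directly on numpy. At ~25k parameters,
vectorized CPU linear algebra trains in seconds to minutes, gradients are
verified against central differences in the test suite, and a single seed
controls initialization, batch order and dropout, giving bit-reproducible
training. A config-driven grid-search harness reproduces the 5-fold
patient-stratified cross-validation selection protocol over
(n_filters, dropout, learning_rate).

## Decision cascade

"Interconnected windows" is interpreted as 8-connectivity on the window
lattice (diagonal neighbors count; 4-connectivity is a config switch), and
the component mean is computed over its surviving cells only. Component
means are accumulated with correctly-rounded summation (`math.fsum`) so
that a mean landing exactly on the 0.65 threshold resolves independently
of cell order. The cascade is monotone — raising any cell's probability
can never flip a blurred verdict to sharp — and is tested against an
exhaustive BFS enumeration oracle on small grids.

The sliding stride defaults to the window size (non-overlapping lattice),
which makes "ten interconnected windows" a plain connected-component count;
overlapping strides are supported but off by default.

## Statistical evaluation

- AUROC by the Mann–Whitney rank statistic (ties credited 0.5), with a
  percentile bootstrap CI (default n = 10,000 resamples with replacement)
  and a one-sided one-sample t-test of the bootstrap values against 0.5.
- Threshold sweeps report per-threshold confusion matrices with
  stratified-bootstrap CIs on the class-conditional rates; the operating
  point maximizing TPR + TNR (Youden's J) is flagged.
- Cohen's κ with marginal-product expected agreement; weighted accuracy
  with inverse-frequency weights, which reduces to balanced accuracy,
  (sensitivity + specificity)/2. Note that reader-study reports sometimes
  pair confusion counts with a "weighted accuracy" computed by an
  unpublished weighting: the bundled example table (tp 26/32, tn 97/127)
  gives balanced accuracy 0.788, whereas the figure printed alongside
  those counts elsewhere is 0.840. The package implements the standard
  definition and documents the discrepancy rather than reverse-engineering
  an undefined formula.
- χ² test of independence with Yates continuity correction on 2 × 2
  tables (switchable); Spearman ρ with midranks; Shapiro–Wilk normality
  (delegated to scipy; valid for 3 ≤ n ≤ 5000).

## Shapley attribution

A permutation-sampling estimator: for each sampled feature ordering, a
background spectrum (drawn from sharp-window spectra) is morphed bin by
bin into the explained spectrum and each bin is credited with the blur-
probability change it causes. Per-bin means are exact Shapley values in
the sampling limit; the Monte-Carlo standard error and the efficiency
residual |Σφ − (f(x) − E_bg f)| are reported alongside. For a linear model
the estimator is checked against the closed form φᵢ = wᵢ(xᵢ − E[xᵢ]).
Aggregation over the windows classified as blurred (probability ≥ 0.45)
yields the per-frequency mean ± SE profile and a bar-plot rendering.

## Synthetic phantoms

The generator is the package's self-contained test bed and defines the
study conditions for every learned-component test:

- **Support**: a half-ellipse abutting the chest-wall edge given by
  laterality (vertical semi-axis 0.47 × height, horizontal 0.85 × width).
- **Anatomy**: a breast-thickness dome (0.5 base + 0.35 dome) plus a
  power-law textured Gaussian field with spectral exponent β = 3.0 —
  within the 2.5–3.5 range accepted for mammographic anatomical texture —
  at amplitude 0.12.
- **Quantum noise**: Gaussian with standard deviation 0.01·√signal,
  emulating Poisson statistics at mammographic exposure.
- **Motion blur**: convolution with a unit-sum line PSF (supersampled,
  bilinearly deposited, so oblique angles keep unit mass exactly),
  blended smoothly (σ = 4 px) at the polygon boundary. Noise is added
  *after* the blur: motion smears anatomy, not per-pixel photon counts,
  which is what keeps high-frequency spectral power alive inside real
  blurred regions.
- **Quantization**: 16-bit integers, so phantoms round-trip bit-exactly
  through PNG.

Cohorts contain 4 views (L/R × CC/MLO) per synthetic patient; each view
independently receives one blur region with the configured prevalence.
PSF lengths are drawn from 6–12 px (0.3–0.6 mm of motion — the amplitude
range that visibly degrades mammograms). Blur polygons are lattice-aligned
rectangles of 12–16 windows placed fully inside the eroded support, so the
ten-window image-level rule is geometrically satisfiable by construction.

**Problem sizes.** Module-level tests use 1,200-px (6-cm) phantoms. The
end-to-end experiment uses a 1,600-px (8-cm) canvas: a ten-window (10 cm²)
lattice-aligned region cannot fit inside the breast support of a 6-cm
half-ellipse, so 8 cm is the smallest canvas on which the full decision
cascade is exercisable; clinical 25-cm mammograms carry it trivially. The
end-to-end experiment trains on a 25-patient cohort (100 images) and
evaluates on a held-out 10-patient cohort with disjoint seeds and patient
namespaces.

**What passing means.** The phantoms share real mammograms' gross spectral
morphology (power-law anatomy over a quantum-noise floor, blur draining
the 1–3 mm⁻¹ band) but none of their hard parts: no vendor-to-vendor
detector differences, no pectoralis, folds, calcifications or implants, no
reader disagreement in the labels, and blur regions are clean rectangles
rather than free-hand polygons. High synthetic AUROC therefore validates
the machinery — spectra, learning, decision logic — not clinical
performance: on real mammograms the anatomical variability, vendor
differences and label noise make window-level discrimination materially
harder (clinically reported AUROCs for this task sit near 0.8, far from
the near-perfect separation phantoms allow).

## Numerical and degenerate-input conventions

- Constant rasters normalize to all-zeros with a degeneracy warning;
  all-zero spectra are flagged `degenerate` rather than raising.
- ROIs must be ≥ 16 px square and ≥ 95% inside the analysis mask
  (placement error otherwise); analysis windows need ≥ 90% coverage and
  are blurred-labelled at ≥ 50% polygon overlap.
- Patient-stratified splits shuffle patients by seed and fill greedily to
  the target record fraction; folds balance record counts largest-first.
  No patient ever appears on both sides of any split, asserted at
  training time.
- MONOCHROME1 DICOMs are inverted on read to the monotone-increasing
  photometric convention; pixel-spacing/laterality/view overrides take
  precedence over file tags, and their absence in both places is an error,
  never a guess.

## Known limitations

- The pectoralis "segmentation" shipped here is a geometric corner
  heuristic, explicitly a stand-in; supply a real mask for MLO clinical
  work.
- The normalization constant of the source study's spectra is not public;
  `unit_area` is this package's reading (it is the one that yields a
  dose/vendor-independent scale), with `mean_square` as the alternative.
- Bootstrap resampling treats windows (window-level metrics) and images
  (image-level metrics) as the exchangeable unit, not patients.
- Overlapping-stride probability maps compute connectivity on lattice
  adjacency regardless of pixel overlap.
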