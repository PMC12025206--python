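# Methods

## Problem and pipeline

A colorimetric immunoassay read by a phone camera produces an 8-bit RGB
photograph of a backlit measurement cell. The concentration signal lives in
the color of the flat liquid inlet; everything else in the frame is
housing texture. The pipeline is:

1. locate the inlet as the lowest-gradient window (ROI extraction),
2. summarize its color with the RGBscore, a weighted channel mean,
3. calibrate weights and curve by exhaustive search against known
   standards,
4. invert the curve for unknowns; derive a detection limit from blanks.

## ROI extraction

* Grayscale: BT.601 luma (0.299, 0.587, 0.114), configurable. Any
  fixed positive combination would do for flatness ranking; BT.601 is the
  default of mainstream imaging libraries.
* Texture filter: the 3×3 8-direction Laplacian (center −8, neighbors +1)
  with replicate-edge padding, followed by the absolute value so that
  positive and negative curvature both count as texture. The kernel is
  zero-sum, so the ranking is invariant to adding a constant to the image.
* Window statistic: the mean of absolute responses inside the window
  (scale-free in the window size; `sum` available). Windows are 200 px
  squares by default, slid with stride 10 px; the maximal origin along each
  axis is always visited (end-clamping), so the bottom-right corner is
  covered for any image size. Stride 1 gives an exhaustive scan.
* Tie-break: the first minimal window in row-major order, deterministic by
  construction (`argmin` on the row-major scan).
* The scan uses a summed-area table; the winning window's statistic is then
  recomputed directly on the gradient-map slice, so the stored value equals
  a direct recomputation bit-for-bit.

The exact pixel coordinates of a published ROI are not reproducible without
the original stride (unknown); what the module guarantees — and what the
tests assert — is the flat-region property: on any image whose flat patch
is larger than the window and strictly flatter per window than the
background, the selected window lies entirely inside the patch.

## Scoring and brute-force calibration

RGBscore(ROI; α, β, γ) = mean(α·R + β·G + γ·B). The score is linear in
each channel and each weight, so per-level scores for all weight triples
are one matrix product with the per-level channel means. The grid is
α, β, γ ∈ {k·step : k integer} ∩ [−1, 1], step 0.05 by default
(41³ − 1 = 68,920 triples; the all-zero triple is excluded). Grid values
are computed as k·step from integers, never by repeated addition.

Model fits, all batched over triples:

* linear — closed-form OLS.
* logarithmic, y = a·ln(x + b) + c — the only reading of the published
  "a log x + b + c" form that is defined at x = 0, which every calibration
  series includes; the base is absorbed into a. For fixed b the fit is
  linear, so b is profiled: 49 candidates geometrically spaced from
  10⁻⁶·max(1, x_max) to 10⁴·(x_max + 1) (the upper decades make ln(x + b)
  effectively affine, so the model nests the linear one), then 48
  golden-section iterations on ln b inside the bracketing interval.
* logistic4, y = a/(1 + b·e^(−c·x)) + d — the four-parameter logistic
  (the literal "a{1 + b·e^(−c·x)} + d" reading has only three effective
  parameters and is not a sigmoid). Fitting is Levenberg–Marquardt with a
  fixed 100-iteration budget, per-triple damping (×5 on reject, /3 on
  accept), and analytic initialization: d ≈ min y (max y for decreasing
  series), a ≈ signed range, c ≈ 4/x-span, inflection at the half-range
  crossing. Fits ending with non-finite parameters are flagged
  `converged = False` with R² = −∞. Final parameters are canonicalized to
  c ≥ 0 via the identity a/(1+b·e^(−cx)) = −a/(1+(1/b)·e^(cx)) + a.

Degenerate triples (zero score variance, e.g. identical images at all
levels) are assigned R² = 0 rather than an undefined value. Zero variance
is detected with a scale-aware floor (n·(10⁻¹⁰·scale)²) because summing
identical floats need not center to exactly zero.

Per model, triples are ranked by R² rounded to 10⁻⁶; ties go to the
lexicographically smallest (α, β, γ), which the row-major enumeration
delivers as the first maximum. The winning triple is then re-scored on the
raw ROI pixels and re-fit, so reported parameters are exactly what a naive
per-triple enumeration produces — the test suite checks this equality
against an independently written brute-force oracle on reduced grids.

### Cross-model selection and parsimony

Within a model the raw maximum R² is the selection rule. Across models it
cannot be: the four-parameter logistic *nests* near-affine shapes
(c → 0) and approximates logarithmic ones on any finite level set, so with
a competent optimizer its best R² is ≥ the linear and logarithmic maxima,
minus noise-level slack, on essentially any real series — raw
maximization would select the logistic family almost surely, regardless of
the data-generating law. (Published per-model tables in this application
area often show suspiciously low logistic R², consistent with
non-converged fits rather than a real ranking.) The overall winner is
therefore the per-model winner with the highest R² rounded to 10⁻³, ties
resolved in parsimony order linear → logarithmic → logistic4. On ≤ 18
calibration points an R² difference below 10⁻³ carries no evidence, and
this rule makes model selection identifiable: with phantoms generated
under each law, the matching model is selected 10/10 times per law in the
acceptance checks, while the mis-matched laws stay separated by far more
than the rounding (linear fits of log-law data land near R² ≈ 0.9).

## Quantification

* Inversion is exact algebra per model kind; the invertible score interval
  is the fitted curve evaluated at the calibrated concentration extremes
  (monotone on that interval for all three kinds). Scores outside it are
  clamped to the nearest calibrated endpoint and flagged
  (`clamped = True, in_range = False`) rather than extrapolated — beyond
  the calibrated range the curve flattens and score noise maps to
  unbounded concentration error.
* Detection limit: the blank mean score is shifted by k standard
  deviations (sample sd, ddof = 1; k = 3 default) in the direction of
  increasing concentration, both scores are inverted, and the LOD is the
  separation. For a linear calibration this reduces to k·sd/|a|. Identical
  blanks give LOD = 0 with a warning. The k-sigma convention is the field
  standard when no formula is published alongside a reported LOD.
* Method comparison: Pearson product-moment correlation (scipy), with the
  paired values and means reported.

## Synthetic phantoms

`render_phantom` emulates a backlit measurement-cell photograph: a flat
square inlet over a textured background (checkerboard tiles of 8 px at
±30 intensity around mid-gray, or uniform speckle), per-pixel i.i.d.
Gaussian sensor noise in the inlet, 8-bit quantization. The inlet color
follows a Beer–Lambert-style law per channel,

    I_i(c) = I0_i · 10^(−k_i · f(c)),   i ∈ {R, G, B},

with f a normalized response in [0, 1]: f(c) = c/c_ref (`linear`),
ln(1 + c)/ln(1 + c_ref) (`log`), or a sigmoid in c rescaled so f(0) = 0
(`logistic`). Choosing f makes the matching calibration family the true
score–concentration law, which is what lets model-selection recovery be
tested at all.

Defaults, chosen once to resemble a TMB-type yellow reaction under a
warm-white backlight: base color (235, 228, 210); k = (0.04, 0.12, 0.35),
i.e. ~9%/24%/55% maximum attenuation of R/G/B — a clearly visible but
unsaturated color change; c_ref = 880 pg/mL (the top calibration level);
logistic inflection at 150 pg/mL with width 60, placing the slow-change
region near 200 pg/mL as observed for this assay class; noise_sd = 2
intensity units; image 1280×960 with a 260 px inlet (reduced-geometry
variants are used in tests where the criterion does not fix the size).
Seeding uses numpy's SeedSequence/PCG64; each image of a calibration set
draws from a generator derived from (seed, level index, replicate index),
so any subset regenerates identically.

What the phantoms do **not** model: demosaicing, firmware tone curves and
white balance, lens shading, perspective, illumination gradients, JPEG
artifacts. Passing tests therefore demonstrate the correctness of the
algorithmic chain (ROI search, scoring, exhaustive calibration,
inversion), not robustness to real device-to-device color processing —
the very variability the weight search exists to absorb; on real data that
must be established with real photographs.

A useful side effect of sensor noise: with noise ≥ ~1 intensity unit the
8-bit rounding dithers and the window mean becomes an almost unbiased
estimate of the continuous law (residual score noise ~σ/window ≈ 0.01
units), whereas a noiseless flat inlet keeps a deterministic quantization
offset up to 0.5 units per channel. Both regimes are exercised in the
tests; analytic blank-noise formulas include the 1/12 quantization
variance.

## Problem sizes and numerical choices

* Acceptance-style checks run on reduced geometries (420×560 images,
  260 px inlet) and reduced grids (step 0.25 or 0.1) where the property
  under test does not fix them; the full 0.05 grid on default-size images
  is exercised once per run (≈ 8 s vectorized).
* Oracle-equivalence checks use 5 seeded series on steps 0.5 and 0.25, all
  three models, and assert float-exact equality of winning triples,
  parameters and R².
* Tolerances: per-model tie rounding 10⁻⁶; cross-model selection rounding
  10⁻³; round-trip identity 10⁻⁹ relative; stored R² vs recomputation
  10⁻⁹.
* Unknown-sample recovery on log-law phantoms achieves ≈ 0.4% mean
  absolute relative error (20 seeds × 4 unknowns); Monte-Carlo LOD agrees
  with the analytic k·σ_score/|slope| within a few percent.

## Known limitations

* Replicates enter fits as separate points; no weighting or pre-averaging.
* The logarithmic profile assumes a unimodal SSE in b (holds on all tested
  series); a pathological multimodal profile could pin b to a local
  optimum between grid candidates.
* The logistic LM budget is fixed, not adaptive; extremely ill-scaled
  series may stop short of the optimum (flagged only if parameters go
  non-finite).
* Clamping hides gross extrapolation but also truncates genuinely
  out-of-range samples; dilution remains the correct remedy.
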