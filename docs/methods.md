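# Methods

## Model and assumptions

The package implements gap-fraction analysis of upward-looking (0° zenith)
canopy photographs. The physical model is Beer–Lambert attenuation of light
through a turbid medium of leaves: if a crown of cover `f_c` transmits a
within-crown gap fraction `Φ`, the leaf area index follows from inverting
`Φ = exp(−k · LAI / f_c)`, giving `LAI = −f_c ln(Φ) / k`. The clumping
index `Ω(0) = (1 − Φ) ln(1 − f_f) / (ln(Φ) f_f)` corrects for non-random
foliage dispersion; effective LAI is `LAI_e = LAI · Ω(0)`.

Assumptions inherited from the cover-photography method:

- the camera looks straight up (a single zenith angle; no ring-wise
  gap-fraction integration as in hemispherical photography);
- sky and canopy are separable in the blue channel (true for clear or
  overcast sky with the sun out of frame);
- leaves are opaque; woody material is counted as canopy, so the output is
  strictly a plant area index unless a bare-canopy baseline is subtracted;
- the extinction coefficient `k` is constant within an image, in (0, 1]
  (0.7 default for vertically trained, continuous grapevine canopies).

## Pipeline and parameters

| parameter | default | meaning |
|---|---|---|
| `grid_n` | 5 | sub-images per side for the large-gap rule (25 tiles) |
| `gap_fraction_threshold` (τ) | 0.75 | sky fraction at which a tile is a large gap (inclusive ≥) |
| `k` | 0.7 | extinction coefficient, dimensionless, in (0, 1] |
| `phi_floor` | 1e−4 | porosity floor at the Beer's-law singularity Φ → 0 |
| `Io` | 12 | maximum open-sky luminance (image-metadata units) |
| `K_MIN` | 0.05 | lower clamp for proxy k (Beer's law divides by k) |

Tiling uses boundaries at `floor(i·dim/grid_n + 1/2)` computed in exact
integer arithmetic, so non-divisible image dimensions are covered by
near-equal rectangles, every pixel exactly once, and the vectorized counter
and the brute-force oracle can never disagree about the tiling itself.
`lg` sums *sky pixels inside* qualifying tiles (not tile areas), which
guarantees `lg ≤ tg` and keeps `f_f ≤ f_c` and `Φ ∈ [0, 1]` downstream.

Segmentation thresholds the blue channel (sky is *strictly greater than*
the threshold; the strict comparison plus the recorded threshold make masks
bit-reproducible). The automatic threshold is Otsu's between-class-variance
criterion, with Ridler–Calvard isodata as a config alternative; both are
standard histogram bimodality splitters. A constant blue channel has no
histogram split and raises a degenerate-image error pointing at the manual
override — the same remedy a field operator uses when over-illumination
defeats the automatic threshold.

Scene luminance is read from the EXIF `BrightnessValue` (APEX) tag, the
standard scene-brightness field on phone/tablet cameras; the tag name is
configurable because devices vary. Missing metadata is represented as
absent, never as 0 (0 is a legal luminance). The EXIF orientation tag is
applied before analysis.

## k-estimation strategies

- **fixed** — the literature constant (configurable, validated in (0, 1]).
- **inverted** — `k_r = −f_c ln(Φ) / LAI_r` per image, given a reference
  LAI. Porosity is floored identically to the forward model so
  invert-then-forward round-trips to machine precision.
- **lowess** — LOWESS of `k_r` on a single cover predictor, crown porosity
  Φ by default (crown cover `f_c` optional). The smoothing window is 5 % of
  the *sample count* (min. 3 points); prediction interpolates the smoothed
  curve and holds the curve ends outside the calibrated range.
- **biggap** — OLS of `k_r` on the normalized large-gap fraction `lg/tp`.
  Normalizing by `tp` makes the fit invariant to image resolution, which
  raw pixel counts are not.
- **luminance** — `I/Io` by default; a `complement` switch gives
  `1 − I/Io`, the convention used for discontinuous orchard canopies where
  below-canopy radiation is referenced to above-canopy radiation.

All proxy outputs are clamped into `[0.05, 1]` and flagged when clamping
fires.

## Degenerate inputs and numerical choices

- `f_c = 0` (open sky, no crowns): porosity is 1 by convention
  (`empty_crown` flag); LAI and LAI_e are 0.
- `Φ ≤ phi_floor` (closed canopy or all gaps large): LAI is evaluated at
  the floor and flagged `porosity_floored` rather than diverging.
- `Ω(0)` at the bounds `f_f ∈ {0, 1}` or `Φ ∈ {0, 1}` is 1 by convention
  (`omega_degenerate`); raw values > 1 (numerically possible) are clamped
  to 1 for LAI_e but retained as `omega0_raw`.
- All metric arithmetic is double precision and never rounded internally;
  the CSV export rounds metrics to 4 decimals (counts stay integral).
- The baseline subtraction (`LAI_e − baseline`) is floored at 0.

The footprint helper returns `2 d tan(fov/2)` — 63.0 cm of cordon at 80 cm
distance with the 43° field of view of the validated tablet camera. Field
practice tables round these lengths inconsistently (e.g. 64 cm printed for
80 cm distance); the helper implements the formula and leaves rounding to
the caller. Capture-distance guidance (70–80 cm optimal, never below
50 cm) is advisory only: an image does not carry its capture distance, so
the CLI can warn but not enforce.

## Synthetic canopies: what they emulate, what they do not

The generator produces two-class scenes with class-conditional Gaussian
channel statistics clipped to [0, 255]; blue means 40 (canopy) / 220 (sky)
with sd 10 are separated by ~9σ, emulating well-exposed photographs with
the sun out of frame. Three gap structures:

- **Bernoulli** fields — randomly dispersed foliage (Ω ≈ 1);
- **blocky** scenes — fully-sky rectangles over a Bernoulli background,
  i.e. clumped canopies with genuine between-crown gaps;
- **defoliation series** — strictly decreasing retention fractions of an
  initial canopy (default gaps at `sky_prob` = 0.2 model the within-crown
  holes present even at full canopy; the series default `[1.0, 0.7, 0.49,
  0.343]` emulates ~30 % removal per stripping step down to a bare-cordon
  analogue). Each image's true LAI is assigned by applying Beer's law to
  its own exact gap counts with the chosen true k, so inversion recovers
  that k to machine precision — the analytic analogue of planimetric
  ground truth.

Not simulated: sun-in-frame and over-illuminated leaves (the documented
failure modes of the field method), mixed vegetation colours, JPEG
compression artefacts, and optics (vignetting, lens distortion). Passing
tests therefore demonstrate the correctness of the *computation engine* —
segmentation on separable histograms, exact gap accounting, the metric
algebra and the k strategies — not the robustness of blue-channel
thresholding on adverse field imagery.

## Problem sizes

The test suite and acceptance script use 100×100–200×200 synthetic scenes,
1000 masks for the oracle-equivalence fuzz, 300 canopies for the sampling
bound, and 100 images for the variable-k strategy comparison; these sizes
give stable statistics (the binomial 3σ bound is size-aware) while keeping
the whole suite in a few seconds.

## Known limitations

- Per-pixel agreement with any particular field app cannot be a contract:
  published implementations differ in their filtering, and none specifies
  its exact threshold algorithm. The engine instead fixes and documents
  its own conventions (Otsu, strict `>`, inclusive τ, half-up tile
  boundaries) so results are reproducible bit-for-bit.
- The LOWESS and big-gap proxy models are only as good as their
  calibration range; predictions outside it are held at the curve ends or
  clamped.
- CieLab-space segmentation and leaf/bunch separation are out of scope.
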