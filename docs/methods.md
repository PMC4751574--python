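# Methods

## The measurement

A single fovea-centred EDI-OCT B-scan is reduced to six numbers per eye.
The grayscale image (intensities normalized to [0, 1] at load time, row 0
at the top, depth increasing downward) is binarized into dark and light
pixels; dark pixels are read as vessel lumen, light as stroma. The choroid
is the band between two annotated boundary polylines — Bruch's membrane
above, the choroid–scleral interface below, stored as fractional row depths
per integer column plus a fovea column. A window of fixed physical width
(default 1.5 mm; the choroidal blood supply is segmental, so a short
fovea-centred segment is taken as representative of the macula) is cut from
that band and closed into a simple polygon. Within it:

* **TCA** — count of pixel centers inside the polygon × pixel area (mm²);
* **LA** — count of *dark* pixel centers inside the polygon × pixel area;
* **SA** = TCA − LA; **CVI** = 100·LA/TCA; **LA/SA** (undefined marker when
  SA = 0, never infinity);
* **SFCT** — (lower − upper) at the fovea column × axial pitch (µm).

TCA deliberately uses the same pixel-center lattice as LA rather than the
continuous shoelace area, so LA ⊆ TCA and SA + LA = TCA hold *exactly*,
the way they do for pixel-count areas read off a binarized raster. The
continuous shoelace area (via the polygon geometry library) is exposed
separately (`ROIPolygon.area_px2`, `polygon_area_mm2`) for reporting.
Membership of a pixel center on the polygon edge follows the even-odd rule.

The image is binarized **before** the region is selected. The alternative
order (select, then binarize) makes boundary placement depend on a raw
image in which the choroid–scleral interface is hard to see; binarizing
first sharpens the interface. Each scan gets its own threshold; no
brightness adjustment and no pre-selection of large vessels is performed.

## Thresholding

Niblack's auto-local rule is the default: pixel (r, c) is dark iff

    I(r,c) < µ_w(r,c) + k · σ_w(r,c)

with mean and population SD over the square window of side
2·radius + 1 centred on the pixel, reflect padding (edge pixel not
duplicated) at borders. Defaults: **radius 15 px, k = −0.2** (dark-object
convention: the threshold sits below the local mean). These are
config-exposed and echoed in every output row, because the literature does
not standardize them. Otsu's global threshold (256-bin between-class
variance maximization, via scikit-image) and Bernsen's midrange rule
(threshold = (local min + local max)/2, with pixels in windows of contrast
below a floor assigned a fixed label) are provided for method comparison.

Numerical tie handling: the dark test is strict `<` with ties light. Since
different windowed-mean algorithms round differently, the comparison is
guarded as `I < T − 1e-9`: a pixel exactly at the threshold in exact
arithmetic classifies light no matter how the mean was accumulated. 1e-9
is ~4 orders above the accumulation error of windowed sums on [0, 1] data
and far below any real contrast, so the guard never touches genuinely dark
pixels.

Degenerate inputs: a constant image has no Otsu threshold (error); windows
larger than the image are rejected with a shape error (no silent shrink);
non-finite intensities are rejected at `BScan` construction.

## Physical scales

Areas need µm-per-pixel in both axes. The axial pitch must come from the
device. The lateral pitch may be derived from a known scan length (e.g. an
8.9 mm raster line divided by the image width) when no explicit value is
given. All µm↔mm conversions happen at the edge; internally everything is
pixels. Doubling both pitches multiplies areas by 4 and leaves CVI and
LA/SA unchanged; SFCT scales with the axial pitch only — these
equivariances are tested on every release.

## Reliability and cohort statistics

* **ICC**: two-way random-effects, absolute-agreement, single-measurement
  form (McGraw–Wong A,1), computed from the three two-way ANOVA mean
  squares, with the F-based confidence interval (Satterthwaite df). The
  absolute-agreement form is the right one for grader studies: adding a
  constant to one grader's column lowers the ICC even though the Pearson
  correlation stays 1. Perfect agreement (zero rater and residual mean
  squares) short-circuits to ICC = 1 with a degenerate CI.
* **Bland–Altman**: differences are first-argument-minus-second; limits of
  agreement are mean ± 1.96 × SD (n−1 SD).
* **COV** = 100·SD/mean — the unit-free way to compare the variability of
  CVI (percent scale) with SFCT (µm scale).
* **Derived covariates**: MAP = DBP + (SBP−DBP)/3; mean OPP = ⅔·MAP − IOP;
  SE = sphere + cylinder/2; BMI = kg/m². Repeated blood-pressure readings
  resolve to the mean of the two closest (systolic gap, then diastolic
  gap, then earliest pair).
* **Screening**: exclusion filters run in a fixed order (visual acuity
  logMAR > 0.30, SE < −6 D, glaucoma/prior surgery, vitreo-retinal
  disease, OCT quality < 18 dB); each subject is tallied under the first
  criterion failed, so the tally sums exactly to the number excluded.
* **Association workflow**: every candidate gets a univariate OLS fit;
  those with two-sided p < 0.10 enter a single multivariable OLS with
  intercept. Standardized β = slope × SD(x)/SD(y). Binary covariates are
  coded 0/1 (female = 1, smoker = 1, drinker = 1). Rank-deficient designs
  raise and name the collinear columns. Statsmodels performs the fits; the
  workflow, selection rule and coefficient standardization live here.

## Synthetic phantoms

Phantoms exist because no public image set accompanies this protocol; all
pipeline validation is against their exact ground truth.

Geometry: two smooth boundary curves (sums of low-frequency sinusoids with
random phases) bound a choroid band (defaults: 384×768 px at 11.6 µm
lateral / 3.87 µm axial — an 8.9 mm line scan — mean thickness 90 px ≈
350 µm, amplitude 10 px). Vessel lumens are ellipses in three depth bands
mirroring choroidal anatomy, inner to outer: choriocapillaris (depth
fraction 0–0.10, lumen radius 5–12 µm), Sattler's layer (0.10–0.50,
18–42 µm), Haller's layer (0.50–1.00, 48–80 µm). Radii are physical; the
anisotropic pixel pitch makes an isotropic lumen ~3× taller than wide in
pixel units, and an extra lateral elongation factor (1.5–3×) models vessels
sectioned obliquely along their course. Two features keep the tissue
texture realistic rather than Poisson-random: lateral positions are
stratified (one vessel per equal-width jittered slot — vascular density in
real tissue is homeostatically tight, not clumped), and every lumen
carries a 5 µm stromal wall that blocks later lumens, so adjacent vessels
stay separated by bright septa instead of merging into featureless dark
blobs. Band counts (240–300, 200–260, 65–85) were calibrated against the
ground-truth masks alone so that the default luminal fraction lands at the
healthy-eye condition, ~65% with ~2.5 pp spread across seeds.

Intensity: stroma 0.65, lumen 0.18 (pre-noise contrast 0.47), retina 0.55,
sclera 0.70; exponential depth attenuation below Bruch's membrane
(0.002/px); multiplicative unit-mean Gamma speckle (SD 0.05), then clipped
to [0, 1]. The ground-truth lumen mask is recorded *before* noise and
confined to the band. Everything is driven by one seed; identical spec +
seed gives bitwise-identical scans.

What the phantom does *not* model: OCT light propagation (no coherent
speckle statistics, no shadowing under large vessels, no RPE
hyper-reflectivity or projection artifacts), melanin-dependent contrast
variation between eyes, segmentation error in the boundary traces, or
motion artifacts. Passing the 3-percentage-point recovery check therefore
demonstrates that the binarization-and-measurement chain is unbiased on
speckled two-class tissue at realistic geometry — not that any specific
clinical accuracy holds on patient scans.

Synthetic cohorts draw covariates independently from normal/Bernoulli
marginals parameterized to a healthy elderly population (age 61.5 ± 8.8 y,
55% female, axial length 23.6 ± 1.0 mm, …). The marginals are literal
normals — no truncation — so sample means are unbiased; rare implausible
tail values are accepted as the price. Outcomes (SFCT, CVI) are linear
models with user-chosen coefficients plus Gaussian noise, giving known
truth for parameter-recovery tests; covariate independence means the
fitted CIs should show nominal coverage, and do (~95% across 100
replicates of n = 345).

## Problem sizes and tolerances

Default validation sizes: 50 random 16×16 images for bitwise
threshold-oracle equivalence; 20 phantoms (384×768) for CVI recovery with
a ±3 pp tolerance — an engineering bound chosen against the ~2.3 pp
between-eye SD of CVI in healthy cohorts, i.e. recovery error stays within
natural biological spread; 35 rater pairs for reliability statistics
(matching a typical 10% regrading subsample); 100 cohorts of n = 345 for
CI coverage with a ≥ 90% pass bound on nominal-95% intervals. Monte-Carlo
polygon-area checks use 10⁶ points at a fixed seed (0.5% relative
tolerance, ~5× its sampling SD).

## Known limitations

* Boundary annotation is an input; there is no layer segmentation, and
  annotation error propagates directly into TCA and SFCT.
* Niblack with a 15 px radius under-segments the interior of homogeneous
  regions much larger than its window; at anatomical vessel calibre this
  bias is negligible (see recovery numbers), but pathologically dilated
  vessels (e.g. pachychoroid) would need a larger window or different k.
* CVI is reported for one B-scan per eye; no volumetric averaging.
* The regression module fits ordinary least squares only — no mixed
  models, no eye-level clustering (use one eye per subject).
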