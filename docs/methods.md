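# Methods

This note documents the models, parameters and design choices behind
`dxaspine`, and what the synthetic experiments do and do not demonstrate.

## Pipeline model

The screener assumes a supine whole-body projection image with the head at
row 0, a roughly vertical body axis, and a spine that is brighter than the
surrounding soft tissue. Under those assumptions the stages are:

**Standardisation.** All images are isotropically rescaled to a common
height (`target_height_px`, default 512) with bilinear interpolation, so
pixel-unit parameters downstream have a fixed meaning. Width follows from
rounding; no padding is applied.

**Segmentation.** The silhouette is binarised by Otsu's threshold and the
largest connected component is taken as the body. The row-wise width
profile then drives the partition: the *neck* is the width minimum in the
top 30% of the body and separates the head; the *crotch* is the first row
past mid-body where the silhouette splits into two runs of leg-like width
and stays split (the persistence requirement guards against interpolation
slivers at tilted pelvis corners); the *pelvis* is the widest band between
the lower torso and the crotch; the two components below the crotch are the
*legs*, ordered by centroid column. The *spine* is the medial
high-intensity ridge: the search is seeded at the row of strongest medial
contrast within the central third of the torso, then the per-row intensity
argmax is tracked up and down within a window of
`ridge_track_halfwidth_px` (default 6 px at standard height) around the
previous row's ridge. Pure windowed search in the central third was
rejected because large curves (≳ 25°) leave it; tracking follows the ridge
wherever it goes while still being a simple, explicit rule. Tracking stops
when the ridge-to-median contrast falls below `ridge_stop_fraction`
(default 0.35) of the seed row's contrast. Per tracked row, spine pixels
are those within `spine_band_halfwidth_px` (default 5 px) of the ridge
whose intensity exceeds the midpoint between the ridge and the row median.
Torso soft tissue belonging to none of the five structures keeps the
background label (arms are deliberately not modelled). Failures raise an
error naming the violated expectation (head, legs, pelvis, spine).

**Mid-spine map.** For each row with spine pixels, the likelihood is a
Gaussian bump (`midspine_sigma_px`, default 3 px at standard height)
centred on the intensity-weighted centroid column of the row's spine
window, with the window minimum subtracted from the weights so the
soft-tissue baseline does not drag the centroid toward the integer ridge.
Rows are normalised to peak 1; the map is zero outside a dilation of the
spine mask.

**Midline and curvature.** The midline column per row is the centre of
mass of the row's likelihood, smoothed by a cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`, penalty
`midline_smoothing_lam`). The curvature statistic is the *tangent-angle
range*: θ(r) = arctan(c′(r)) evaluated on a dense row grid from the spline
derivative, with `tangent_trim_fraction` (default 2%) trimmed at each end
where spline derivatives are least reliable; the angle is max θ − min θ in
degrees. This is a supine Cobb analogue: it equals the angle between the
two most-tilted tangents of the midline, and is invariant to left-right
mirroring and (exactly, since a rigid rotation shifts every tangent
equally) insensitive to whole-body tilt. `n_curves` is one plus the number
of sign changes of the centred tangent profile outside a 2% dead band;
apexes are prominence-filtered local maxima of the deviation from the
endpoint chord.

**Grading and scores.** Grades follow the three-class scheme for supine
scans: none < 6°, mild 6–10° (10.0° inclusive), major > 10°. The
suspiciousness score is logistic in the measured angle,
`1/(1+exp(−k(angle−m)))` with midpoint `m = 6°` (the lower scoliosis
boundary scores exactly 0.5) and steepness `k = 1.5/°`; it is strictly
increasing, and maps the commonly examined extreme cut-offs to sensible
angles (0.95 ↔ ~8.0°, 0.999 ↔ ~10.6°, 0.9995 ↔ ~11.1°). A softmax-style
class-probability score from a learned classifier would fill the same
contract; only the range and monotone meaning are relied on. The binary
call is strict: positive iff score > cutoff (default 0.999). The
positioning-error score is the maximum of three normalised components
measured on the segmentation — principal-axis tilt / 10°, lateral centroid
offset / 15% of width, leg-length asymmetry / 0.2 — clipped to [0, 1];
scans scoring > 0.5 are excluded before any diagnostic statistic. The
normalisers are conventions of this package (the exclusion rule itself
fixes only the 0.5 threshold) and live in config.

## Diagnostics

The population projection rounds the diseased stratum and the true
negatives half-up (`floor(x+0.5)`) and derives complements by subtraction,
so the projected table sums exactly to N and inverts to its input
sensitivity/specificity within count-rounding error. Half-up rounding
avoids the binary-representation surprises of round-half-even on values
like `n·prevalence` that are exact in decimal. AUC is the Mann–Whitney
statistic (ties ½) via `sklearn.metrics.roc_auc_score`, with a stratified
bootstrap percentile CI (2000 resamples, seeded); tests verify it against
an exhaustive pairwise oracle. Cohen's kappa uses marginal-product expected
agreement and the classical large-sample standard error
`sqrt(p_o(1−p_o)/(n(1−p_e)²))` with a normal interval clipped to [−1, 1];
when both raters are constant and identical, kappa is undefined (NaN) and
percent agreement is still returned. χ² is Pearson's without continuity
correction by default (flag available); the t test is Welch's by default
(pooled optional).

## Phantom generator

The generator emulates exactly what the pipeline consumes: a five-part
supine silhouette (head ellipse, tapering torso, widest-band pelvis, two
leg capsules) with a bright spine band of Gaussian cross-section (σ = 3 px
at 800-row height) along an analytic midline; Poisson counting noise
(2000 counts per unit intensity) plus additive Gaussian noise
(`noise_sigma`, default 0.02 on a [0, 1] intensity scale); and pose
perturbations — whole-body rotation, lateral shift, leg shortening —
applied as one rigid transform to image, truth masks and truth midline
alike.

The midline family is a piecewise-cosine bump (single C, apex position
configurable) or two opposite-signed bumps (double S). These have zero end
slope, so the tangent-angle extrema are interior — a half-sine or plain
sinusoid would put them exactly at the spine endpoints, where any extractor
is weakest, making ground truth fragile for no physiological gain. The
amplitude is solved by bisection from the closed-form slope extrema so the
injected tangent-range angle is exact to < 0.1°.

Cohort simulation draws scoliosis status as Bernoulli(prevalence, default
5.9%) and class-conditional uniform angles: none 0–4°, mild 6–10°, major
11–28° (half of scoliotic cases mild, 30% of scoliotic curves double-S,
reflecting the frequency of double curves on supine imaging). The gaps
around the 6° boundary and above 10° make the simulated cohort a
screening-population emulation, not a boundary stress test. Repeat pairs
re-sample tilt (SD 2°), offset (SD 4 px) and asymmetry (SD 0.02) around the
first scan's pose with fresh noise. A phantom parameter counts as a *true*
positioning error when it exceeds half its score normaliser (tilt > 5°,
offset > 7.5% of width, asymmetry > 0.1), i.e. exactly when the ideal
measured score crosses the 0.5 exclusion threshold.

What the phantoms do **not** emulate: bone-density physics, soft-tissue
composition, ribs, arms, vertebral anatomy, scanner artefacts, or
anatomical variation beyond the pose parameters. Passing phantom tests
therefore demonstrates that the pipeline's geometry and statistics are
correct and self-consistent — not that the segmentation heuristics would
survive real patient images, where the learned-model ancestry of this
design exists for a reason.

## Numerical choices

- Smoothing penalty `midline_smoothing_lam = 1000`, chosen by a pilot sweep
  on phantom ladders: noiseless bias ≤ 0.06°, bias under default noise
  ≤ 0.8°; smaller penalties let centroid noise inflate the tangent range
  (the range statistic has a positive noise bias), larger ones flatten
  genuine curvature (−1.4° at 30° for λ = 10⁴).
- End trim 2% of the midline per side before taking the tangent range;
  harmless for interior-extremum midlines, ≤ 0.05° low for end-extremum
  curves like a half-sine.
- Strict inequalities for both decision rules (call iff score > cutoff,
  exclude iff positioning > 0.5); equality is a negative/kept scan.
- Degenerate inputs raise typed errors rather than returning NaN: empty
  confusion margins, single-class ROC truth, zero-variance t test, and the
  constant-raters kappa (which alone returns NaN plus percent agreement,
  since the agreement remains meaningful).
- Determinism: every stochastic component (noise, cohort draws, bootstrap)
  is driven by an explicit integer seed; identical seeds give bit-identical
  images and byte-identical batch reports.

## Problem sizes

The shipped experiments use phantoms of 800×300 px (an arbitrary
convention — scanner pixel dimensions vary), recovery ladders over
{0, 4, 8, 12, 20, 30}°, screening cohorts of 150–200 phantoms at 5.9%
prevalence, and 200 repeat pairs for reliability; these sizes give stable
statistics (binomial/kappa noise well inside the asserted bands) at
interactive runtimes.

## Known limitations

- The segmentation heuristics are tuned to the phantom's silhouette
  grammar; real scans with arms along the body, implants, or missing limbs
  will trip the anatomy checks (by design they fail loudly).
- The tangent-range angle underestimates the standing-radiograph Cobb angle
  (supine positioning alone flattens curves by roughly 10°); grades here
  are supine-scale, not clinical Cobb grades.
- The suspiciousness calibration is a stand-in with the contract's shape;
  absolute cut-off values are only meaningful relative to this calibration.
- Kappa's large-sample CI is anti-conservative for very sparse positive
  calls; with ~6 positive pairs in 200 the point estimate is the quantity
  to read, and the repeat-pair experiment asserts only the conventional
  "almost perfect" band.
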