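# Methods

## Pipeline model

The package treats one 2-D slice as the unit of analysis. Processing is a
fixed composition of elementary, individually testable operations:

    stored values --rescale--> intensities --window/level--> 8-bit display
    display --per-compartment band--> threshold masks
    rough polygon --rasterize--> rough mask
    final mask = rough mask AND threshold mask
    label map  = merge(final M, S, V)   with priority M > S > V
    areas      = pixel counts x (row_spacing x col_spacing)   [mm^2]
    ratios     = MA/SA, MA/VA, MA/(SA+VA)

Assumptions: a single-frame, monochrome DICOM with valid `PixelSpacing`;
T1-like contrast after loading (fat bright, muscle intermediate,
background dark — MONOCHROME1 sources are inverted on load to enforce
this); rough ROIs that generously cover their compartment, since the
threshold intersection can only *shrink* a region, never grow it. The
thresholds operate on the windowed 8-bit image, not raw intensities,
reproducing the viewer-style order bit-conversion → window/level →
threshold; threshold bounds are inclusive at both ends.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| window `W` | display units | 255 | identity map for 8-bit phantom data |
| level `L` | display units | 127.5 | centre of the 8-bit range |
| muscle band | 8-bit | [50, 149] | brackets the phantom muscle mean (100) |
| fat band | 8-bit | [150, 255] | brackets the phantom fat mean (200) |
| pixel spacing | mm | 0.74 × 0.74 | typical high-resolution T1 abdominal protocol |
| overlay colors | RGB | M red, S yellow, V blue | convention only, configurable |
| min component size | px | 0 (off) | the core workflow applies no morphology |

There are **no** universally correct window/level/threshold values: they
depend on scanner, sequence and vendor display pipeline, and must be set
per protocol on real data. The defaults are calibrated to the phantom's
intensity model and documented as such.

Rounding in printed summaries is decimal half-up at 1 decimal (areas and
ratios), implemented over the shortest decimal representation with an
8-digit guard so ties behave as written; CSVs carry areas at 1 decimal and
ratios at 6 decimals. An undefined ratio (zero denominator) is an explicit
missing value with a reason, never 0 or infinity.

## Rasterization contract

A pixel (i, j) belongs to a polygon iff its center (j + 0.5, i + 0.5) is
inside under the even-odd rule. Centers exactly on an edge follow the
half-open convention of the crossing test (lower/left edges count as
inside), which makes rasterization deterministic and lets a brute-force
per-pixel oracle reproduce it exactly — the property the test suite
checks on random simple polygons. Self-intersecting polygons are rejected
(validity via shapely). Polygon vertices are continuous (x, y) = (col,
row) coordinates, 0-based.

## Label-map merge

Overlaps between final compartment masks are resolved by fixed priority
M > S > V with a warning carrying the overlap pixel count. Muscle is the
diagnostic target and silent double-counting would corrupt every ratio
index; the warning keeps the conflict visible instead of hiding it.

## Statistics

*t-test.* Student's pooled-variance independent two-sample t-test,
two-sided, df = nA + nB − 2 (the conventional reading of "independent
two-sample t-test"; Welch's variant is available behind a flag). Zero
pooled variance and groups below 2 subjects are errors, not NaNs.

*ICC.* ICC(2,1): two-way random effects, absolute agreement, single
rater, computed from the two-way ANOVA mean squares

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + k (MSC − MSE)/n)

with the F-based 95% CI using a Satterthwaite approximation for the
denominator degrees of freedom, and significance from F = MSR/MSE on
(n−1, (n−1)(k−1)) df. The implementation is cross-checked against
pingouin's `intraclass_corr` in the test suite. Guards: at least 5
subjects (the CI is useless below that), no missing cells, non-constant
ratings; a tiny negative error sum of squares from cancellation under
perfect agreement is clamped to zero so identical observers give exactly
ICC = 1. Reliability bands: < 0.5 poor, [0.5, 0.75) moderate,
[0.75, 0.9] good, > 0.9 excellent — boundary values 0.5 and 0.75 go up,
0.9 stays good, matching the usual wording of the guideline.

*Summaries.* Mean ± SD with the n−1 denominator; a single observation
reports SD = 0 by convention. The overall row pools all records, so for
equal group sizes it equals the average of the group means.

## Phantom design

The synthetic slice emulates an L3-level T1-weighted abdominal image as
nested ellipses on a 512×512, 0.74 mm grid: body outline (semi-axes
200×150 px), a 28 px subcutaneous-fat annulus, a 22 px muscle ring, and
three visceral-fat ellipses in the dark central cavity. Intensity means
(fat 200, muscle 100, background 10 on the 8-bit scale) are separated by
10 noise SDs at the default Gaussian noise level (SD 5), so band
misclassification is negligible and segmentation accuracy is governed by
geometry, not noise. Everything is deterministic given (spec, seed).

Ground truth labels each pixel by center-in-region; analytic areas come
from π·a·b and annulus differences. The rough ROIs emitted with the
phantom are deliberately *dilated supersets* of their true regions —
muscle: a padded ellipse over the whole muscle disk; subcutaneous fat: a
padded "keyhole" annulus (a simple polygon cannot contain a hole, so the
two boundaries are joined through a 0.05 px-half-width radial slit placed
between pixel-center rows, which therefore excludes no centers);
visceral fat: a slightly shrunk cavity ellipse. Consequently the
confirmation step must use the threshold bands to recover the exact
compartments, which is precisely the workflow property worth testing.
On a noiseless phantom the pipeline reproduces the ground-truth label map
pixel-exactly; rasterized-vs-analytic area error is bounded by the
perimeter-to-area ratio and falls below 0.5% at the default scale
(checked to decrease monotonically across three geometry scales).

What the phantom does **not** model: anatomical shape variation, muscle
fascia and intermuscular fat, bias fields, Rician noise statistics,
partial-volume effects, or motion. Passing phantom tests therefore
demonstrates correctness of the computational pipeline — rasterization,
thresholding, bookkeeping, statistics — not clinical segmentation
accuracy on real images.

Simulated cohorts draw per-subject (MA, SA, VA) from group-specific
Gaussians truncated at 0, with defaults matching published group means
and SDs for sarcopenic-obesity and healthy-control cohorts of n = 30;
BMI and ALT are drawn by rejection sampling inside each group's defining
band, so group classification reproduces the intended labels by
construction. Rater pairs add a fixed per-rater offset plus i.i.d.
Gaussian error to a shared truth, giving a known population ICC of
σ²_subject / (σ²_subject + σ²_error) when offsets are zero.

## Numerical and design choices

- Areas are exact integer pixel counts times spacing²; no sub-pixel
  weighting. Partial-volume modelling is out of scope.
- The confirmed-ROI files are traced from the final masks by
  marching-squares contours at the 0.5 level (largest and all other
  components each written as separate polygon files); this boundary is
  approximate by nature and provided for interoperability, not as the
  source of the area numbers, which always come from the masks.
- The native ROI format is a small JSON polygon schema; ImageJ's binary
  `.roi` dialect is deliberately not parsed.
- Multiple rough ROI files with the same compartment tag are unioned
  before thresholding, which is how several disjoint visceral pockets
  are expressed.
- The scaled-down phantom used in most tests (160×160 grid, same nesting
  structure) keeps the suite fast; full-size 512×512 runs are exercised
  in the end-to-end and acceptance paths.
- Acceptance simulation sizes (200 power replicates, 1000 CI-coverage
  replicates, n = 5000 for variance-component recovery) are chosen so
  Monte-Carlo error is comfortably below the assertion tolerances.

## Known limitations

- Single-slice, single-frame DICOM only; no multi-frame or volumetric
  quantification, no skeletal-muscle-index normalization by height².
- No automatic threshold selection (e.g. Otsu) or bias-field correction;
  thresholds are protocol-level configuration.
- S/V separation quality is entirely operator-dependent through the
  rough polygons, as in the manual workflow being automated.
- The ICC confidence interval is the standard F-based approximation;
  its coverage is checked by simulation (~95% at n = 30, two raters)
  but it is not exact for small n or extreme ICC values.
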