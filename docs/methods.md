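# Methods

## Cell model and the synthetic micrograph generator

Cells are rendered as **spherocylinders** — a rectangle of size
(length − width) × width capped by two half-disks of diameter width — the
standard idealization of a rod-shaped bacterium. "Length" is end-to-end
including the caps, matching the bounding-rectangle definition used by the
measurement pipeline, so generator truth and pipeline output share one
convention. A pixel is foreground when its center lies within width/2 of the
cell's axis segment.

Lengths and widths are drawn from a **lognormal** distribution (positive
support) parameterized by mean and coefficient of variation; a normal option
exists. Defaults: mean length 40 px, cv 0.15; mean width 12 px, cv 0.05;
at the default calibration of 0.1 µm/px this is a 4 µm × 1.2 µm rod, a
typical elongated cyanobacterial cell. Orientations are uniform in
[0°, 180°) unless an `angle_range` is given (used by tests that need
axis-aligned cells).

Noise is **additive Gaussian** over a flat background after an optional
Gaussian blur (default σ = 1 px) — the simplest model sufficient for
recovery testing. SNR is defined as (cell intensity − background)/noise sd;
defaults give SNR 10, and the validation workflows use SNR 5. The generator
does **not** model a confocal point-spread function, Poisson shot noise,
uneven illumination, z-stacks, or cell clumping beyond the overlap budget;
passing tests therefore demonstrate correctness of the measurement chain on
well-separated rods, not robustness to every real-microscopy artifact.

Placement is rejection sampling with a configurable `max_overlap` fraction;
the default 0 enforces non-touching cells with a `min_gap` (4 px) clearance,
because the measurement algorithm deliberately has no declumping step —
touching cells are meant to be rejected by its shape limits, not split.
Exhausting the attempt budget raises an explicit placement error.

## Cell measurement

1. **Auto-tuning.** For each point of a (blur σ, threshold offset) grid —
   defaults σ ∈ {0, 0.5, 1, 1.5, 2, 3} px, offsets ∈ {−10…+10}% of the
   robust (1st–99th percentile) dynamic range around the isodata level of
   the smoothed image — components touching the border or below a 5 px²
   noise floor are discarded; those inside the area window are
   *candidates*, and candidates additionally passing the elongation and
   hull-ratio limits are *detected*. The grid point maximizing
   detected/candidates wins; ties prefer more detections, then less blur,
   then the offset closest to the unmodified isodata level (large offsets
   bias measured extents: at −10% offset the mean length over-reads by
   ~4.5%, at the isodata level by ~2%).
2. **Detection.** 8-connected components of the thresholded image filtered
   by area, elongation (rectangle length/width) and shape complexity
   (convex-hull area / region area, = 1 for convex shapes). The hull ratio
   and the rectangle both use the **unit-square pixel model**: each pixel
   contributes its four corners, so a noiseless axis-aligned 50-px bar
   measures exactly 50 and a filled rectangle has hull ratio exactly 1.
3. **Morphometry.** The rotated minimum-area bounding rectangle is computed
   by **rotating calipers** on the convex hull (an optimal rectangle has a
   side collinear with a hull edge); area ties break toward the smaller
   angle. Angles are degrees from the image x-axis with y pointing down, in
   [0°, 180°). Degenerate collinear components get width 0. Lengths are
   reported in px and in µm (px × pixel size).

Verified properties: the calipers rectangle matches an exhaustive
0.05°-step rotation sweep on random clouds and low-aspect rasterized rods to
0.1% relative, and is never larger than any swept box. Note the sweep's own
discretization error at an edge-aligned minimum grows like
(aspect ratio) × (half-step in radians), so for aspect ≳ 2 only the
one-sided bound is resolvable at that step — the two-sided check uses
shapes the sweep can actually certify. On synthetic fields at SNR ≥ 5,
≥ 95% of cells are detected and the mean length is recovered within 3%
(residual bias ≈ +2%: half-pixel corner convention plus threshold placement
on the blurred edge).

## Plate model and halo measurement

Synthetic plates are RGB images: a lawn (low red) over which the inhibition
halo exposes the red background (high red) as a disk of known diameter with
a logistic edge ramp of configurable softness (real halos are diffuse), a
white disk filter at the center, and optional bright specks on the lawn as
artifacts. There is no agar-diffusion PDE or optics model; halo diameter is
prescribed, not simulated.

Measurement chain: red channel → isodata threshold (polarity flag available
for inverted contrast) → **3 dilations, 73 erosions, 70 dilations** with a
3×3 square structuring element, border padded as background → moment-based
ellipse fit of the largest component (axes from normalized second central
moments, as in regionprops; a solid disk of radius r yields axes 2r) →
D = (major + minor)/2 × pixel size − disk diameter, radius r = D/2,
sensitivity S = r². Negative D clamps to 0 with a warning (no inhibition).
The disk filter diameter defaults to 6 mm (standard antibiogram disk) and
must be calibrated via the pixel size; uncalibrated images report in px².

The smoothing cycle erases any isolated object whose half-width after the
initial 3 dilations is below the 70-px net erosion depth — hence specks up
to ~30 px radius vanish — and fills gaps up to ~3 px. Although the net
cycle count is zero, the **square** element is anisotropic: its corners
reach 70√2 ≈ 99 px, so halos must be much larger than ~100 px radius to
survive undistorted (a radius-100 disk degenerates to a square; a
radius-250 disk keeps its area within 2%; above radius ~250 the diameter
bias falls below 1%). Plate defaults therefore emulate a photograph at
20 px/mm, where a 25 mm halo is 500 px and the macro's bias is negligible;
measuring small halos requires proportionally fewer erosion cycles.

The dose-series workflow generates halos with r² = slope × amount
(default slope 90 mm² per unit amount, radii ≈ 9.5–23 mm), 2% multiplicative
radius noise and 8 specks per plate; the pipeline recovers every diameter
within 2% and the S-vs-amount regression gives R² > 0.99, validating the
squared-radius sensitivity statistic.

## Statistics

- **Rank-sum test**: mid-ranks for ties; exact null by full enumeration when
  n₁+n₂ ≤ 12 and the data are tie-free, otherwise the normal approximation
  with tie correction and (default, switchable) 0.5 continuity correction.
  The two-sided exact p is the doubled smaller tail, capped at 1. Percent
  change is computed from means (matching how average-length increases are
  reported); medians are also returned since length distributions are
  skewed. Under the null at n = 186 per group the empirical type-I error at
  α = 0.05 sits within [0.04, 0.06] (2000 simulations); with a 14.4% mean
  shift at cv 0.20 the test rejects at α = 10⁻⁴ with ~99.7% power, so an
  occasional unlucky sample can exceed that threshold honestly.
- **Dose linearity**: ordinary least squares of S on amount; requires ≥ 2
  distinct amounts; noiseless linear data return R² = 1 to machine
  precision.
- **Protection ratio**: S_with/S_without, undefined (error) at
  S_without = 0; the reference points are 0 (total protection), 0.5, 1 (no
  effect) and 2 (twofold sensitization).
- **Boxplots**: linear-interpolation (type-7) quantiles; Tukey whiskers at
  the most extreme data within 1.5 IQR of the box; points beyond are
  outliers.

## Synteny

Coordinates are 1-based inclusive (GFF3/GenBank). The signed intergenic
distance is start₂ − end₁ − 1 after ordering by start, so abutting genes
have distance 0 and a 1-nt overlap gives −1; overlap length = max(0, −d).
Strand is reported but does not affect distance. Whether published
"< 167 nt" linkage thresholds use the same convention cannot be established
from coordinates alone; the convention here is documented rather than
guessed. GFF3 parsing uses gffutils, GenBank uses Biopython; gene names
match case-insensitively on gene/Name/locus_tag/ID. Surveys across many
genomes require externally supplied annotations — the package computes the
statistics, it does not download genomes.

## Problem sizes and determinism

Validation workflows use populations of 186–200 cells rendered in 512×512
fields of ≤ 50 non-touching cells (detection tuned on the first field of a
batch and reused, as under constant imaging conditions), 6-plate dose series
at 1200×1200, 2000 null simulations for test calibration, and 100-instance
oracle sweeps — sizes at which every property is measurable in seconds on a
single core. All generators take explicit seeds and are bit-reproducible;
all measurement pipelines are deterministic functions of their inputs.
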