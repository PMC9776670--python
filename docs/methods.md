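# Methods

This note documents the models, conventions and numerical choices behind
`glomopipe`, and what the synthetic test bed does and does not establish
about real slides.

## Coordinate model

All geometry lives in the WSI micron frame (origin top-left, x right,
y down); rasters attach a `PixelFrame` (μm/px calibration plus a label).
Pixel conventions are fixed once and used everywhere: 0-based indices,
half-open boxes `[x_min, x_max)`. Micron *lengths* convert to pixel counts
by round-half-up; micron *coordinates* floor at near edges and ceil at far
edges, so a pixel box never under-covers its micron box. The round trip
micron → pixel → micron is accurate to ±0.5 px by construction.
Downsampling by an integer factor k multiplies μm/px by exactly k; the
default detection scale is the base frame downsampled 8× (0.23 μm/px at
40x → ≈1.84 μm/px, a 5x working magnification).

## Sliding-window grid

Windows are `window_side = 2000 μm` squares with `overlap_fraction = 0.10`
(stride 1800 μm, 200 μm shared strips). Per axis the origins are
`0, stride, 2·stride, …`, with the final origin clamped so the last
window's far edge lands exactly on the slide edge: no window extends
beyond the slide, every point is covered at least once, and edge windows
are never padded with invented out-of-slide pixels. The 200 μm strip is
sized to contain a whole typical glomerulus (~200 μm diameter), so a
border glomerulus is seen completely by at least one window.

## Duplicate merging

The merge criterion is **intersection over the smaller box's area**, not
IoU. Rationale: the rule exists to fuse duplicate detections of one
glomerulus split across a window border, where one fragment is small — the
min-area ratio approaches 1 in exactly that situation while IoU stays low
and would under-trigger. The threshold default is 0.35; both the ratio
definition and an optional restriction of merging to pairs touching a
common inter-window overlap strip are configurable.

Merging runs to a fixpoint over connected components of the overlap graph
(a bounding-box union can create new overlaps, so components are
recomputed until none remain). This makes the result deterministic and
independent of input order — a sequential "merge the first overlapping
pair" scheme does not have a unique fixpoint, which is why the
component-closure semantics were chosen. A merged box's confidence is the
max of its constituents: a duplicate should not dilute the best evidence.

Detection F1 uses greedy one-to-one matching in descending box IoU with a
0.5 threshold (standard detection practice; configurable), and the
0/0 → 0 convention for precision, recall and F1.

## Cropping, segmentation and stitching

Detected boxes are cropped with a 20 μm margin on all sides (one tenth of
the 200 μm glomerular diameter), clipped to the slide. The margin context
is part of what the segmenter sees, and by default its predicted labels
*are* written back into the composite (`write_margin_labels=False`
restricts write-back to the unmargined box — both conventions are
defensible and supported). Stitching initializes the full-slide map to
background and writes each crop's non-background labels at its origin;
where crops overlap, non-background beats background and, among
non-background claims, the crop whose centre is nearest the pixel wins
(ties to the lower glomerulus id; `last_write`/`first_write` alternatives
provided). The nearest-centre rule was chosen for determinism — after
merging, real glomerular crops rarely overlap, so the rule is mostly
exercised by degraded detectors.

Colour normalization (optional) is a per-channel mean/SD transfer onto a
reference tile, applied before detection and segmentation; it is
deliberately minimal and swappable.

## Quantification and evaluation

Areas are pixel counts × (μm/px)². The per-glomerulus sclerotic proportion
is sclerotic / (tuft + sclerotic); with no tuft tissue at all the
proportion is undefined and excluded from slide-level means (logged).
Slide-level summary defaults to the unweighted mean over glomeruli
(`pooled_areas` offered for sensitivity analysis).

Per-class IoU is computed from a 5×5 pixel confusion matrix; a class
absent from both prediction and truth is undefined and excluded from the
mean rather than scored 1, which avoids inflating scores on lesion-free
crops (configurable). Fold aggregation reports mean and standard error
(sample SD/√k); within a fold, per-class IoU is micro-averaged (pixel
counts pooled over the fold's images) — macro-averaging is available.
Group comparisons use Welch's t-test with Welch–Satterthwaite degrees of
freedom; truth-vs-prediction totals use Pearson correlation.

## Prognosis regression

Per patient, the eGFR slope is the unweighted OLS slope over visits within
two years of biopsy (closed interval at t = 2; visits exactly at two years
count). Eligibility mirrors adult IgAN prognosis practice: ≥ 18 years at
biopsy, not end-stage at biopsy (eGFR ≥ 15 mL/min/1.73 m², plus any
explicit end-stage flag), ≥ 1 year of follow-up; exclusions are counted
per criterion.

The multivariate model regresses the slope on age, sex (male = 1),
hypertension (present = 1), eGFR at biopsy, UPCR and sclerotic proportion.
All predictors — binaries included, so each variable gets a single
comparable coefficient — are z-scored with sample SD (ddof = 1). The
outcome stays in natural units by default, so a beta reads as "eGFR-slope
change per SD of the predictor"; this is the convention under which a
noise-free synthetic cohort returns its construction coefficients exactly,
and the magnitudes match how standardized partial regression coefficients
are reported for this outcome. `standardize_outcome=True` switches to the
fully-standardized convention (under which, for orthogonal predictors,
beta equals the predictor–outcome Pearson correlation). p-values are
per-coefficient two-sided t-tests with no multiple-testing correction;
multicollinearity is screened with VIF = 1/(1 − R²ⱼ) from regressing each
predictor on the others with intercept (exact collinearity flags `inf`,
and a rank-deficient design raises an error naming the dependent columns).

## Synthetic test bed

**Phantom slides.** Glomeruli are axis-aligned ellipses: the outer ellipse
bounds Bowman's capsule interior, the ring between it and a concentric
tuft ellipse (radius ratio 0.72) is Bowman's space, and angular sectors of
tuft and ring are converted to sclerotic and crescentic tissue. Sector
angles are solved against the rasterized area directly — pixels ranked by
angle from a random start, the first `fraction·n` taken — so realized
area fractions match the targets to one pixel. Placement is rejection
sampling with boxes kept ≥ 50 μm apart (which keeps 20 μm-margin crops
disjoint, making area conservation exact); a retry cap raises a generation
error. Classes are painted with well-separated palette colours plus
optional Gaussian noise (default SD 3 intensity units), which makes the
nearest-palette-colour reference segmenter exact at zero noise and robust
at moderate noise. Defaults: 200 μm mean diameter (CV 0.1, aspect
0.8–1.25), 2 μm/px (the ~5x scale the detection stage operates at; a
base-resolution phantom of useful extent would be ~10⁹ px for no testing
benefit), 40 % of glomeruli lesion-free with the rest uniform in sclerotic
fraction 0.05–0.6. One seeded generator per call; the seed fully
determines the output.

What phantoms do **not** emulate: PAS staining appearance, tubules,
vessels and interstitium, scanner artefacts, overlapping glomeruli, or
annotation noise. Passing tests therefore establish the correctness of the
*machinery* — geometry, scanning, merging, stitching, quantification,
statistics — not the accuracy of any trained model on real histology.

**Synthetic cohorts.** Covariates span realistic adult-IgAN ranges (age
≈ 46 ± 15 y truncated to 18–85; 54 % male; 61 % hypertensive; baseline
eGFR ≈ 65 ± 24 truncated at 16; UPCR log-normal around 1.2 g/g; sclerotic
proportion Beta(1.2, 10)). The true slope is `Σ βⱼ·zⱼ + N(0, σ_slope)`
with default betas (0, 0, 0, 0, 0, −2.9) — sclerosis the only real effect
— σ_slope = 4, and eGFR visits are `egfr0 + slope·t + N(0, 3)` at nine
equally spaced times over two years (roughly quarterly labs). True slopes
are stored so recovery tests compare against construction. With nine
visits over two years, measurement noise adds ≈ 1.5 to the per-patient
slope SE, so at n = 500 the standardized sclerosis beta is recovered with
SE ≈ 0.2.

## Problem sizes and numerical conventions

The exactness battery runs on an 8 × 6 mm phantom with 12 glomeruli at
2 μm/px (12 Mpx); property sweeps use 3.2 × 2.4 mm phantoms with 4
glomeruli over 20 seeds, 500 random box sets for merge closure, 1000
random 64×64 mask pairs for IoU, and 50 cohorts of n = 500 for beta
recovery — sizes chosen so the whole battery completes in seconds while
every code path is exercised at scale. Degenerate inputs raise typed
errors rather than returning NaN silently (zero-area boxes, overlap ≥ 1,
constant predictors, < 2 usable eGFR points); undefined statistics that
are legitimately possible in normal operation (per-class IoU with the
class absent, sclerotic proportion without tuft tissue, SE of a single
fold) are NaN-flagged and excluded from aggregates.

## Known limitations

- No pyramidal-slide reader: rasters are read as PNG/TIFF with an explicit
  μm/px calibration. Pyramid handling would slot in behind `WsiRaster`.
- Rotated or polygonal detection regions are out of scope (axis-aligned
  boxes only), as are crescent/sclerosis subtypes.
- The prognosis model is plain OLS per the study design it mirrors — no
  mixed-effects slope estimation, survival modelling or treatment
  adjustment.
- The shipped detectors/segmenters are references; scientific use on real
  WSIs requires plugging in trained backends honouring the two contracts.
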