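# glomopipe

Glomerulus detection, five-class glomerular segmentation and sclerosis-based
eGFR prognosis for whole-slide kidney images.

## The problem

Grading IgA nephropathy (IgAN) from a renal biopsy means finding every
glomerulus on a gigapixel PAS-stained whole-slide image (WSI), delineating
its components, and relating the lesion burden to the patient's kidney
function. Doing this by eye is slow and inconsistent. `glomopipe` implements
the computational side of that workflow for researchers in digital
nephropathology:

1. **Detection** — the WSI is scanned row-by-row, left-to-right with
   2000 μm sliding windows overlapping by 10 % (200 μm — wide enough to
   contain a whole ~200 μm glomerulus lying on a window border), at a
   reduced detection magnification (integer downsample of the base
   0.23 μm/px frame). A pluggable per-window detector returns boxes, which
   are remapped into slide micron coordinates; duplicate boxes of one
   glomerulus seen from neighbouring windows are merged whenever their
   overlap ratio (intersection over the smaller box) reaches 35 %,
   iterated to a fixpoint.
2. **Segmentation** — each detected box is cropped with a 20 μm margin and
   classified per pixel into five classes: background, Bowman's space,
   glomerular tuft, crescentic region and sclerotic region; the labels are
   repositioned into a full-WSI label map, with everything not detected as
   glomerulus forced to background.
3. **Quantification & prognosis** — per glomerulus, the sclerotic
   proportion is `sclerotic / (tuft + sclerotic)` (the *whole glomerular
   tuft* being tuft + sclerotic regions combined; a globally sclerosed
   glomerulus with no remaining tuft scores 1). Slide-level proportion is
   the mean over glomeruli. Per patient, the eGFR slope (mL/min/1.73 m²
   per year) is the OLS slope of eGFR over time within two years of
   biopsy, and the slope is regressed on six prognostic variables — age,
   sex, hypertension, eGFR at biopsy, UPCR, sclerotic proportion — with
   every predictor z-scored, reporting standardized betas ± SE,
   per-coefficient p-values, VIF and R².

Deep-learning backends (e.g. a Faster-R-CNN-style detector, a
SegFormer-style segmenter) plug in through small I/O contracts; the package
ships deterministic reference backends (truth oracle, jittered oracle,
palette/blob classifiers) and a **synthetic generator** — phantom WSIs with
elliptical glomeruli and exact per-class ground truth, plus an IgAN-like
cohort whose eGFR slope depends on sclerotic proportion by construction —
so every stage is testable end to end without restricted clinical data.

## Worked example

```bash
glomopipe phantom  --out-dir slide --extent-um 4000x3000 --n-glomeruli 6 \
                   --noise-sd 3 --seed 11
glomopipe pipeline --wsi slide/wsi.png --detector blob --segmenter palette \
                   --out-dir out
glomopipe cohort   --out cohort.csv --n-patients 200 --seed 5
glomopipe prognosis --cohort cohort.csv --out report.json
```

The pipeline command prints

```
6 glomeruli; slide-level sclerotic proportion 0.175
```

— the blob detector found all six phantom glomeruli and the palette
segmenter's masks give a mean per-glomerulus sclerotic proportion of
0.175. `out/quantification.csv` holds the per-glomerulus class areas in
μm² and proportions, e.g.

```
wsi_id,glom_id,area_bowman,area_tuft,area_crescent,area_sclerotic,sclerotic_prop
wsi,0,14092.0,16396.0,1136.0,0.0,0.0
wsi,1,15212.0,11700.0,0.0,4700.0,0.2865853658536585
```

The prognosis command fits the standardized regression on the synthetic
cohort (whose only true effect is sclerosis at β = −2.9 per SD) and prints

```
                     beta (SE)         p  VIF
age              0.558 (0.304)    0.0682  1.0
sex             -0.241 (0.305)     0.431  1.0
hypertension     0.192 (0.307)     0.532  1.0
egfr0            0.063 (0.309)     0.837  1.0
upcr             0.303 (0.307)     0.325  1.0
sclerotic_prop  -2.919 (0.305)  5.79e-18  1.0
R² = 0.34, n = 200
```

— the sclerosis coefficient is recovered within one SE of its true value
and is the only significant predictor, with all VIFs ≈ 1 under independent
covariates.

The same operations are available as a library (`glomopipe.run_pipeline`,
`glomopipe.fit_prognosis_model`, …); the CLI is a thin wrapper.

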