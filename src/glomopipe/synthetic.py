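"""Synthetic test bed: phantom slides, augmentations and an IgAN-like cohort.

Real renal-biopsy WSIs and the matching electronic-health-record data are
facility-restricted, so the package ships a generator for each of the two
inputs the pipeline consumes:

* **Phantom WSIs** — white slides carrying elliptical glomeruli: an outer
  ellipse is Bowman's capsule interior, the ring between it and an inner
  "tuft" ellipse is Bowman's space, and angular sectors of tuft and ring are
  converted to sclerotic and crescentic tissue so that the *area fractions*
  (the only lesion property the downstream quantification uses) hit
  requested targets.  Classes are painted with well-separated palette
  colours (:data:`~glomopipe.wsi.CLASS_PALETTE`) plus optional Gaussian
  noise, which makes the nearest-colour reference segmenter exact at zero
  noise and gives every stage an analytic ground truth.
* **Synthetic cohorts** — per-patient prognostic covariates spanning
  realistic IgAN ranges, with a true eGFR slope that is a linear function of
  the z-scored covariates (units: mL/min/1.73 m² per year per SD) plus
  noise, and a timestamped eGFR series around that slope.  True slopes are
  kept so parameter-recovery tests can compare against construction.

All randomness flows from one `numpy` generator seeded per call; the seed
fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.transform import rescale

from .errors import GenerationError, InvalidParameterError
from .geometry import MicronBox, PixelFrame
from .wsi import CLASS_PALETTE, LabelMask, WsiRaster

__all__ = [
    "PhantomSpec",
    "PhantomWsi",
    "generate_phantom",
    "augment",
    "CohortSpec",
    "CohortTable",
    "generate_cohort",
    "PREDICTOR_COLUMNS",
]

FractionDist = "float | Callable[[np.random.Generator], float] | None"


def _default_sclerotic_dist(rng: np.random.Generator) -> float:
    # Most glomeruli unsclerosed; the rest segmental up to heavy involvement.
    return 0.0 if rng.random() < 0.4 else float(rng.uniform(0.05, 0.6))


def _default_crescent_dist(rng: np.random.Generator) -> float:
    return 0.0 if rng.random() < 0.6 else float(rng.uniform(0.05, 0.4))


def _draw_fraction(dist, rng: np.random.Generator, default) -> float:
    if dist is None:
        value = default(rng)
    elif callable(dist):
        value = float(dist(rng))
    else:
        value = float(dist)
    if not (0.0 <= value <= 1.0):
        raise InvalidParameterError(f"lesion fraction must lie in [0, 1], got {value}")
    return value


@dataclass
class PhantomSpec:
    """Parameters of a phantom slide.

    Defaults give a desk-scale slide: 4×3 mm at 2 μm/px (the ~5x scale the
    detection stage operates at) with 200 μm glomeruli — the textbook
    glomerular diameter and the size the pipeline's window/margin defaults
    are tuned to.
    """

    wsi_extent_um: tuple[float, float] = (4000.0, 3000.0)
    microns_per_pixel: float = 2.0
    n_glomeruli: int = 6
    glom_diameter_mean_um: float = 200.0
    glom_diameter_cv: float = 0.10
    tuft_scale: float = 0.72  # tuft ellipse radii relative to the capsule's
    sclerotic_fraction_dist: object = None  # scalar or callable(rng) -> [0, 1]
    crescent_fraction_dist: object = None
    noise_sd: float = 3.0
    min_gap_um: float = 50.0  # box-to-box clearance; keeps 20 μm margins disjoint
    seed: int = 0


@dataclass
class PhantomWsi:
    """A generated slide with its full ground truth."""

    wsi: WsiRaster
    truth_boxes: list[MicronBox]
    truth_mask: LabelMask
    per_glom_truth: pd.DataFrame  # glom_id, per-class areas (μm²), target fractions
    spec: PhantomSpec


def _carve_sector(sub: np.ndarray, region: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                  cx: float, cy: float, fraction: float, code: int,
                  rng: np.random.Generator) -> None:
    """Relabel an angular wedge of `region` pixels to `code`.

    The wedge angle is solved against the rasterized area directly: pixels
    are ranked by angle from a random start and the first ``fraction·n``
    taken, so the realized area fraction is exact to one pixel.
    """
    idx = np.nonzero(region)
    n = idx[0].size
    m = int(round(fraction * n))
    if m <= 0:
        return
    ang = np.arctan2(ys[idx[0]] - cy, xs[idx[1]] - cx)
    rel = np.mod(ang - rng.uniform(0.0, 2.0 * math.pi), 2.0 * math.pi)
    order = np.argsort(rel, kind="stable")[:m]
    sub[idx[0][order], idx[1][order]] = code


def generate_phantom(spec: PhantomSpec) -> PhantomWsi:
    """Generate a phantom WSI with truth boxes, truth mask and per-glomerulus areas.

    Glomeruli are placed by rejection sampling so their bounding boxes stay
    at least ``min_gap_um`` apart (overlapping glomeruli are out of scope);
    a retry cap turns impossible placements into a :class:`GenerationError`.
    """
    rng = np.random.default_rng(spec.seed)
    mpp = spec.microns_per_pixel
    frame = PixelFrame(mpp, "phantom")
    w_um, h_um = spec.wsi_extent_um
    width_px = int(round(w_um / mpp))
    height_px = int(round(h_um / mpp))
    mask = np.zeros((height_px, width_px), dtype=np.uint8)

    # --- placement ---------------------------------------------------------
    gloms: list[tuple[float, float, float, float, float, float]] = []
    boxes: list[MicronBox] = []
    tries, cap = 0, 400 * max(spec.n_glomeruli, 1)
    while len(gloms) < spec.n_glomeruli:
        if tries > cap:
            raise GenerationError(
                f"could not place {spec.n_glomeruli} non-overlapping glomeruli "
                f"(min_gap={spec.min_gap_um} μm) in a {w_um}×{h_um} μm slide "
                f"after {cap} tries"
            )
        tries += 1
        diam = spec.glom_diameter_mean_um * float(
            np.clip(1.0 + spec.glom_diameter_cv * rng.standard_normal(), 0.6, 1.4)
        )
        aspect = rng.uniform(0.8, 1.25)
        rx = 0.5 * diam * math.sqrt(aspect)
        ry = 0.5 * diam / math.sqrt(aspect)
        if 2 * rx + 2 > w_um or 2 * ry + 2 > h_um:
            raise GenerationError("slide extent too small for the glomerulus diameter")
        cx = rng.uniform(rx + 1.0, w_um - rx - 1.0)
        cy = rng.uniform(ry + 1.0, h_um - ry - 1.0)
        box = MicronBox(cx - rx, cy - ry, cx + rx, cy + ry)
        padded = box.expand(spec.min_gap_um / 2.0)
        if any(padded.intersection(b.expand(spec.min_gap_um / 2.0)) for b in boxes):
            continue
        frac_s = _draw_fraction(spec.sclerotic_fraction_dist, rng, _default_sclerotic_dist)
        frac_c = _draw_fraction(spec.crescent_fraction_dist, rng, _default_crescent_dist)
        gloms.append((cx, cy, rx, ry, frac_s, frac_c))
        boxes.append(box)

    # --- rasterization -----------------------------------------------------
    records = []
    for gid, ((cx, cy, rx, ry, frac_s, frac_c), box) in enumerate(zip(gloms, boxes)):
        x0, y0, x1, y1 = box.to_pixel(frame)
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, width_px), min(y1, height_px)
        xs = (np.arange(x0, x1) + 0.5) * mpp
        ys = (np.arange(y0, y1) + 0.5) * mpp
        ex = ((xs[None, :] - cx) / rx) ** 2
        ey = ((ys[:, None] - cy) / ry) ** 2
        outer = ex + ey <= 1.0
        inner = ex / spec.tuft_scale ** 2 + ey / spec.tuft_scale ** 2 <= 1.0
        sub = mask[y0:y1, x0:x1]
        sub[outer & ~inner] = 1  # Bowman's space ring
        sub[inner] = 2           # glomerular tuft
        _carve_sector(sub, sub == 2, xs, ys, cx, cy, frac_s, 4, rng)
        _carve_sector(sub, sub == 1, xs, ys, cx, cy, frac_c, 3, rng)
        counts = np.bincount(sub.ravel(), minlength=5)
        records.append(
            {
                "glom_id": gid,
                "area_bowman": counts[1] * mpp ** 2,
                "area_tuft": counts[2] * mpp ** 2,
                "area_crescent": counts[3] * mpp ** 2,
                "area_sclerotic": counts[4] * mpp ** 2,
                "target_sclerotic_fraction": frac_s,
                "target_crescent_fraction": frac_c,
            }
        )

    raster = CLASS_PALETTE[mask].astype(np.float64)
    if spec.noise_sd > 0:
        raster = raster + rng.normal(0.0, spec.noise_sd, raster.shape)
    raster = np.clip(np.rint(raster), 0, 255).astype(np.uint8)

    per_glom = pd.DataFrame.from_records(
        records,
        columns=[
            "glom_id", "area_bowman", "area_tuft", "area_crescent",
            "area_sclerotic", "target_sclerotic_fraction", "target_crescent_fraction",
        ],
    )
    return PhantomWsi(
        wsi=WsiRaster(raster, frame),
        truth_boxes=boxes,
        truth_mask=LabelMask(mask, frame),
        per_glom_truth=per_glom,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# augmentations

def _as_float(img: np.ndarray) -> tuple[np.ndarray, bool]:
    if img.dtype == np.uint8:
        return img.astype(np.float64), True
    return img.astype(np.float64, copy=True), False


def _restore(img: np.ndarray, was_uint8: bool) -> np.ndarray:
    if was_uint8:
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def augment(image: np.ndarray, ops: Sequence, seed: int | None = None) -> np.ndarray:
    """Apply an ordered list of augmentation ops; deterministic given `seed`.

    Each op is either a bare name (``"flip_h"``) or a ``(name, params)``
    pair.  Supported: ``flip_h``, ``flip_v``, ``gaussian_blur(sigma)``,
    ``sharpen(amount)``, ``contrast(factor)``, ``scale(factor)`` and
    ``crop(box)`` with a half-open pixel box ``(x0, y0, x1, y1)``.  Flips are
    exact involutions; ``scale`` and ``crop`` change the output dimensions.
    None of the shipped ops draws random numbers, so `seed` currently only
    pins the contract for future stochastic ops.
    """
    del seed  # reserved; all shipped ops are deterministic
    out = np.asarray(image)
    for op in ops:
        name, params = (op, {}) if isinstance(op, str) else (op[0], dict(op[1]))
        if name == "flip_h":
            out = out[:, ::-1].copy()
        elif name == "flip_v":
            out = out[::-1].copy()
        elif name == "gaussian_blur":
            arr, u8 = _as_float(out)
            sigma = float(params["sigma"])
            arr = ndi.gaussian_filter(arr, sigma=(sigma, sigma, 0) if arr.ndim == 3 else sigma,
                                      mode="reflect")
            out = _restore(arr, u8)
        elif name == "sharpen":
            arr, u8 = _as_float(out)
            amount = float(params.get("amount", 1.0))
            blurred = ndi.gaussian_filter(
                arr, sigma=(1.0, 1.0, 0) if arr.ndim == 3 else 1.0, mode="reflect"
            )
            out = _restore(arr + amount * (arr - blurred), u8)
        elif name == "contrast":
            arr, u8 = _as_float(out)
            mean = arr.mean()
            out = _restore(mean + float(params["factor"]) * (arr - mean), u8)
        elif name == "scale":
            arr, u8 = _as_float(out)
            factor = float(params["factor"])
            if factor <= 0:
                raise InvalidParameterError("scale factor must be positive")
            arr = rescale(arr, factor, channel_axis=-1 if arr.ndim == 3 else None,
                          anti_aliasing=factor < 1, preserve_range=True)
            out = _restore(arr, u8)
        elif name == "crop":
            x0, y0, x1, y1 = (int(v) for v in params["box"])
            h, w = out.shape[:2]
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise InvalidParameterError(
                    f"crop box {(x0, y0, x1, y1)} outside image of size {(w, h)}"
                )
            out = out[y0:y1, x0:x1].copy()
        else:
            raise InvalidParameterError(f"unknown augmentation op {name!r}")
    return out


# ---------------------------------------------------------------------------
# synthetic IgAN cohort

PREDICTOR_COLUMNS = ("age", "sex", "hypertension", "egfr0", "upcr", "sclerotic_prop")


@dataclass
class CohortSpec:
    """Synthetic cohort parameters.

    `betas` are true standardized effects on the eGFR slope, one per
    predictor in :data:`PREDICTOR_COLUMNS`, in mL/min/1.73 m²/yr per SD of
    the predictor.  The default makes sclerosis the only real effect at a
    Table-5-like magnitude; `slope_noise_sd` is patient-level slope
    variability and `egfr_measure_noise_sd` visit-level measurement noise,
    both in eGFR units.
    """

    n_patients: int = 46
    betas: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, -2.9)
    slope_noise_sd: float = 4.0
    egfr_measure_noise_sd: float = 3.0
    visits_per_patient: int = 9
    followup_years: float = 2.0
    seed: int = 0


@dataclass
class CohortTable:
    """Per-patient covariates (with stored true slopes) plus the visit-level series."""

    patients: pd.DataFrame  # patient_id, covariates, true_slope
    visits: pd.DataFrame    # patient_id, visit_time_yr, egfr
    spec: CohortSpec

    def to_long(self) -> pd.DataFrame:
        """One row per visit, covariates repeated — the cohort CSV dialect."""
        cols = ["patient_id", *PREDICTOR_COLUMNS]
        return self.visits.merge(self.patients[cols], on="patient_id")[
            [*cols, "visit_time_yr", "egfr"]
        ]

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


def _zscore(x: np.ndarray) -> np.ndarray:
    # ddof=1 to match the regression layer's standardization; constant
    # columns map to zero rather than dividing by zero.
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a synthetic IgAN cohort whose eGFR slope follows the requested betas.

    Covariate distributions span the ranges typical of adult IgAN biopsy
    cohorts (age ≈ 46 ± 15 y, eGFR at biopsy ≈ 65 ± 24, UPCR log-normal
    around 1.2 g/g, modest sclerotic proportions).  The true slope is
    ``Σ β_j·z_j + N(0, slope_noise_sd)`` and each eGFR visit is
    ``egfr0 + slope·t + N(0, egfr_measure_noise_sd)`` at equally spaced
    times in ``[0, followup_years]``.
    """
    if spec.n_patients < 2:
        raise InvalidParameterError("need at least 2 patients")
    if len(spec.betas) != len(PREDICTOR_COLUMNS):
        raise InvalidParameterError(
            f"betas must have {len(PREDICTOR_COLUMNS)} entries, got {len(spec.betas)}"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    age = np.clip(rng.normal(46.0, 15.0, n), 18.0, 85.0)
    sex = (rng.random(n) < 25.0 / 46.0).astype(float)          # male = 1
    hypertension = (rng.random(n) < 28.0 / 46.0).astype(float)  # present = 1
    egfr0 = np.clip(rng.normal(65.0, 24.0, n), 16.0, 130.0)
    upcr = np.clip(np.exp(rng.normal(math.log(1.18), 0.8, n)), 0.05, 12.0)
    sclerotic_prop = rng.beta(1.2, 10.0, n)

    covariates = np.column_stack([age, sex, hypertension, egfr0, upcr, sclerotic_prop])
    z = np.column_stack([_zscore(covariates[:, j]) for j in range(covariates.shape[1])])
    true_slope = z @ np.asarray(spec.betas, dtype=float)
    if spec.slope_noise_sd > 0:
        true_slope = true_slope + rng.normal(0.0, spec.slope_noise_sd, n)

    patients = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age": age,
            "sex": sex,
            "hypertension": hypertension,
            "egfr0": egfr0,
            "upcr": upcr,
            "sclerotic_prop": sclerotic_prop,
            "true_slope": true_slope,
        }
    )

    times = np.linspace(0.0, spec.followup_years, spec.visits_per_patient)
    egfr = egfr0[:, None] + true_slope[:, None] * times[None, :]
    if spec.egfr_measure_noise_sd > 0:
        egfr = egfr + rng.normal(0.0, spec.egfr_measure_noise_sd, egfr.shape)
    visits = pd.DataFrame(
        {
            "patient_id": np.repeat(patients["patient_id"].to_numpy(), times.size),
            "visit_time_yr": np.tile(times, n),
            "egfr": egfr.ravel(),
        }
    )
    return CohortTable(patients=patients, visits=visits, spec=spec)
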