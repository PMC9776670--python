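"""Step 2 — five-class segmentation of detected glomeruli, stitched into WSI space.

Each detected box is cropped with a 20 μm margin on all sides (one tenth of
the ~200 μm glomerular diameter, mirroring how segmentation training crops
are framed), handed to a pluggable five-class segmenter, and the predicted
labels are repositioned at the crop's origin in a full-slide label map.
Every pixel not covered by a detection stays background — the "not
glomerulus in step 1 → background" rule.

Where two crops overlap, a non-background label always beats background,
and among competing non-background labels the crop whose centre is nearer
to the pixel wins (ties to the lower glomerulus id).  Real glomeruli rarely
overlap after merging, so the rule mostly matters for jittered/degraded
detectors; `last_write` and `first_write` alternatives are provided.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .errors import ContractViolationError, InvalidInputError, InvalidParameterError
from .geometry import MicronBox, PixelFrame
from .wsi import CLASS_PALETTE, N_CLASSES, LabelMask, WsiRaster

__all__ = [
    "SegmenterContract",
    "CropResult",
    "PipelineResult",
    "crop_with_margin",
    "stitch_masks",
    "run_pipeline",
    "normalize_colors",
    "PaletteSegmenter",
    "NoisySegmenter",
    "OracleSegmenter",
]


class SegmenterContract(Protocol):
    """Per-crop segmenter interface.

    Called with the RGB crop, its pixel frame and the crop's micron box in
    the WSI (model backends may ignore the box; the truth oracle needs it).
    Must return a 2D array of class codes {0..4} with the crop's exact
    height × width.
    """

    def __call__(
        self, crop: np.ndarray, frame: PixelFrame, crop_box: MicronBox
    ) -> np.ndarray:
        ...


@dataclass
class CropResult:
    """A margin-expanded glomerulus crop and where it sits in the WSI."""

    crop: np.ndarray            # (h, w, 3) uint8
    box_um: MicronBox           # margin-expanded box, clipped to the slide
    px_box: tuple[int, int, int, int]  # half-open pixel box actually extracted


def crop_with_margin(wsi: WsiRaster, box: MicronBox, margin_um: float = 20.0) -> CropResult:
    """Crop `box` from the slide with `margin_um` added on all four sides.

    The effective box is clipped to the slide bounds; a box fully outside
    raises.  The margin context is what segmentation backends are trained
    with, so it is part of the crop they see.
    """
    if margin_um < 0:
        raise InvalidParameterError("margin must be ≥ 0")
    eff = box.expand(margin_um).clip(wsi.extent_um)
    if eff is None:
        raise InvalidInputError(f"box {box} lies entirely outside the slide")
    crop, px_box = wsi.region(eff)
    return CropResult(crop=crop, box_um=eff, px_box=px_box)


def stitch_masks(
    wsi_extent_um: tuple[float, float],
    frame: PixelFrame,
    masks: Sequence[LabelMask],
    rule: str = "nearest_center",
    restrict_boxes: Sequence[MicronBox] | None = None,
) -> LabelMask:
    """Reposition per-glomerulus masks into one full-WSI label map.

    Pixels outside every crop are background.  `restrict_boxes` (parallel to
    `masks`) limits each crop's write-back to its unmargined detection box,
    for the convention in which margin-pixel predictions are discarded.
    """
    if rule not in ("nearest_center", "last_write", "first_write"):
        raise InvalidParameterError(f"unknown stitching rule {rule!r}")
    mpp = frame.microns_per_pixel
    width = int(round(wsi_extent_um[0] / mpp))
    height = int(round(wsi_extent_um[1] / mpp))
    out = np.zeros((height, width), dtype=np.uint8)
    dist: np.ndarray | None = None
    if rule == "nearest_center":
        dist = np.full((height, width), np.inf, dtype=np.float32)

    for gid, m in enumerate(masks):
        if abs(m.frame.microns_per_pixel - mpp) > 1e-9:
            raise ContractViolationError(f"mask {gid} frame differs from the WSI frame")
        ox, oy = m.origin_px
        h, w = m.data.shape
        if ox < 0 or oy < 0 or ox + w > width or oy + h > height:
            raise ContractViolationError(
                f"mask {gid} at origin {(ox, oy)} size {(w, h)} extends beyond "
                f"the {width}×{height} px slide"
            )
        nz = m.data != 0
        if restrict_boxes is not None:
            bx0, by0, bx1, by1 = restrict_boxes[gid].to_pixel(frame)
            cols = np.arange(ox, ox + w)
            rows = np.arange(oy, oy + h)
            nz = nz & ((cols >= bx0) & (cols < bx1))[None, :] & (
                (rows >= by0) & (rows < by1)
            )[:, None]
        sub = out[oy:oy + h, ox:ox + w]
        if rule == "last_write":
            sub[nz] = m.data[nz]
            continue
        if rule == "first_write":
            write = nz & (sub == 0)
            sub[write] = m.data[write]
            continue
        cx, cy = m.origin_um[0] + w * mpp / 2.0, m.origin_um[1] + h * mpp / 2.0
        xs = (np.arange(ox, ox + w) + 0.5) * mpp
        ys = (np.arange(oy, oy + h) + 0.5) * mpp
        d2 = ((xs - cx) ** 2)[None, :] + ((ys - cy) ** 2)[:, None]
        sub_d = dist[oy:oy + h, ox:ox + w]
        write = nz & ((sub == 0) | (d2 < sub_d))
        sub[write] = m.data[write]
        sub_d[write] = d2[write].astype(np.float32)
    return LabelMask(out, frame, (0.0, 0.0))


def normalize_colors(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-channel mean/SD transfer onto a reference tile.

    A minimal stain/scanner normalization: each channel is shifted and
    scaled so its mean and SD match the reference's.  Deliberately simple
    and swappable; it is applied before detection and segmentation when a
    reference is supplied.
    """
    img = image.astype(np.float64)
    ref = reference.astype(np.float64)
    out = np.empty_like(img)
    for c in range(img.shape[-1]):
        mu, sd = img[..., c].mean(), img[..., c].std()
        rmu, rsd = ref[..., c].mean(), ref[..., c].std()
        out[..., c] = (img[..., c] - mu) / (sd if sd > 0 else 1.0) * rsd + rmu
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass
class PipelineResult:
    """Everything the two-step pipeline produces for one slide."""

    run: "DetectionRun"
    wsi_mask: LabelMask
    glom_masks: list[LabelMask]
    crop_boxes: list[MicronBox]


def run_pipeline(
    wsi: WsiRaster,
    detector,
    segmenter: SegmenterContract,
    window_side_um: float = 2000.0,
    overlap_fraction: float = 0.10,
    detection_downsample: int = 8,
    merge_threshold: float = 0.35,
    margin_um: float = 20.0,
    stitch_rule: str = "nearest_center",
    write_margin_labels: bool = True,
    color_norm_reference: np.ndarray | None = None,
) -> PipelineResult:
    """Compose the full pipeline: scan → merge → crop → segment → stitch.

    Deterministic whenever the detector and segmenter backends are.
    Stage failures propagate with stage-named context.
    """
    from .detection import merge_boxes, scan_wsi  # local import avoids a cycle

    if color_norm_reference is not None:
        wsi = WsiRaster(normalize_colors(wsi.raster, color_norm_reference), wsi.frame)

    try:
        raw, grid = scan_wsi(wsi, detector, window_side_um, overlap_fraction,
                             detection_downsample)
    except Exception as exc:
        raise type(exc)(f"[detection stage] {exc}") from exc
    run = merge_boxes(raw, merge_threshold)

    glom_masks: list[LabelMask] = []
    crop_boxes: list[MicronBox] = []
    for gid, det in enumerate(run.merged):
        cr = crop_with_margin(wsi, det.box, margin_um)
        try:
            labels = np.asarray(segmenter(cr.crop, wsi.frame, cr.box_um))
        except Exception as exc:
            raise type(exc)(f"[segmentation stage, glomerulus {gid}] {exc}") from exc
        if labels.shape != cr.crop.shape[:2]:
            raise ContractViolationError(
                f"[segmentation stage, glomerulus {gid}] segmenter returned shape "
                f"{labels.shape}, expected {cr.crop.shape[:2]}"
            )
        x0, y0, _, _ = cr.px_box
        mpp = wsi.frame.microns_per_pixel
        glom_masks.append(
            LabelMask(labels.astype(np.uint8), wsi.frame, (x0 * mpp, y0 * mpp))
        )
        crop_boxes.append(cr.box_um)

    wsi_mask = stitch_masks(
        wsi.extent_um,
        wsi.frame,
        glom_masks,
        rule=stitch_rule,
        restrict_boxes=None if write_margin_labels else [d.box for d in run.merged],
    )
    return PipelineResult(run=run, wsi_mask=wsi_mask, glom_masks=glom_masks,
                          crop_boxes=crop_boxes)


# ---------------------------------------------------------------------------
# reference segmenter backends


class PaletteSegmenter:
    """Nearest-palette-colour classifier — exact on zero-noise phantoms.

    Assigns each pixel to the class whose palette centroid is nearest in
    RGB; the phantom palette keeps centroids far apart, so moderate Gaussian
    noise still classifies correctly.
    """

    def __call__(self, crop, frame, crop_box):
        arr = crop.astype(np.float64)
        d2 = ((arr[..., None, :] - CLASS_PALETTE[None, None, :, :].astype(np.float64)) ** 2
              ).sum(axis=-1)
        return d2.argmin(axis=-1).astype(np.uint8)


class NoisySegmenter:
    """Palette segmenter degraded by a seeded per-pixel label-flip rate.

    The flip pattern is derived from the seed *and* the crop bytes, so a
    given crop always degrades the same way (deterministic contract) while
    different crops get independent noise.
    """

    def __init__(self, flip_rate: float = 0.05, seed: int = 0):
        if not (0.0 <= flip_rate <= 1.0):
            raise InvalidParameterError("flip_rate must be in [0, 1]")
        self.flip_rate = flip_rate
        self.seed = seed
        self._base = PaletteSegmenter()

    def __call__(self, crop, frame, crop_box):
        labels = self._base(crop, frame, crop_box)
        rng = np.random.default_rng(
            [self.seed, zlib.crc32(np.ascontiguousarray(crop).tobytes())]
        )
        flip = rng.random(labels.shape) < self.flip_rate
        offset = rng.integers(1, N_CLASSES, size=labels.shape)
        labels = np.where(flip, (labels + offset) % N_CLASSES, labels)
        return labels.astype(np.uint8)


class OracleSegmenter:
    """Reads the ground-truth mask at the crop's location (round-trip backend)."""

    def __init__(self, truth_mask: LabelMask):
        self.truth_mask = truth_mask

    def __call__(self, crop, frame, crop_box):
        x0, y0, x1, y1 = crop_box.to_pixel(self.truth_mask.frame)
        h, w = self.truth_mask.data.shape
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        labels = self.truth_mask.data[y0:y1, x0:x1]
        if labels.shape != crop.shape[:2]:
            raise ContractViolationError(
                f"oracle crop shape {labels.shape} != crop {crop.shape[:2]}"
            )
        return labels.copy()
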