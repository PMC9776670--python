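"""Coordinate frames, sliding-window grids and axis-aligned box algebra.

Everything in the pipeline lives in one of two frames:

* the **WSI micron frame** — origin at the slide's top-left corner, x to the
  right, y downward, units of micrometres; detection boxes, window origins
  and quantified areas are expressed here so that results are independent of
  scan resolution;
* a **pixel frame** — a raster sampled at some μm/px calibration
  (:class:`PixelFrame`), e.g. 0.23 μm/px for a 40x scan or 8x that after
  downsampling to the 5x detection magnification.

Pixel conventions, used consistently package-wide: 0-based indices, half-open
boxes ``[x_min, x_max)``, origin top-left.  Micron lengths convert to pixel
counts by round-half-up; micron *coordinates* convert with floor for near
edges and ceil for far edges, so a pixel box never under-covers its micron
box.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import CalibrationError, InvalidParameterError

__all__ = [
    "PixelFrame",
    "MicronBox",
    "WindowGrid",
    "micron_to_pixel",
    "pixel_to_micron",
    "build_window_grid",
    "box_overlap_ratio",
    "box_iou",
    "read_boxes_csv",
    "write_boxes_csv",
    "boxes_to_coco",
    "coco_to_boxes",
]


@dataclass(frozen=True)
class PixelFrame:
    """Calibration of a raster: micrometres per pixel plus a free-text label."""

    microns_per_pixel: float
    magnification_label: str = ""

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0):
            raise CalibrationError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel!r}"
            )

    def downsampled(self, factor: int) -> "PixelFrame":
        """Frame after integer downsampling: μm/px multiplied by exactly `factor`."""
        if int(factor) != factor or factor < 1:
            raise InvalidParameterError(f"downsample factor must be integer ≥ 1, got {factor}")
        label = f"{self.magnification_label}/{int(factor)}" if self.magnification_label else ""
        return PixelFrame(self.microns_per_pixel * int(factor), label)


def micron_to_pixel(value_um: float, frame: PixelFrame) -> int:
    """Convert a micron length to an integer pixel count (round half-up)."""
    q = value_um / frame.microns_per_pixel
    return int(math.floor(q + 0.5))


def pixel_to_micron(value_px: float, frame: PixelFrame) -> float:
    """Convert pixels back to microns; round-trips within ±0.5 px."""
    return value_px * frame.microns_per_pixel


# Guard against float dust when a micron coordinate is an exact pixel multiple.
_EPS = 1e-9


@dataclass(frozen=True)
class MicronBox:
    """Axis-aligned box in the WSI micron frame (x right, y down)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidParameterError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def intersection(self, other: "MicronBox") -> "MicronBox | None":
        x0 = max(self.x_min, other.x_min)
        y0 = max(self.y_min, other.y_min)
        x1 = min(self.x_max, other.x_max)
        y1 = min(self.y_max, other.y_max)
        if x0 < x1 and y0 < y1:
            return MicronBox(x0, y0, x1, y1)
        return None

    def union_box(self, other: "MicronBox") -> "MicronBox":
        """Tight axis-aligned bounding box of the pair."""
        return MicronBox(
            min(self.x_min, other.x_min),
            min(self.y_min, other.y_min),
            max(self.x_max, other.x_max),
            max(self.y_max, other.y_max),
        )

    def expand(self, margin_um: float) -> "MicronBox":
        return MicronBox(
            self.x_min - margin_um,
            self.y_min - margin_um,
            self.x_max + margin_um,
            self.y_max + margin_um,
        )

    def clip(self, extent_um: tuple[float, float]) -> "MicronBox | None":
        """Clip to [0, w] × [0, h]; None if the box falls entirely outside."""
        w, h = extent_um
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, w), min(self.y_max, h)
        if x0 < x1 and y0 < y1:
            return MicronBox(x0, y0, x1, y1)
        return None

    def translate(self, dx: float, dy: float) -> "MicronBox":
        return MicronBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def scale(self, factor: float) -> "MicronBox":
        if factor <= 0:
            raise InvalidParameterError("scale factor must be positive")
        return MicronBox(
            self.x_min * factor, self.y_min * factor, self.x_max * factor, self.y_max * factor
        )

    def to_pixel(self, frame: PixelFrame) -> tuple[int, int, int, int]:
        """Half-open pixel box (floor near edges, ceil far edges: never under-covers)."""
        mpp = frame.microns_per_pixel
        return (
            int(math.floor(self.x_min / mpp + _EPS)),
            int(math.floor(self.y_min / mpp + _EPS)),
            int(math.ceil(self.x_max / mpp - _EPS)),
            int(math.ceil(self.y_max / mpp - _EPS)),
        )

    @staticmethod
    def from_pixel(px_box: Sequence[float], frame: PixelFrame) -> "MicronBox":
        x0, y0, x1, y1 = px_box
        mpp = frame.microns_per_pixel
        return MicronBox(x0 * mpp, y0 * mpp, x1 * mpp, y1 * mpp)


def box_overlap_ratio(a: MicronBox, b: MicronBox) -> float:
    """Intersection area over the *smaller* box's area, in [0, 1].

    This is the duplicate-merging criterion: a glomerulus split across a
    window border leaves one small fragment box, for which IoU against the
    full box stays low while the min-area ratio approaches 1.
    """
    inter = a.intersection(b)
    if inter is None:
        return 0.0
    return inter.area / min(a.area, b.area)


def box_iou(a: MicronBox, b: MicronBox) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    inter = a.intersection(b)
    if inter is None:
        return 0.0
    ia = inter.area
    return ia / (a.area + b.area - ia)


def _axis_origins(extent: float, side: float, stride: float) -> list[float]:
    # Final origin clamped so the last window's far edge lands on the extent.
    if side >= extent:
        return [0.0]
    origins: list[float] = []
    k = 0
    while True:
        o = k * stride
        if o + side >= extent - _EPS:
            origins.append(extent - side)
            return origins
        origins.append(o)
        k += 1


@dataclass(frozen=True)
class WindowGrid:
    """Row-major (row-by-row, left-to-right) sliding-window grid in microns."""

    window_side: float
    stride: float
    origins: tuple[tuple[float, float], ...]
    extent: tuple[float, float] = field(default=(0.0, 0.0))

    def windows(self) -> list[MicronBox]:
        w, h = self.extent
        out = []
        for ox, oy in self.origins:
            out.append(
                MicronBox(ox, oy, min(ox + self.window_side, w), min(oy + self.window_side, h))
            )
        return out

    def overlap_strips(self) -> list[MicronBox]:
        """Regions covered by more than one window (used to restrict merging)."""
        strips: list[MicronBox] = []
        w, h = self.extent
        xs = sorted({o[0] for o in self.origins})
        ys = sorted({o[1] for o in self.origins})
        for a, b in zip(xs, xs[1:]):
            if a + self.window_side > b:  # vertical strip shared by columns a, b
                strips.append(MicronBox(b, 0.0, min(a + self.window_side, w), h))
        for a, b in zip(ys, ys[1:]):
            if a + self.window_side > b:
                strips.append(MicronBox(0.0, b, w, min(a + self.window_side, h)))
        return strips


def build_window_grid(
    wsi_extent_um: tuple[float, float],
    window_side_um: float = 2000.0,
    overlap_fraction: float = 0.10,
) -> WindowGrid:
    """Sliding-window grid covering the whole slide.

    Stride is ``window_side × (1 − overlap_fraction)`` (2000 μm windows with
    10% overlap → 200 μm shared strips, wide enough to contain a whole
    ~200 μm glomerulus lying on a window border).  The last window per axis
    is clamped so its far edge coincides with the slide edge; no window ever
    extends beyond the slide and every point is covered at least once.
    """
    if not (0.0 <= overlap_fraction < 1.0):
        raise InvalidParameterError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if window_side_um <= 0:
        raise InvalidParameterError("window_side must be positive")
    stride = window_side_um * (1.0 - overlap_fraction)
    xs = _axis_origins(wsi_extent_um[0], window_side_um, stride)
    ys = _axis_origins(wsi_extent_um[1], window_side_um, stride)
    origins = tuple((x, y) for y in ys for x in xs)  # row-major
    return WindowGrid(window_side_um, stride, origins, tuple(wsi_extent_um))


# ---------------------------------------------------------------------------
# box table I/O

_CSV_COLUMNS = ["glom_id", "x_min", "y_min", "x_max", "y_max", "frame"]


def write_boxes_csv(path, boxes: Iterable[MicronBox], frame_label: str = "wsi_um") -> None:
    rows = [
        {"glom_id": i, "x_min": b.x_min, "y_min": b.y_min,
         "x_max": b.x_max, "y_max": b.y_max, "frame": frame_label}
        for i, b in enumerate(boxes)
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_boxes_csv(path) -> list[MicronBox]:
    df = pd.read_csv(path)
    return [
        MicronBox(r.x_min, r.y_min, r.x_max, r.y_max) for r in df.itertuples(index=False)
    ]


def boxes_to_coco(boxes: Iterable[MicronBox], frame: PixelFrame,
                  confidences: Sequence[float] | None = None) -> dict:
    """COCO-style detection dicts in pixels, with calibration kept as metadata."""
    anns = []
    for i, b in enumerate(boxes):
        x0, y0, x1, y1 = b.to_pixel(frame)
        ann = {"id": i, "category_id": 1, "bbox": [x0, y0, x1 - x0, y1 - y0]}
        if confidences is not None:
            ann["score"] = float(confidences[i])
        anns.append(ann)
    return {
        "annotations": anns,
        "categories": [{"id": 1, "name": "glomerulus"}],
        "frame": {"microns_per_pixel": frame.microns_per_pixel,
                  "magnification_label": frame.magnification_label},
    }


def coco_to_boxes(doc: dict) -> tuple[list[MicronBox], PixelFrame]:
    frame = PixelFrame(**doc["frame"])
    boxes = []
    for ann in doc["annotations"]:
        x, y, w, h = ann["bbox"]
        boxes.append(MicronBox.from_pixel((x, y, x + w, y + h), frame))
    return boxes, frame


def write_coco_json(path, doc: dict) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_coco_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
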