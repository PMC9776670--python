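"""Raster containers shared by both pipeline steps.

:class:`WsiRaster` is the calibrated base-resolution slide image — the
coordinate reference for every box, mask and area in the package.
:class:`LabelMask` is a per-pixel class map over the five-class scheme used
for glomerular components:

====  ==================  =================
code  class               palette (R,G,B)
====  ==================  =================
0     background          255, 255, 255
1     Bowman's space      250, 214, 120
2     glomerular tuft     205,  60,  60
3     crescentic region    60, 180,  75
4     sclerotic region     60,  80, 210
====  ==================  =================

The palette doubles as the phantom generator's paint colours and as the
class centroids of the reference nearest-colour segmenter, which makes the
synthetic pipeline analytically exact at zero noise.  Masks are written as
single-channel indexed PNGs carrying this palette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .errors import InvalidInputError
from .geometry import MicronBox, PixelFrame

__all__ = [
    "CLASS_NAMES",
    "CLASS_PALETTE",
    "N_CLASSES",
    "WsiRaster",
    "LabelMask",
    "read_raster_png",
    "read_mask_png",
]

CLASS_NAMES = (
    "background",
    "bowman_space",
    "tuft",
    "crescentic",
    "sclerotic",
)
N_CLASSES = 5

CLASS_PALETTE = np.array(
    [
        [255, 255, 255],  # background: white
        [250, 214, 120],  # Bowman's space: pale amber
        [205, 60, 60],    # glomerular tuft: red (matches conventional renderings)
        [60, 180, 75],    # crescentic region: green
        [60, 80, 210],    # sclerotic region: blue
    ],
    dtype=np.uint8,
)


@dataclass
class WsiRaster:
    """Base-resolution RGB slide raster with micron calibration."""

    raster: np.ndarray  # (H, W, 3) uint8
    frame: PixelFrame

    def __post_init__(self) -> None:
        if self.raster.ndim != 3 or self.raster.shape[2] != 3:
            raise InvalidInputError(f"expected (H, W, 3) raster, got {self.raster.shape}")

    @property
    def extent_um(self) -> tuple[float, float]:
        h, w = self.raster.shape[:2]
        return (w * self.frame.microns_per_pixel, h * self.frame.microns_per_pixel)

    def region(self, box: MicronBox) -> tuple[np.ndarray, tuple[int, int, int, int]]:
        """Pixel sub-raster covering `box`, clipped to the slide.

        Returns the view and the half-open pixel box actually extracted.
        """
        clipped = box.clip(self.extent_um)
        if clipped is None:
            raise InvalidInputError(f"box {box} lies entirely outside the slide")
        x0, y0, x1, y1 = clipped.to_pixel(self.frame)
        h, w = self.raster.shape[:2]
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        return self.raster[y0:y1, x0:x1], (x0, y0, x1, y1)

    def save_png(self, path) -> None:
        Image.fromarray(self.raster).save(path)


@dataclass
class LabelMask:
    """Per-pixel class codes {0..4} with calibration and placement in the WSI.

    `origin_um` is the micron offset of the mask's top-left pixel corner in
    the WSI frame ((0, 0) for a full-slide mask).
    """

    data: np.ndarray  # (H, W) uint8, values in {0..4}
    frame: PixelFrame
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.size == 0:
            raise InvalidInputError(f"expected non-empty 2D mask, got shape {self.data.shape}")
        if self.data.max(initial=0) >= N_CLASSES:
            raise InvalidInputError("mask contains codes outside {0..4}")

    @property
    def origin_px(self) -> tuple[int, int]:
        mpp = self.frame.microns_per_pixel
        return (int(round(self.origin_um[0] / mpp)), int(round(self.origin_um[1] / mpp)))

    def class_counts(self) -> np.ndarray:
        """Pixel count per class, length 5."""
        return np.bincount(self.data.ravel(), minlength=N_CLASSES)[:N_CLASSES]

    def class_areas_um2(self) -> np.ndarray:
        """Area per class in μm² (pixel count × calibration²)."""
        return self.class_counts() * self.frame.microns_per_pixel ** 2

    def save_png(self, path) -> None:
        img = Image.fromarray(self.data, mode="P")
        img.putpalette(CLASS_PALETTE.ravel().tolist())
        img.save(path)


def read_raster_png(path, frame: PixelFrame) -> WsiRaster:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return WsiRaster(arr, frame)


def read_mask_png(path, frame: PixelFrame, origin_um: tuple[float, float] = (0.0, 0.0)) -> LabelMask:
    arr = np.asarray(Image.open(path), dtype=np.uint8)
    return LabelMask(arr, frame, origin_um)
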