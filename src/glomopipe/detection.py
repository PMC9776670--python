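"""Step 1 — sliding-window glomerulus detection on a whole slide.

The slide is scanned row-by-row, left-to-right with 2000 μm windows
overlapping by 10% (200 μm, enough to contain a whole ~200 μm glomerulus
lying on a window border).  Each window is extracted at a reduced detection
magnification (integer downsample of the base frame, default 8: 0.23 μm/px
at 40x → ~1.84 μm/px, the 5x working scale), fed to a pluggable detector,
and the returned pixel boxes are remapped into the WSI micron frame.
Duplicate boxes of one glomerulus seen from neighbouring windows are then
merged: any pair overlapping by 35% or more (intersection over the smaller
box) collapses to its tight bounding-box union, iterated to a fixpoint.

The detector backend is pluggable (`DetectorContract`); a deep-learning
adapter plugs in exactly like the shipped reference detectors (truth oracle,
jittered oracle, palette blob detector), which exist so every property of
the surrounding machinery can be tested without trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import scipy.ndimage as ndi

from .errors import ContractViolationError, InvalidParameterError
from .geometry import (
    MicronBox,
    PixelFrame,
    WindowGrid,
    box_iou,
    box_overlap_ratio,
    build_window_grid,
)
from .wsi import WsiRaster

__all__ = [
    "DetectorContract",
    "RawDetection",
    "Detection",
    "DetectionRun",
    "DetectionEval",
    "scan_wsi",
    "merge_boxes",
    "evaluate_detection",
    "OracleDetector",
    "JitterDetector",
    "BlobDetector",
]


class DetectorContract(Protocol):
    """Per-window detector interface.

    Called with the window raster at the detection frame, that frame, and
    the window's micron box in the WSI (model backends may ignore the box;
    the oracle backends need it to look up ground truth).  Returns
    ``[(pixel_box, confidence), ...]`` with half-open pixel boxes
    ``(x0, y0, x1, y1)`` local to the window and confidences in [0, 1].
    Boxes must lie inside the window.
    """

    def __call__(
        self, window: np.ndarray, frame: PixelFrame, window_box: MicronBox
    ) -> list[tuple[tuple[float, float, float, float], float]]:
        ...


@dataclass(frozen=True)
class RawDetection:
    """A detector box remapped to the WSI micron frame, tagged with its window."""

    box: MicronBox
    confidence: float
    window_index: int


@dataclass(frozen=True)
class Detection:
    box: MicronBox
    confidence: float


@dataclass
class DetectionRun:
    """Merged detections plus, per box, the raw contributions it absorbed."""

    merged: list[Detection]
    provenance: list[list[RawDetection]]
    threshold: float

    @property
    def boxes(self) -> list[MicronBox]:
        return [d.box for d in self.merged]


@dataclass(frozen=True)
class DetectionEval:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float


def scan_wsi(
    wsi: WsiRaster,
    detector: DetectorContract,
    window_side_um: float = 2000.0,
    overlap_fraction: float = 0.10,
    detection_downsample: int = 8,
) -> tuple[list[RawDetection], WindowGrid]:
    """Scan the slide and collect raw (unmerged) detections in the WSI frame.

    Output order is grid order (row-major) then the detector's own order.
    Windows are subsampled by the integer `detection_downsample` factor; the
    remap chain is window-local px → window-local μm → WSI μm.
    """
    if int(detection_downsample) != detection_downsample or detection_downsample < 1:
        raise InvalidParameterError("detection_downsample must be an integer ≥ 1")
    k = int(detection_downsample)
    grid = build_window_grid(wsi.extent_um, window_side_um, overlap_fraction)
    det_frame = wsi.frame.downsampled(k)
    raw: list[RawDetection] = []
    for widx, wbox in enumerate(grid.windows()):
        region, (px0, py0, px1, py1) = wsi.region(wbox)
        window = region[::k, ::k]
        # pixel-aligned window box: what the detector's pixel grid actually covers
        eff_box = MicronBox.from_pixel((px0, py0, px1, py1), wsi.frame)
        h, w = window.shape[:2]
        for px_box, conf in detector(window, det_frame, eff_box):
            x0, y0, x1, y1 = px_box
            tol = 1e-6
            if x0 < -tol or y0 < -tol or x1 > w + tol or y1 > h + tol or x0 >= x1 or y0 >= y1:
                raise ContractViolationError(
                    f"detector emitted box {px_box} outside window {widx} "
                    f"of size {(w, h)} px"
                )
            mpp = det_frame.microns_per_pixel
            raw.append(
                RawDetection(
                    box=MicronBox(
                        eff_box.x_min + x0 * mpp,
                        eff_box.y_min + y0 * mpp,
                        eff_box.x_min + x1 * mpp,
                        eff_box.y_min + y1 * mpp,
                    ),
                    confidence=float(conf),
                    window_index=widx,
                )
            )
    return raw, grid


def _boxes_touch_common_strip(a: MicronBox, b: MicronBox, strips: Sequence[MicronBox]) -> bool:
    return any(a.intersection(s) and b.intersection(s) for s in strips)


def merge_boxes(
    raw: Sequence[RawDetection | Detection],
    threshold: float = 0.35,
    overlap_strips: Sequence[MicronBox] | None = None,
) -> DetectionRun:
    """Merge duplicate boxes: overlap ratio ≥ `threshold` → bounding-box union.

    Runs to a fixpoint via connected components of the overlap graph (a
    union can create new overlaps, so components are recomputed until
    stable).  The result is independent of input order; a merged box's
    confidence is the max of its constituents.  With `overlap_strips` set
    (from :meth:`WindowGrid.overlap_strips`), only pairs that both touch a
    common inter-window strip are eligible — the literal reading of merging
    restricted to window-border duplicates.
    """
    if not (0.0 < threshold <= 1.0):
        raise InvalidParameterError(f"merge threshold must be in (0, 1], got {threshold}")
    items: list[tuple[MicronBox, float, list[RawDetection]]] = []
    for d in raw:
        prov = [d] if isinstance(d, RawDetection) else [RawDetection(d.box, d.confidence, -1)]
        items.append((d.box, float(d.confidence), prov))

    changed = True
    while changed:
        changed = False
        n = len(items)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if box_overlap_ratio(items[i][0], items[j][0]) >= threshold:
                    if overlap_strips is not None and not _boxes_touch_common_strip(
                        items[i][0], items[j][0], overlap_strips
                    ):
                        continue
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
                        changed = True
        if changed:
            groups: dict[int, list[int]] = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(i)
            merged_items = []
            for members in groups.values():
                box = items[members[0]][0]
                conf = items[members[0]][1]
                prov: list[RawDetection] = []
                for m in members:
                    box = box.union_box(items[m][0])
                    conf = max(conf, items[m][1])
                    prov.extend(items[m][2])
                merged_items.append((box, conf, prov))
            items = merged_items

    # deterministic output order: by position, then confidence
    items.sort(key=lambda it: (it[0].y_min, it[0].x_min, -it[1]))
    return DetectionRun(
        merged=[Detection(b, c) for b, c, _ in items],
        provenance=[p for _, _, p in items],
        threshold=threshold,
    )


def evaluate_detection(
    pred: Sequence[MicronBox],
    truth: Sequence[MicronBox],
    match_iou: float = 0.5,
) -> DetectionEval:
    """Greedy one-to-one matching in descending IoU; pairs ≥ `match_iou` are TP.

    Precision/recall/F1 use the 0/0 → 0 convention.
    """
    if not (0.0 < match_iou <= 1.0):
        raise InvalidParameterError(f"match_iou must be in (0, 1], got {match_iou}")
    pairs = []
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            iou = box_iou(p, t)
            if iou >= match_iou:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    fp = len(pred) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionEval(tp, fp, fn, precision, recall, f1)


# ---------------------------------------------------------------------------
# reference detector backends


class OracleDetector:
    """Returns the ground-truth boxes intersecting each window, clipped to it.

    Exactness backend: with it, any discrepancy downstream is the
    machinery's fault, not the model's.
    """

    def __init__(self, truth_boxes: Sequence[MicronBox]):
        self.truth_boxes = list(truth_boxes)

    def __call__(self, window, frame, window_box):
        mpp = frame.microns_per_pixel
        out = []
        for tb in self.truth_boxes:
            inter = tb.intersection(window_box)
            if inter is None:
                continue
            out.append(
                (
                    (
                        (inter.x_min - window_box.x_min) / mpp,
                        (inter.y_min - window_box.y_min) / mpp,
                        (inter.x_max - window_box.x_min) / mpp,
                        (inter.y_max - window_box.y_min) / mpp,
                    ),
                    1.0,
                )
            )
        return out


class JitterDetector:
    """Oracle degraded by seeded box jitter, drops and spurious boxes.

    The perturbed box set is drawn once at construction (corner jitter
    ~N(0, `jitter_sd_um`), each truth box dropped with `drop_rate`, plus
    `n_spurious` random boxes), then served like the oracle — so a scan is
    deterministic and repeatable for a fixed seed.
    """

    def __init__(
        self,
        truth_boxes: Sequence[MicronBox],
        extent_um: tuple[float, float],
        jitter_sd_um: float = 40.0,
        drop_rate: float = 0.05,
        n_spurious: int = 0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        boxes: list[MicronBox] = []
        for tb in truth_boxes:
            if rng.random() < drop_rate:
                continue
            d = rng.normal(0.0, jitter_sd_um, 4)
            x0, y0 = tb.x_min + d[0], tb.y_min + d[1]
            x1, y1 = tb.x_max + d[2], tb.y_max + d[3]
            if x1 - x0 < 10.0:  # keep boxes valid under extreme draws
                x0, x1 = tb.x_min, tb.x_max
            if y1 - y0 < 10.0:
                y0, y1 = tb.y_min, tb.y_max
            clipped = MicronBox(x0, y0, x1, y1).clip(extent_um)
            if clipped is not None:
                boxes.append(clipped)
        for _ in range(n_spurious):
            w = rng.uniform(80.0, 240.0)
            h = rng.uniform(80.0, 240.0)
            x0 = rng.uniform(0.0, max(extent_um[0] - w, 1.0))
            y0 = rng.uniform(0.0, max(extent_um[1] - h, 1.0))
            boxes.append(MicronBox(x0, y0, x0 + w, y0 + h))
        self._oracle = OracleDetector(boxes)
        self.boxes = boxes

    def __call__(self, window, frame, window_box):
        return self._oracle(window, frame, window_box)


class BlobDetector:
    """Model-free detector for phantom slides: connected non-white blobs.

    Thresholds the distance from the white background, labels connected
    components and returns their bounding boxes.  A demonstration backend,
    not a histology detector.
    """

    def __init__(self, white_distance: float = 60.0, min_area_um2: float = 2000.0):
        self.white_distance = white_distance
        self.min_area_um2 = min_area_um2

    def __call__(self, window, frame, window_box):
        arr = window.astype(np.float64)
        dist = np.linalg.norm(arr - 255.0, axis=-1)
        labels, n = ndi.label(dist > self.white_distance)
        min_px = self.min_area_um2 / frame.microns_per_pixel ** 2
        out = []
        for lab, sl in enumerate(ndi.find_objects(labels), start=1):
            if sl is None:
                continue
            ys, xs = sl
            if (labels[sl] == lab).sum() < min_px:
                continue
            out.append(((xs.start, ys.start, xs.stop, ys.stop), 0.9))
        return out
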