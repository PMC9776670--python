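"""Sliding-window scanning, duplicate merging and detection evaluation."""

import numpy as np
import pytest

from glomopipe import (
    BlobDetector,
    JitterDetector,
    MicronBox,
    OracleDetector,
    PixelFrame,
    WsiRaster,
    box_iou,
    box_overlap_ratio,
    evaluate_detection,
    merge_boxes,
    scan_wsi,
)
from glomopipe.detection import Detection, RawDetection
from glomopipe.errors import ContractViolationError, InvalidParameterError


def _white_slide(extent_um, mpp=2.0):
    w, h = int(extent_um[0] / mpp), int(extent_um[1] / mpp)
    return WsiRaster(np.full((h, w, 3), 255, dtype=np.uint8), PixelFrame(mpp))


def test_empty_detector_yields_no_boxes():
    wsi = _white_slide((3800.0, 2000.0))
    raw, _ = scan_wsi(wsi, lambda window, frame, box: [])
    assert raw == []


def test_oracle_on_single_window_slide_is_identity():
    # slide smaller than one window → single window, remap is the identity
    wsi = _white_slide((2000.0, 2000.0))
    truth = [MicronBox(300, 400, 500, 600), MicronBox(1000, 200, 1250, 460)]
    raw, _ = scan_wsi(wsi, OracleDetector(truth))
    assert len(raw) == len(truth)
    for r, t in zip(raw, truth):
        assert box_iou(r.box, t) == pytest.approx(1.0, abs=1e-9)


def test_straddling_glomerulus_clips_then_merges_back():
    """A glomerulus wider than the overlap strip appears clipped in both windows."""
    wsi = _white_slide((3800.0, 2000.0))
    truth = MicronBox(1700.0, 800.0, 2100.0, 1200.0)  # 400 μm, centered mid-strip
    raw, _ = scan_wsi(wsi, OracleDetector([truth]))
    assert len(raw) == 2
    frag_a, frag_b = raw[0].box, raw[1].box
    assert frag_a.x_max == pytest.approx(2000.0)  # clipped at window 0's far edge
    assert frag_b.x_min == pytest.approx(1800.0)  # clipped at window 1's near edge
    assert box_overlap_ratio(frag_a, frag_b) == pytest.approx(2 / 3, abs=1e-9)

    merged = merge_boxes(raw, threshold=0.35)
    assert len(merged.merged) == 1
    assert box_iou(merged.boxes[0], truth) == pytest.approx(1.0, abs=1e-9)
    for frag in (frag_a, frag_b):  # merged box contains each fragment
        assert box_overlap_ratio(merged.boxes[0], frag) == pytest.approx(1.0)

    unmerged = merge_boxes(raw, threshold=1.0)
    assert len(unmerged.merged) == 2


def test_contract_violation_names_the_window():
    wsi = _white_slide((2000.0, 2000.0))

    def bad_detector(window, frame, box):
        h, w = window.shape[:2]
        return [((0.0, 0.0, w + 10.0, h), 0.9)]

    with pytest.raises(ContractViolationError, match="window 0"):
        scan_wsi(wsi, bad_detector)


def _det(box):
    return Detection(box, 1.0)


def test_merge_examples():
    a = MicronBox(0, 0, 100, 100)
    b = MicronBox(50, 0, 150, 100)     # ratio 0.5 with a
    far = MicronBox(500, 500, 600, 600)
    run = merge_boxes([_det(a), _det(far)], 0.35)
    assert sorted(run.boxes, key=lambda x: x.x_min) == [a, far]
    run = merge_boxes([_det(a), _det(b)], 0.35)
    assert run.boxes == [MicronBox(0, 0, 150, 100)]


def test_merge_is_transitive_through_chains():
    a = MicronBox(0, 0, 100, 100)
    b = MicronBox(60, 0, 160, 100)    # ratio(a,b) = 0.4
    c = MicronBox(120, 0, 220, 100)   # ratio(b,c) = 0.4, ratio(a,c) = 0
    assert box_overlap_ratio(a, c) == 0.0
    run = merge_boxes([_det(x) for x in (a, b, c)], 0.35)
    assert run.boxes == [MicronBox(0, 0, 220, 100)]


def _random_boxes(rng, n=8):
    out = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, 800, 2)
        w, h = rng.uniform(40, 300, 2)
        out.append(MicronBox(x0, y0, x0 + w, y0 + h))
    return out


def _closure_oracle(boxes, threshold):
    """Independent transitive-closure merge: numpy adjacency matrix + BFS components,
    repeated until every component is a singleton."""
    arr = np.array([[b.x_min, b.y_min, b.x_max, b.y_max] for b in boxes], dtype=float)
    while True:
        n = len(arr)
        iw = np.clip(np.minimum(arr[:, None, 2], arr[None, :, 2])
                     - np.maximum(arr[:, None, 0], arr[None, :, 0]), 0, None)
        ih = np.clip(np.minimum(arr[:, None, 3], arr[None, :, 3])
                     - np.maximum(arr[:, None, 1], arr[None, :, 1]), 0, None)
        areas = (arr[:, 2] - arr[:, 0]) * (arr[:, 3] - arr[:, 1])
        ratio = iw * ih / np.minimum(areas[:, None], areas[None, :])
        adj = ratio >= threshold
        np.fill_diagonal(adj, False)
        if not adj.any():
            return [MicronBox(*row) for row in arr]
        seen = np.zeros(n, dtype=bool)
        merged_rows = []
        for start in range(n):
            if seen[start]:
                continue
            frontier, members = [start], []
            seen[start] = True
            while frontier:
                i = frontier.pop()
                members.append(i)
                for j in np.nonzero(adj[i] & ~seen)[0]:
                    seen[j] = True
                    frontier.append(j)
            sub = arr[members]
            merged_rows.append(
                [sub[:, 0].min(), sub[:, 1].min(), sub[:, 2].max(), sub[:, 3].max()]
            )
        arr = np.array(merged_rows, dtype=float)


def _key(box):
    return (round(box.x_min, 6), round(box.y_min, 6), round(box.x_max, 6), round(box.y_max, 6))


def test_merge_matches_closure_oracle_and_is_stable(rng):
    for trial in range(60):
        boxes = _random_boxes(rng)
        run = merge_boxes([_det(b) for b in boxes], 0.35)
        oracle = _closure_oracle(boxes, 0.35)
        assert sorted(map(_key, run.boxes)) == sorted(map(_key, oracle))
        # idempotent
        again = merge_boxes(run.merged, 0.35)
        assert sorted(map(_key, again.boxes)) == sorted(map(_key, run.boxes))
        # permutation-invariant
        perm = list(boxes)
        rng.shuffle(perm)
        shuffled = merge_boxes([_det(b) for b in perm], 0.35)
        assert sorted(map(_key, shuffled.boxes)) == sorted(map(_key, run.boxes))


def test_higher_threshold_never_merges_more(rng):
    for _ in range(30):
        boxes = [_det(b) for b in _random_boxes(rng)]
        counts = [len(merge_boxes(boxes, t).merged) for t in (0.2, 0.5, 0.8, 1.0)]
        assert counts == sorted(counts)


def test_merged_confidence_is_max_of_constituents():
    a = RawDetection(MicronBox(0, 0, 100, 100), 0.4, 0)
    b = RawDetection(MicronBox(50, 0, 150, 100), 0.9, 1)
    run = merge_boxes([a, b], 0.35)
    assert run.merged[0].confidence == 0.9
    assert {r.window_index for r in run.provenance[0]} == {0, 1}


def test_merge_rejects_bad_threshold():
    with pytest.raises(InvalidParameterError):
        merge_boxes([], 0.0)


@pytest.mark.parametrize(
    "n_pred_match, n_truth, precision, recall, f1",
    [(2, 3, 1.0, 2 / 3, 0.8)],
)
def test_evaluate_detection_partial_match(n_pred_match, n_truth, precision, recall, f1):
    truth = [MicronBox(i * 300, 0, i * 300 + 200, 200) for i in range(n_truth)]
    pred = truth[:n_pred_match]
    ev = evaluate_detection(pred, truth)
    assert (ev.precision, ev.recall) == (precision, recall)
    assert ev.f1 == pytest.approx(f1)


def test_evaluate_detection_edge_cases():
    truth = [MicronBox(0, 0, 100, 100)]
    perfect = evaluate_detection(truth, truth)
    assert perfect.f1 == 1.0
    empty = evaluate_detection([], truth)
    assert (empty.recall, empty.f1) == (0.0, 0.0)
    nothing = evaluate_detection([], [])
    assert nothing.f1 == 0.0


def test_oracle_pipeline_scan_recovers_truth(phantom_noise0):
    ph = phantom_noise0
    raw, _ = scan_wsi(ph.wsi, OracleDetector(ph.truth_boxes))
    run = merge_boxes(raw, 0.35)
    ev = evaluate_detection(run.boxes, ph.truth_boxes)
    assert ev.f1 == 1.0
    assert len(run.merged) == len(ph.truth_boxes)


def test_blob_detector_finds_phantom_glomeruli(phantom_noise0):
    ph = phantom_noise0
    raw, _ = scan_wsi(ph.wsi, BlobDetector())
    run = merge_boxes(raw, 0.35)
    ev = evaluate_detection(run.boxes, ph.truth_boxes, match_iou=0.5)
    assert ev.f1 == 1.0


def test_jitter_detector_is_seeded_and_degrades(phantom_noise0):
    ph = phantom_noise0
    kwargs = dict(extent_um=ph.wsi.extent_um, jitter_sd_um=40.0, drop_rate=0.05)
    det_a = JitterDetector(ph.truth_boxes, seed=3, **kwargs)
    det_b = JitterDetector(ph.truth_boxes, seed=3, **kwargs)
    assert det_a.boxes == det_b.boxes  # same seed, same perturbed set
    f1s = []
    for seed in range(5):
        det = JitterDetector(ph.truth_boxes, seed=seed, **kwargs)
        raw, _ = scan_wsi(ph.wsi, det)
        f1s.append(evaluate_detection(merge_boxes(raw).boxes, ph.truth_boxes).f1)
    assert min(f1s) < 1.0  # 40 μm jitter must break exact matching sometimes
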