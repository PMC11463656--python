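"""Object-level detection evaluation: boxes, matching, NMS, AP.

Segmentation masks become detections by drawing a tight box around each
connected component; nearby boxes (fragments of one tangle) are merged
when their centers lie within 150 px.  Ground-truth boxes come from the
truth mask's extent inside a 400x400 window around each point
annotation — the same window used to bootstrap the masks.  Predictions
and truths are matched greedily by descending IOU; unmatched or
near-zero-IOU predictions are false positives and unmatched truths
false negatives.

Boxes are half-open, 0-based: (xmin, ymin, xmax, ymax) with
xmin < xmax, ymin < ymax; IOU uses pixel-area semantics.  The detection
text format is one box per line: ``label xmin ymin xmax ymax
[confidence]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "BoundingBox",
    "MatchResult",
    "box_iou",
    "masks_to_boxes",
    "merge_boxes",
    "gt_boxes_from_points",
    "match_boxes",
    "object_prf",
    "nms",
    "average_precision",
    "assign_boxes_to_tiles",
    "write_detection_file",
    "read_detection_file",
]


@dataclass(frozen=True)
class BoundingBox:
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    confidence: float | None = None
    label: int = 0

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)


@dataclass
class MatchResult:
    """Outcome of matching predictions against ground truths."""

    pairs: list[tuple[int, int, float]]  # (gt index, pred index, IOU)
    unmatched_pred: list[int]  # false positives
    unmatched_gt: list[int]  # false negatives
    min_iou: float = 0.001

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def masks_to_boxes(mask: np.ndarray, connectivity: int = 2) -> list[BoundingBox]:
    """Tight bounding box of every connected component of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    labels = cc_label(mask, connectivity=connectivity)
    boxes = []
    for region in regionprops(labels):
        min_row, min_col, max_row, max_col = region.bbox
        boxes.append(BoundingBox(min_col, min_row, max_col, max_row))
    return boxes


def _enclosing(boxes: list[BoundingBox]) -> BoundingBox:
    return BoundingBox(
        min(b.xmin for b in boxes),
        min(b.ymin for b in boxes),
        max(b.xmax for b in boxes),
        max(b.ymax for b in boxes),
        confidence=max((b.confidence for b in boxes if b.confidence is not None),
                       default=None),
    )


def merge_boxes(
    boxes: list[BoundingBox], center_dist: float = 150.0
) -> list[BoundingBox]:
    """Merge boxes whose centers lie within ``center_dist`` px.

    Groups are the connected components of the center-distance graph
    (transitive closure: a 140-140 chain merges even though its ends are
    280 apart), each replaced by its common enclosing box.  Merging can
    move centers closer, so the procedure iterates to a fixpoint; it is
    idempotent and order-independent.
    """
    current = list(boxes)
    while True:
        n = len(current)
        if n <= 1:
            return current
        centers = np.array([b.center for b in current])
        diff = centers[:, None, :] - centers[None, :, :]
        adjacent = (diff ** 2).sum(-1) <= center_dist ** 2

        # union-find over the adjacency graph
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if adjacent[i, j]:
                    parent[find(i)] = find(j)

        groups: dict[int, list[BoundingBox]] = {}
        for i, b in enumerate(current):
            groups.setdefault(find(i), []).append(b)
        merged = [_enclosing(g) for g in groups.values()]
        if len(merged) == n:
            return merged
        current = merged


def gt_boxes_from_points(
    gt_mask: np.ndarray,
    points: list[tuple[float, float]] | np.ndarray,
    crop: int = 400,
) -> list[BoundingBox]:
    """Ground-truth box per point: truth-mask extent in a window around it.

    For each annotation, take the min/max coordinates of mask foreground
    within the ``crop`` x ``crop`` window centered on the point (clipped
    at ROI borders), shifted back to the ROI frame.  A window with no
    foreground yields no box (logged as a warning).
    """
    gt_mask = np.asarray(gt_mask).astype(bool)
    height, width = gt_mask.shape
    half = crop // 2
    boxes = []
    for px, py in np.asarray(points, dtype=float).reshape(-1, 2):
        x, y = int(round(px)), int(round(py))
        x0, y0 = max(0, x - half), max(0, y - half)
        x1, y1 = min(width, x - half + crop), min(height, y - half + crop)
        window = gt_mask[y0:y1, x0:x1]
        if not window.any():
            warnings.warn(
                f"no truth foreground in window around point ({px}, {py})",
                stacklevel=2,
            )
            continue
        rows, cols = np.nonzero(window)
        boxes.append(
            BoundingBox(
                x0 + int(cols.min()),
                y0 + int(rows.min()),
                x0 + int(cols.max()) + 1,
                y0 + int(rows.max()) + 1,
            )
        )
    return boxes


def match_boxes(
    gt: list[BoundingBox],
    pred: list[BoundingBox],
    min_iou: float = 0.001,
    method: str = "greedy",
) -> MatchResult:
    """Match predictions to ground truths one-to-one by IOU.

    Greedy (default): repeatedly take the highest-IOU unused (gt, pred)
    pair.  A pair is only accepted when its IOU is positive and at least
    ``min_iou`` — so the default discards near-zero overlaps as false
    positives, and ``min_iou=0`` keeps any pair whose IOU exceeds 0.
    ``method="hungarian"`` solves the optimal assignment instead.
    """
    iou = np.zeros((len(gt), len(pred)))
    for i, g in enumerate(gt):
        for j, p in enumerate(pred):
            iou[i, j] = box_iou(g, p)

    pairs: list[tuple[int, int, float]] = []
    if method == "greedy":
        used_gt: set[int] = set()
        used_pred: set[int] = set()
        order = np.argsort(iou, axis=None)[::-1]
        for flat in order:
            i, j = divmod(int(flat), max(len(pred), 1))
            v = iou[i, j]
            if v < min_iou or v <= 0:
                break
            if i in used_gt or j in used_pred:
                continue
            pairs.append((i, j, float(v)))
            used_gt.add(i)
            used_pred.add(j)
    elif method == "hungarian":
        if len(gt) and len(pred):
            rows, cols = linear_sum_assignment(-iou)
            for i, j in zip(rows, cols):
                if iou[i, j] >= min_iou and iou[i, j] > 0:
                    pairs.append((int(i), int(j), float(iou[i, j])))
    else:
        raise ValueError(f"unknown matching method {method!r}")

    matched_gt = {i for i, _, _ in pairs}
    matched_pred = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_pred=[j for j in range(len(pred)) if j not in matched_pred],
        unmatched_gt=[i for i in range(len(gt)) if i not in matched_gt],
        min_iou=min_iou,
    )


def object_prf(result: MatchResult) -> tuple[float, float, float]:
    """Object-level precision, recall and F1 from a match result."""
    tp, fp, fn = result.tp, result.fp, result.fn
    if tp + fp == 0:
        warnings.warn("no predictions; precision undefined, reporting 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def nms(boxes: list[BoundingBox], iou_thresh: float = 0.5) -> list[BoundingBox]:
    """Greedy non-maximum suppression by descending confidence."""
    if any(b.confidence is None for b in boxes):
        raise ValueError("all boxes need a confidence for NMS")
    remaining = sorted(boxes, key=lambda b: -b.confidence)
    kept: list[BoundingBox] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if box_iou(best, b) <= iou_thresh]
    return kept


def average_precision(
    gt_by_image: dict[str, list[BoundingBox]],
    pred_by_image: dict[str, list[BoundingBox]],
    iou_thresh: float = 0.5,
) -> tuple[float, np.ndarray, np.ndarray]:
    """All-point-interpolation AP at one IOU threshold, with its PR curve.

    Predictions are ranked by confidence across images; each is a TP if
    it overlaps (IOU >= threshold) a not-yet-matched ground truth in its
    image, preferring the highest-IOU one.  Returns (AP, precision,
    recall) where the arrays trace the staircase.
    """
    n_gt = sum(len(v) for v in gt_by_image.values())
    if n_gt == 0:
        raise ValueError("AP undefined: no ground-truth boxes")
    records = []
    for img, preds in pred_by_image.items():
        for b in preds:
            if b.confidence is None:
                raise ValueError("all predictions need a confidence for AP")
            records.append((img, b))
    records.sort(key=lambda r: -r[1].confidence)

    matched: dict[str, set[int]] = {img: set() for img in gt_by_image}
    tps = np.zeros(len(records))
    for k, (img, pred) in enumerate(records):
        gts = gt_by_image.get(img, [])
        best_iou, best_i = 0.0, -1
        for i, g in enumerate(gts):
            if i in matched.setdefault(img, set()):
                continue
            v = box_iou(g, pred)
            if v > best_iou:
                best_iou, best_i = v, i
        if best_i >= 0 and best_iou >= iou_thresh:
            tps[k] = 1
            matched[img].add(best_i)

    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(1 - tps)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)

    # all-point interpolation: integrate the precision envelope over recall
    r = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = float(np.sum((r[1:] - r[:-1]) * p[1:]))
    return ap, precision, recall


def average_precision_range(
    gt_by_image: dict[str, list[BoundingBox]],
    pred_by_image: dict[str, list[BoundingBox]],
    thresholds: np.ndarray | None = None,
) -> float:
    """Mean AP over IOU thresholds 0.50:0.05:0.95 (COCO-style)."""
    if thresholds is None:
        thresholds = np.arange(0.50, 0.96, 0.05)
    return float(
        np.mean([average_precision(gt_by_image, pred_by_image, t)[0] for t in thresholds])
    )


def assign_boxes_to_tiles(
    boxes: list[BoundingBox],
    roi_shape: tuple[int, int],
    tile: int = 1024,
    stride: int = 1024,
) -> dict[tuple[int, int], list[BoundingBox]]:
    """Assign each box to the tile containing its center; shift and clip.

    Tile keys are (x, y) top-left corners on the stride lattice; each box
    appears under exactly one key (half-open center rule), with
    coordinates shifted into the tile frame and clipped to tile bounds.
    Boxes whose center falls outside the grid are dropped with a warning.
    """
    height, width = roi_shape
    out: dict[tuple[int, int], list[BoundingBox]] = {}
    for b in boxes:
        cx, cy = b.center
        if not (0 <= cx < width and 0 <= cy < height):
            warnings.warn(f"box center ({cx}, {cy}) outside ROI; dropped", stacklevel=2)
            continue
        tx, ty = int(cx // stride) * stride, int(cy // stride) * stride
        tw, th = min(tile, width - tx), min(tile, height - ty)
        clipped = BoundingBox(
            max(b.xmin - tx, 0.0),
            max(b.ymin - ty, 0.0),
            min(b.xmax - tx, float(tw)),
            min(b.ymax - ty, float(th)),
            confidence=b.confidence,
            label=b.label,
        )
        out.setdefault((tx, ty), []).append(clipped)
    return out


def write_detection_file(boxes: list[BoundingBox], path: str | Path) -> Path:
    """One detection per line: ``label xmin ymin xmax ymax [confidence]``."""
    def fmt(v: float) -> str:
        return f"{v:g}" if v == int(v) else f"{v:.6f}"

    lines = []
    for b in boxes:
        fields = [str(b.label), *(fmt(v) for v in (b.xmin, b.ymin, b.xmax, b.ymax))]
        if b.confidence is not None:
            fields.append(fmt(b.confidence))
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return Path(path)


def read_detection_file(path: str | Path) -> list[BoundingBox]:
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise ValueError(f"bad detection line: {line!r}")
        boxes.append(
            BoundingBox(
                float(parts[1]), float(parts[2]), float(parts[3]), float(parts[4]),
                confidence=float(parts[5]) if len(parts) == 6 else None,
                label=int(parts[0]),
            )
        )
    return boxes
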