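"""Super-tile slicing and expert re-annotation round trips.

Bootstrapped labels inherit the first annotator's misses, which surface
as false-positive clusters in agreement maps.  For efficient expert
review each ROI is sliced into large "super-tiles" (default 4247 x 3560
px — an ROI of 21,236 x 10,680 px yields exactly fifteen), composed into
side-by-side review images (overlay left, raw right), exported in
randomized order, and new point annotations collected on them are mapped
back into the ROI frame as version-2 annotations.  Re-annotation is
additive only: version 2 is a superset of version 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pixel_metrics import AgreementMap, render_agreement_overlay
from .store import PointAnnotation

__all__ = [
    "SuperTile",
    "slice_super_tiles",
    "compose_review_image",
    "randomized_review_order",
    "ingest_new_points",
]

SUPER_TILE_W = 4247
SUPER_TILE_H = 3560


@dataclass
class SuperTile:
    """One review crop of an ROI.

    ``offset`` is the (x, y) of the crop's top-left corner in the ROI
    frame on the super-tile lattice; the final row/column absorbs any
    remainder by clipping (``shape`` may be smaller than nominal).
    ``display_id`` is the randomized identifier used on the review
    platform.
    """

    roi_id: str
    row: int
    col: int
    offset: tuple[int, int]
    shape: tuple[int, int]  # (H, W)
    display_id: str = ""


def slice_super_tiles(
    roi_shape: tuple[int, int],
    roi_id: str = "roi",
    tile_w: int = SUPER_TILE_W,
    tile_h: int = SUPER_TILE_H,
) -> list[SuperTile]:
    """Slice an ROI into a grid of super-tile frames.

    The grid has ``round(W / tile_w)`` columns and ``round(H / tile_h)``
    rows — rounding, not flooring, so a sub-pixel remainder (e.g.
    21,236 / 4247 = 5.0002) does not spawn a sliver column; the final
    row/column is clipped instead.  An ROI smaller than one tile yields a
    single clipped tile.
    """
    height, width = roi_shape
    n_cols = max(1, round(width / tile_w))
    n_rows = max(1, round(height / tile_h))
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = c * tile_w, r * tile_h
            # final row/col absorbs the remainder (clip or extend-to-edge)
            x1 = width if c == n_cols - 1 else min(x0 + tile_w, width)
            y1 = height if r == n_rows - 1 else min(y0 + tile_h, height)
            tiles.append(
                SuperTile(
                    roi_id=roi_id, row=r, col=c,
                    offset=(x0, y0), shape=(y1 - y0, x1 - x0),
                )
            )
    return tiles


def compose_review_image(
    tile_rgb: np.ndarray, amap: AgreementMap, alpha: float = 0.5
) -> np.ndarray:
    """Side-by-side review panel: overlay-blended left, raw right.

    The left panel blends the agreement-map palette (TP cyan, FP yellow,
    FN magenta) over the crop; the right panel is untouched so the
    reviewer can judge the underlying stain.  Output width is twice the
    tile width.
    """
    tile_rgb = np.asarray(tile_rgb)
    if tile_rgb.shape[:2] != amap.categories.shape:
        raise ValueError("tile and agreement map dims must match")
    left = render_agreement_overlay(tile_rgb, amap, alpha=alpha)
    return np.concatenate([left, tile_rgb], axis=1)


def randomized_review_order(
    tiles: list[SuperTile], seed: int = 0, prefix: str = "review"
) -> list[SuperTile]:
    """Assign randomized display ids and return tiles in export order."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tiles))
    out = []
    for k, idx in enumerate(order):
        t = tiles[int(idx)]
        t.display_id = f"{prefix}_{k:04d}"
        out.append(t)
    return out


def ingest_new_points(
    records: list[dict],
    registry: list[SuperTile],
    existing: list[PointAnnotation] | None = None,
    annotator: str = "expert",
) -> tuple[list[PointAnnotation], list[dict]]:
    """Map reviewed points back to the ROI frame as version-2 annotations.

    ``records`` are ``{"image_id": ..., "x": ..., "y": ...}`` with
    coordinates local to the super-tile identified by ``image_id``
    (matched against ``display_id``, falling back to
    ``roi_id:row:col``).  ROI coordinates are offset + local.  Records
    with unresolvable ids are quarantined and returned, never silently
    dropped.  Existing version-1 annotations pass through unchanged, so
    the merged list is a superset of version 1.
    """
    by_id: dict[str, SuperTile] = {}
    for t in registry:
        if t.display_id:
            by_id[t.display_id] = t
        by_id[f"{t.roi_id}:{t.row}:{t.col}"] = t

    merged = list(existing) if existing else []
    quarantined = []
    for rec in records:
        tile = by_id.get(str(rec.get("image_id")))
        if tile is None:
            quarantined.append(rec)
            continue
        merged.append(
            PointAnnotation(
                roi_id=tile.roi_id,
                x=float(rec["x"]) + tile.offset[0],
                y=float(rec["y"]) + tile.offset[1],
                version=2,
                annotator=annotator,
            )
        )
    return merged, quarantined
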