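"""Training-tile grid over ROIs and class-balanced sampling.

Tangles are sparse: at a 1024-px grid most tiles contain no annotation,
so uniform sampling starves the positive class.  The tile index labels
each grid tile positive iff at least one point annotation falls inside
its half-open extent, and the balanced sampler draws tiles so that each
draw is positive with a configured probability (default 0.5), uniform
within class, with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TileIndex", "build_tile_grid", "balanced_sample"]


@dataclass
class TileIndex:
    """Grid of candidate training tiles over one ROI.

    ``table`` columns: roi_id, x, y, width, height, clipped, has_nft.
    (x, y) is the tile's top-left corner on the stride lattice; clipped
    border tiles have width/height < ``tile`` and are excluded from
    training draws by default (uniform tile shape) while still covering
    the ROI for inference.
    """

    table: pd.DataFrame
    tile: int
    stride: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_positive(self) -> int:
        return int(self.table["has_nft"].sum())

    def to_csv(self, path: str | Path) -> Path:
        self.table.to_csv(path, index=False)
        return Path(path)


def build_tile_grid(
    roi_shape: tuple[int, int],
    points: list[tuple[float, float]] | np.ndarray,
    roi_id: str = "roi",
    tile: int = 1024,
    stride: int = 1024,
    include_clipped: bool = True,
) -> TileIndex:
    """Lay a tile grid over an ROI and label tiles by annotation presence.

    A tile at (x, y) is positive iff some point lies in
    [x, x+tile) x [y, y+tile) — half-open, so a point on a shared edge
    belongs to exactly one tile.  With ``include_clipped`` the final
    row/column remainder tiles are kept (flagged) so the grid covers the
    whole ROI.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if tile <= 0:
        raise ValueError("tile size must be positive")
    height, width = roi_shape
    pts = np.asarray(points, dtype=float).reshape(-1, 2)

    rows = []
    for y in range(0, height, stride):
        for x in range(0, width, stride):
            w = min(tile, width - x)
            h = min(tile, height - y)
            clipped = (w < tile) or (h < tile)
            if clipped and not include_clipped:
                continue
            has_nft = bool(
                np.any(
                    (pts[:, 0] >= x) & (pts[:, 0] < x + tile)
                    & (pts[:, 1] >= y) & (pts[:, 1] < y + tile)
                )
            ) if len(pts) else False
            rows.append(
                {
                    "roi_id": roi_id, "x": x, "y": y,
                    "width": w, "height": h,
                    "clipped": clipped, "has_nft": has_nft,
                }
            )
    table = pd.DataFrame(
        rows, columns=["roi_id", "x", "y", "width", "height", "clipped", "has_nft"]
    )
    return TileIndex(table=table, tile=tile, stride=stride)


def balanced_sample(
    index: TileIndex,
    n_draws: int,
    positive_fraction: float = 0.5,
    seed: int | None = 0,
    include_clipped: bool = False,
) -> pd.DataFrame:
    """Draw training tiles with class-balanced replacement.

    Each draw is positive with probability ``positive_fraction`` and
    uniform within its class — equivalent to weighting every tile by the
    inverse frequency of its class, so the expected positive share equals
    ``positive_fraction`` regardless of class imbalance.  Deterministic
    for a fixed seed.
    """
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    table = index.table if include_clipped else index.table[~index.table["clipped"]]
    pos = table.index[table["has_nft"]].to_numpy()
    neg = table.index[~table["has_nft"]].to_numpy()
    if positive_fraction > 0 and len(pos) == 0:
        raise ValueError("tile index has no positive tiles; cannot balance classes")
    if positive_fraction < 1 and len(neg) == 0:
        raise ValueError("tile index has no negative tiles; cannot balance classes")

    rng = np.random.default_rng(seed)
    take_pos = rng.random(n_draws) < positive_fraction
    draws = np.where(
        take_pos,
        rng.choice(pos, size=n_draws) if len(pos) else 0,
        rng.choice(neg, size=n_draws) if len(neg) else 0,
    )
    return index.table.loc[draws].reset_index(drop=True)
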