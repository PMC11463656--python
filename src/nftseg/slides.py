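"""Slide-level inference and tangle-burden scoring.

A pluggable predictor (tile RGB -> per-pixel probability) is slid over
the slide in non-overlapping windows to build a whole-slide mask.  The
burden score counts contiguous detected blobs at a coarse resolution
(1/64 by default), normalizes by detected tissue area at the same
resolution, and rescales by a reference (median training-set) tissue
area so the number reads as "blobs per median-sized slide":

    score = blob_count / tissue_area * median_area

An annotator-analog score applies the same form with the count of point
annotations over the annotated ROI area, letting model and human scores
share an axis.  Scores are compared against ordinal slide grades
(none/sparse/moderate/frequent) with Spearman rank correlation and
pairwise Welch t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2gray
from skimage.measure import block_reduce
from skimage.measure import label as cc_label

from .stains import RUIFROK_JOHNSTON, StainMatrix, dab_binary_mask
from .store import GRADES

__all__ = [
    "DabThresholdPredictor",
    "SlideScore",
    "sliding_window_segment",
    "count_blobs_downscaled",
    "tissue_mask",
    "nft_burden_score",
    "annotator_score",
    "correlate_with_grades",
    "compare_grade_groups",
]


class DabThresholdPredictor:
    """Classical stain-threshold predictor satisfying the tile contract.

    Maps a tile to a binary {0, 1} probability map via
    :func:`~nftseg.stains.dab_binary_mask` (deconvolution + Otsu +
    morphology).  Deterministic; serves as the default stand-in wherever
    a learned segmenter would plug in.
    """

    name = "dab-threshold"

    def __init__(self, stains: StainMatrix = RUIFROK_JOHNSTON,
                 morphology_radius: int = 3) -> None:
        self.stains = stains
        self.morphology_radius = morphology_radius

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        dm = dab_binary_mask(tile, stains=self.stains,
                             morphology_radius=self.morphology_radius)
        return dm.mask.astype(float)


@dataclass
class SlideScore:
    wsi_id: str
    blob_count: int
    tissue_area: int  # px at downscaled resolution
    median_area: float  # rescale constant, same resolution
    score: float
    source: str = "model"  # model | annotator


def sliding_window_segment(
    wsi: np.ndarray,
    predictor,
    tile: int = 1024,
    stride: int = 1024,
    threshold: float = 0.5,
) -> np.ndarray:
    """Non-overlapping sliding-window inference over a whole slide.

    Each tile is predicted independently, thresholded at ``threshold``
    and placed at its grid coordinates; border tiles are clipped.  The
    output binary mask has the slide's spatial dims.
    """
    if stride != tile:
        raise ValueError("inference uses non-overlapping tiles (stride == tile)")
    wsi = np.asarray(wsi)
    height, width = wsi.shape[:2]
    out = np.zeros((height, width), dtype=bool)
    for y in range(0, height, stride):
        for x in range(0, width, stride):
            window = wsi[y : y + tile, x : x + tile]
            prob = np.asarray(predictor(window), dtype=float)
            if prob.shape != window.shape[:2]:
                raise ValueError(
                    f"predictor returned {prob.shape} for tile of {window.shape[:2]}"
                )
            out[y : y + tile, x : x + tile] = prob >= threshold
    return out


def count_blobs_downscaled(
    mask: np.ndarray, factor: int = 64, connectivity: int = 2
) -> int:
    """Count contiguous blobs after block-max downscaling.

    The mask is reduced by taking the max over ``factor`` x ``factor``
    blocks — so thin detections survive — then 8-connected components
    are counted.  Blobs closer than ~``factor`` px can fuse; that bias is
    shared by every slide scored with the same factor.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    mask = np.asarray(mask).astype(bool)
    if factor > 1:
        mask = block_reduce(mask, (factor, factor), np.max)
    labels = cc_label(mask, connectivity=connectivity)
    return int(labels.max())


def tissue_mask(
    wsi: np.ndarray, factor: int = 64, min_od: float = 0.02
) -> tuple[np.ndarray, int]:
    """Separate tissue from white glass on a downscaled slide.

    Downscale by block mean, convert to grayscale optical density,
    Otsu-threshold, and fill holes.  Returns the downscaled binary mask
    and its foreground area in downscaled pixels.  A slide with no
    appreciable stain (OD range below ``min_od``) yields zero area.
    """
    wsi = np.asarray(wsi)
    if wsi.ndim != 3 or wsi.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB, got {wsi.shape}")
    small = block_reduce(wsi.astype(float), (factor, factor, 1), np.mean)
    gray = rgb2gray(small / 255.0)
    od = -np.log10(np.maximum(gray, 1.0 / 255.0))
    if od.max() - od.min() < min_od:
        return np.zeros(od.shape, dtype=bool), 0
    from skimage.filters import threshold_otsu

    mask = od >= threshold_otsu(od, nbins=256)
    mask = binary_fill_holes(mask)
    return mask, int(mask.sum())


def nft_burden_score(
    blob_count: int, tissue_area: float, median_area: float,
    wsi_id: str = "wsi", source: str = "model",
) -> SlideScore:
    """Area-normalized, median-rescaled slide burden score.

    ``count / tissue_area * median_area``: linear in the count, inverse
    in tissue area, and invariant to scaling all areas and the median by
    a common factor.  Zero detections score exactly 0.
    """
    if tissue_area <= 0:
        raise ValueError("tissue area must be positive to normalize the count")
    score = blob_count / tissue_area * median_area
    return SlideScore(
        wsi_id=wsi_id,
        blob_count=int(blob_count),
        tissue_area=int(tissue_area),
        median_area=float(median_area),
        score=float(score),
        source=source,
    )


def annotator_score(
    n_points: int, roi_area: float, median_area: float, wsi_id: str = "wsi",
) -> SlideScore:
    """Human-analog burden score: annotation count over annotated area.

    Same functional form as :func:`nft_burden_score`, with the number of
    point annotations across a slide's ROIs in place of the blob count
    and the total ROI pixel area in place of the tissue area.
    """
    score = nft_burden_score(
        n_points, roi_area, median_area, wsi_id=wsi_id, source="annotator"
    )
    return score


def score_slide(
    wsi: np.ndarray,
    predictor=None,
    wsi_id: str = "wsi",
    tile: int = 1024,
    factor: int = 64,
    median_area: float | None = None,
    threshold: float = 0.5,
) -> SlideScore:
    """End-to-end slide scoring: segment, count, normalize.

    When ``median_area`` is None the slide's own tissue area is used
    (score = blob count).
    """
    predictor = predictor or DabThresholdPredictor()
    mask = sliding_window_segment(wsi, predictor, tile=tile, stride=tile,
                                  threshold=threshold)
    count = count_blobs_downscaled(mask, factor=factor)
    _, area = tissue_mask(wsi, factor=factor)
    if area == 0:
        raise ValueError(f"no tissue detected on slide {wsi_id}; cannot normalize")
    return nft_burden_score(
        count, area, median_area if median_area is not None else area, wsi_id=wsi_id
    )


def _grade_codes(grades: list[str] | np.ndarray) -> np.ndarray:
    codes = []
    for g in grades:
        if isinstance(g, str):
            if g not in GRADES:
                raise ValueError(f"unknown grade {g!r}; expected one of {GRADES}")
            codes.append(GRADES.index(g))
        else:
            codes.append(int(g))
    return np.asarray(codes)


def correlate_with_grades(
    scores: list[float] | np.ndarray, grades: list[str] | np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation of slide scores vs ordinal grades.

    Grades may be names (none/sparse/moderate/frequent) or codes 0-3;
    ties get midranks.  Needs >= 3 pairs and non-constant grades.
    """
    scores = np.asarray(scores, dtype=float)
    codes = _grade_codes(grades)
    if len(scores) != len(codes):
        raise ValueError("scores and grades must pair up")
    if len(scores) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(codes == codes[0]):
        raise ValueError("grades are constant; rank correlation undefined")
    rho, p = stats.spearmanr(scores, codes)
    return float(rho), float(p)


def compare_grade_groups(
    scores_by_grade: dict[str, list[float]],
) -> pd.DataFrame:
    """Pairwise Welch t-tests between adjacent grade groups.

    Groups are ordered by grade severity; each adjacent pair with >= 2
    observations per side gets an unequal-variance t statistic and
    two-sided p.  Singleton groups are skipped with a warning; pairs of
    zero-variance groups with different means are flagged degenerate.
    """
    ordered = [g for g in GRADES if g in scores_by_grade]
    ordered += [g for g in scores_by_grade if g not in GRADES]
    rows = []
    for a, b in zip(ordered, ordered[1:]):
        xa = np.asarray(scores_by_grade[a], dtype=float)
        xb = np.asarray(scores_by_grade[b], dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(
                f"skipping {a} vs {b}: needs >= 2 observations per group",
                stacklevel=2,
            )
            continue
        degenerate = xa.std() == 0 and xb.std() == 0
        if degenerate and xa.mean() != xb.mean():
            t, p = np.inf, 0.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "group_a": a, "group_b": b,
                "n_a": len(xa), "n_b": len(xb),
                "t": float(t), "p": float(p),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "t", "p", "degenerate"]
    )
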