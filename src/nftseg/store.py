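"""Chunked WSI storage, rotated-ROI extraction and annotation containers.

Whole-slide scans are stored as chunked Zarr arrays (5000-px chunks by
default) so ROI-sized windows can be read without loading gigapixel
images.  Annotated ROIs are rectangles that may be rotated relative to
the slide axes; extraction slices the minimal axis-aligned bounding
region and resamples the rectangle upright.  Point annotations travel
between the slide (global) and ROI (local) frames through the same rigid
transform, so extraction and point mapping commute.

Coordinates are 0-based with (x, y) = (column, row); corners are the
positions of the rectangle's corner *pixel centers*, listed clockwise
from the ROI's top-left.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import zarr
from skimage.transform import AffineTransform, warp

__all__ = [
    "WSIRecord",
    "ROIRecord",
    "PointAnnotation",
    "GRADES",
    "store_chunked",
    "load_chunked",
    "extract_rotated_roi",
    "points_global_to_local",
    "points_local_to_global",
    "read_annotation_csv",
    "write_annotation_csv",
]

#: Ordinal slide grades (CERAD-like), least to most severe.
GRADES = ("none", "sparse", "moderate", "frequent")


@dataclass
class WSIRecord:
    wsi_id: str
    image: str | Path | np.ndarray
    resolution_um: float = 0.11
    scene_suffix: str | None = None
    split: str = "train"
    grade: str | None = None

    def __post_init__(self) -> None:
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if self.split not in ("train", "val", "test", "external"):
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class ROIRecord:
    """An extracted (possibly rotated) rectangular region of a WSI."""

    roi_id: str
    wsi_id: str
    corners: np.ndarray  # 4x2 (x, y), clockwise from top-left
    angle: float  # radians
    shape: tuple[int, int]  # (H, W) of the extracted image
    storage: str | Path | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 2):
            raise ValueError("corners must be 4x2 (x, y)")
        # rectangle check: diagonals share a midpoint and have equal length
        mid_ac, mid_bd = (c[0] + c[2]) / 2, (c[1] + c[3]) / 2
        if np.abs(mid_ac - mid_bd).max() > 0.5:
            raise ValueError("corners do not form a rectangle (midpoint mismatch)")
        d1, d2 = np.linalg.norm(c[2] - c[0]), np.linalg.norm(c[3] - c[1])
        if abs(d1 - d2) > 1.0:
            raise ValueError("corners do not form a rectangle (diagonal mismatch)")
        self.corners = c


@dataclass
class PointAnnotation:
    """Nucleolus point of one tangle, in the local frame of its ROI."""

    roi_id: str
    x: float
    y: float
    version: int = 1
    annotator: str = ""

    def validate(self, shape: tuple[int, int]) -> None:
        height, width = shape
        if not (0 <= self.x < width and 0 <= self.y < height):
            raise ValueError(
                f"point ({self.x}, {self.y}) outside ROI of shape {shape}"
            )


def store_chunked(
    image: np.ndarray, path: str | Path, chunk: int = 5000
) -> Path:
    """Write an 8-bit RGB image to a chunked Zarr store (lossless).

    Chunks are ``chunk`` px in both spatial dimensions (borders smaller);
    the full color axis lives in one chunk.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB, got shape {image.shape}")
    arr = zarr.create_array(
        store=str(path),
        shape=image.shape,
        chunks=(chunk, chunk, 3),
        dtype=image.dtype,
        overwrite=True,
    )
    arr[:] = image
    return Path(path)


def load_chunked(path: str | Path) -> np.ndarray:
    """Read back a full image stored by :func:`store_chunked`."""
    return np.asarray(zarr.open_array(str(path), mode="r")[:])


def _corner_geometry(corners: np.ndarray) -> tuple[float, int, int]:
    """Angle (radians) and extracted (H, W) implied by the corner order."""
    c = np.asarray(corners, dtype=float)
    ex = c[1] - c[0]  # local +x direction
    ey = c[3] - c[0]  # local +y direction
    angle = math.atan2(ex[1], ex[0])
    width = int(round(np.linalg.norm(ex))) + 1
    height = int(round(np.linalg.norm(ey))) + 1
    return angle, height, width


def extract_rotated_roi(
    wsi: np.ndarray,
    corners: np.ndarray,
    roi_id: str = "roi",
    wsi_id: str = "wsi",
    order: int = 1,
) -> tuple[np.ndarray, ROIRecord]:
    """Cut an upright ROI image out of a WSI given four corner points.

    The minimal axis-aligned bounding region around the rotated rectangle
    is sliced first, then resampled (bilinear by default) so the ROI's
    local x-axis runs along its first corner edge.  Angle 0 degenerates to
    a plain slice with pixels identical to the source; multiples of 90
    degrees avoid interpolation up to rounding of the rotation matrix.
    """
    wsi = np.asarray(wsi)
    c = np.asarray(corners, dtype=float)
    height_wsi, width_wsi = wsi.shape[:2]
    for i, (x, y) in enumerate(c):
        if not (-0.5 <= x <= width_wsi - 0.5 and -0.5 <= y <= height_wsi - 0.5):
            raise ValueError(f"corner {i} at ({x}, {y}) outside WSI bounds")
    angle, height, width = _corner_geometry(c)

    # slice the minimal inscribing axis-aligned region (with 1-px guard)
    x_lo = max(int(np.floor(c[:, 0].min())) - 1, 0)
    y_lo = max(int(np.floor(c[:, 1].min())) - 1, 0)
    x_hi = min(int(np.ceil(c[:, 0].max())) + 2, width_wsi)
    y_hi = min(int(np.ceil(c[:, 1].max())) + 2, height_wsi)
    block = wsi[y_lo:y_hi, x_lo:x_hi]

    cos_a, sin_a = math.cos(angle), math.sin(angle)
    # maps ROI (output) coords to block (input) coords
    tform = AffineTransform(
        matrix=np.array(
            [
                [cos_a, -sin_a, c[0, 0] - x_lo],
                [sin_a, cos_a, c[0, 1] - y_lo],
                [0, 0, 1],
            ]
        )
    )
    if abs(angle) < 1e-12:
        roi = block[
            int(round(c[0, 1])) - y_lo : int(round(c[0, 1])) - y_lo + height,
            int(round(c[0, 0])) - x_lo : int(round(c[0, 0])) - x_lo + width,
        ].copy()
    else:
        roi = warp(
            block,
            tform,
            output_shape=(height, width) + block.shape[2:],
            order=order,
            cval=255,
            preserve_range=True,
        )
        roi = np.clip(np.rint(roi), 0, 255).astype(wsi.dtype)
    record = ROIRecord(
        roi_id=roi_id, wsi_id=wsi_id, corners=c, angle=angle, shape=(height, width)
    )
    return roi, record


def points_global_to_local(
    points: np.ndarray | list[tuple[float, float]],
    roi: ROIRecord,
    drop_outside: bool = False,
    version: int = 1,
    annotator: str = "",
) -> list[PointAnnotation]:
    """Map WSI-frame points into an ROI's local frame.

    The transform is the exact inverse of the extraction resampling, so a
    global point and its local image read the same source pixel (within
    1 px for interpolated angles).  Points landing outside the ROI raise
    by default, or are dropped when ``drop_outside`` is set.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cos_a, sin_a = math.cos(roi.angle), math.sin(roi.angle)
    rot_inv = np.array([[cos_a, sin_a], [-sin_a, cos_a]])
    local = (pts - roi.corners[0]) @ rot_inv.T
    height, width = roi.shape
    out: list[PointAnnotation] = []
    for (gx, gy), (lx, ly) in zip(pts, local):
        inside = -0.5 <= lx < width - 0.5 and -0.5 <= ly < height - 0.5
        if not inside:
            if drop_outside:
                warnings.warn(
                    f"dropping point ({gx}, {gy}): outside ROI {roi.roi_id}",
                    stacklevel=2,
                )
                continue
            raise ValueError(f"point ({gx}, {gy}) lies outside ROI {roi.roi_id}")
        out.append(
            PointAnnotation(
                roi_id=roi.roi_id,
                x=float(lx),
                y=float(ly),
                version=version,
                annotator=annotator,
            )
        )
    return out


def points_local_to_global(
    points: list[PointAnnotation] | np.ndarray, roi: ROIRecord
) -> np.ndarray:
    """Inverse of :func:`points_global_to_local`; returns Nx2 (x, y)."""
    if len(points) and isinstance(points[0], PointAnnotation):
        pts = np.array([[p.x, p.y] for p in points], dtype=float)
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
    cos_a, sin_a = math.cos(roi.angle), math.sin(roi.angle)
    rot = np.array([[cos_a, -sin_a], [sin_a, cos_a]])
    return pts @ rot.T + roi.corners[0]


def write_annotation_csv(points: list[PointAnnotation], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {"roi_id": p.roi_id, "x": p.x, "y": p.y, "version": p.version,
             "annotator": p.annotator}
            for p in points
        ],
        columns=["roi_id", "x", "y", "version", "annotator"],
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_annotation_csv(path: str | Path) -> list[PointAnnotation]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        PointAnnotation(
            roi_id=str(r.roi_id), x=float(r.x), y=float(r.y),
            version=int(r.version), annotator=str(r.annotator),
        )
        for r in df.itertuples()
    ]


def write_roi_registry(rois: list[ROIRecord], path: str | Path) -> Path:
    """ROI registry as JSON (corner geometry + storage references)."""
    payload = [
        {
            "roi_id": r.roi_id,
            "wsi_id": r.wsi_id,
            "corners": r.corners.tolist(),
            "angle": r.angle,
            "shape": list(r.shape),
            "storage": str(r.storage) if r.storage else None,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
    return Path(path)


def read_roi_registry(path: str | Path) -> list[ROIRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        ROIRecord(
            roi_id=r["roi_id"],
            wsi_id=r["wsi_id"],
            corners=np.array(r["corners"], dtype=float),
            angle=float(r["angle"]),
            shape=tuple(r["shape"]),
            storage=r["storage"],
        )
        for r in payload
    ]
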