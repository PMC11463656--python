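"""Synthetic AT8-IHC scene generator with per-object ground truth.

Emulates 8-bit RGB tiles of AT8-stained temporal cortex: a
hematoxylin-tinted tissue background, flame-shaped DAB-dense tangle
objects (an elliptical soma with 1-2 tapered protrusions and a nucleolus
point), optional diffuse DAB speckle, and per-object binary masks plus one
nucleolus point annotation per true tangle.  Distractor objects — DAB
blobs that fail the annotation criteria (no nucleolus, diffuse edges) —
carry no points.

Composition follows Beer-Lambert: per-pixel OD = background hematoxylin
OD + object DAB OD, and RGB = 255 * 10^(-OD @ S) for the shared stain
matrix S, so unmixing with :mod:`nftseg.stains` recovers the truth masks.

Scenes are bit-exactly reproducible from (parameters, seed).  All public
coordinates are (x, y) = (column, row), 0-based; arrays are indexed
(row, col).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.measure import label

from .stains import RUIFROK_JOHNSTON, StainMatrix

__all__ = [
    "ObjectSpec",
    "SyntheticScene",
    "SyntheticWSI",
    "PlacementError",
    "render_object_mask",
    "render_scene",
    "make_annotated_roi",
    "make_synthetic_wsi",
    "save_scene",
    "load_scene",
]

#: Background hematoxylin OD of "clean" tissue.
TISSUE_HEMATOXYLIN_OD = 0.25
#: OD of a single diffuse-DAB speckle pixel (well below object OD).
SPECKLE_DAB_OD = 0.35


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed under the separation constraint."""


@dataclass(frozen=True)
class ObjectSpec:
    """Geometry and stain density of one rendered object.

    ``soma_axes`` are the ellipse semi-axes (px) of the cell body; the
    protrusions are tapered triangles leaving the soma along
    ``orientation``.  ``nucleolus_offset`` displaces the annotation point
    from the soma center and must keep it inside the rendered mask.
    ``is_nft`` distinguishes annotated tangles from distractor blobs.
    """

    center: tuple[float, float]  # (x, y)
    soma_axes: tuple[float, float] = (55.0, 38.0)  # (along-axis, across-axis)
    orientation: float = 0.0  # radians
    n_protrusions: int = 2
    protrusion_length: float = 60.0
    dab_od: float = 1.0
    nucleolus_offset: tuple[float, float] = (0.0, 0.0)
    is_nft: bool = True

    def __post_init__(self) -> None:
        a, b = self.soma_axes
        if a <= 0 or b <= 0:
            raise ValueError(f"degenerate soma axes {self.soma_axes}")
        if a < 3 or b < 3:
            raise ValueError("soma axes must be >= 3 px")
        if self.n_protrusions not in (0, 1, 2):
            raise ValueError("n_protrusions must be 0, 1 or 2")
        if self.dab_od <= 0:
            raise ValueError("dab_od must be positive")

    @property
    def nucleolus(self) -> tuple[int, int]:
        """Annotation point (x, y), integer pixel coordinates."""
        return (
            int(round(self.center[0] + self.nucleolus_offset[0])),
            int(round(self.center[1] + self.nucleolus_offset[1])),
        )


@dataclass
class SyntheticScene:
    """A rendered scene plus its ground truth.

    ``masks`` holds one full-frame binary mask per object (NFTs and
    distractors alike, in ``objects`` order); ``points`` holds one
    nucleolus annotation per ``is_nft`` object.
    """

    image: np.ndarray  # HxWx3 uint8
    objects: list[ObjectSpec]
    masks: list[np.ndarray]
    points: list[tuple[int, int]]
    noise: float
    seed: int
    overlapping: bool = field(default=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]

    def union_mask(self, nft_only: bool = False) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for spec, m in zip(self.objects, self.masks):
            if nft_only and not spec.is_nft:
                continue
            out |= m
        return out


def render_object_mask(spec: ObjectSpec, height: int, width: int) -> np.ndarray:
    """Rasterize one flame-shaped object into an HxW boolean mask.

    The mask is the union of the soma ellipse and 0-2 tapered triangular
    protrusions anchored inside the soma along the orientation axis.  The
    result must be a single connected component containing the nucleolus
    point (when the nucleolus lies on the canvas); violations raise.
    """
    cx, cy = spec.center
    a, b = spec.soma_axes
    mask = np.zeros((height, width), dtype=bool)

    # soma: skimage's ellipse wants rotation in (-pi, pi) in the (row, col)
    # frame; the ellipse has period pi, so reduce the orientation first
    rot = -(spec.orientation % np.pi)
    rr, cc = draw_ellipse(cy, cx, b, a, shape=(height, width), rotation=rot)
    mask[rr, cc] = True

    u = np.array([np.cos(spec.orientation), np.sin(spec.orientation)])  # (dx, dy)
    v = np.array([-u[1], u[0]])
    half_width = 0.5 * b
    for k in range(spec.n_protrusions):
        direction = u if k == 0 else -u
        base = np.array([cx, cy]) + 0.8 * a * direction
        tip = np.array([cx, cy]) + (a + spec.protrusion_length) * direction
        p1 = base + half_width * v
        p2 = base - half_width * v
        xs = np.array([tip[0], p1[0], p2[0]])
        ys = np.array([tip[1], p1[1], p2[1]])
        rr, cc = draw_polygon(ys, xs, shape=(height, width))
        mask[rr, cc] = True
        # a sharp tip can rasterize as a detached pixel; the spine from
        # soma center to tip keeps the protrusion one piece
        rr, cc = draw_line(
            int(round(cy)), int(round(cx)), int(round(tip[1])), int(round(tip[0]))
        )
        inside = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
        mask[rr[inside], cc[inside]] = True

    if not mask.any():
        raise ValueError("object lies entirely outside the canvas")
    n_components = int(label(mask, connectivity=2).max())
    if n_components != 1:
        raise ValueError(f"object rendered as {n_components} components; expected 1")
    px, py = spec.nucleolus
    if 0 <= px < width and 0 <= py < height and not mask[py, px]:
        raise ValueError("nucleolus point falls outside the rendered mask")
    return mask


def render_scene(
    objects: list[ObjectSpec],
    dims: tuple[int, int] = (2048, 2048),
    stains: StainMatrix = RUIFROK_JOHNSTON,
    noise: float = 0.0,
    seed: int = 0,
    sensor_sigma: float = 0.0,
    background_od: float = TISSUE_HEMATOXYLIN_OD,
) -> SyntheticScene:
    """Render objects over tinted tissue into an 8-bit RGB scene.

    ``noise`` is the per-pixel Bernoulli rate of diffuse single-pixel DAB
    speckle (0 <= noise < 0.5); ``sensor_sigma`` adds optional Gaussian
    8-bit sensor noise after rendering.  Overlapping object masks are
    allowed but flagged in ``scene.overlapping``.
    """
    if not 0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    height, width = dims
    rng = np.random.default_rng(seed)

    # float32 throughout: halves the footprint on WSI-scale canvases
    hed = np.zeros((height, width, 3), dtype=np.float32)
    hed[..., 0] = background_od

    masks = [render_object_mask(spec, height, width) for spec in objects]
    coverage = np.zeros((height, width), dtype=np.uint8)
    for spec, m in zip(objects, masks):
        hed[..., 2][m] += spec.dab_od
        coverage += m.astype(np.uint8)
    overlapping = bool((coverage > 1).any())
    del coverage

    if noise > 0:
        speckle = rng.random((height, width)) < noise
        hed[..., 2][speckle] += SPECKLE_DAB_OD

    rgb = hed @ stains.matrix.astype(np.float32)
    del hed
    np.negative(rgb, out=rgb)
    np.power(10.0, rgb, out=rgb)
    rgb *= 255.0
    if sensor_sigma > 0:
        rgb += rng.normal(0.0, sensor_sigma, rgb.shape).astype(np.float32)
    image = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    points = [spec.nucleolus for spec in objects if spec.is_nft]
    return SyntheticScene(
        image=image,
        objects=list(objects),
        masks=masks,
        points=points,
        noise=noise,
        seed=seed,
        overlapping=overlapping,
    )


def _sample_nft_spec(rng: np.random.Generator, center: tuple[float, float]) -> ObjectSpec:
    a = rng.uniform(48.0, 68.0)
    b = rng.uniform(32.0, 46.0)
    return ObjectSpec(
        center=center,
        soma_axes=(a, b),
        orientation=rng.uniform(0.0, 2.0 * np.pi),
        n_protrusions=int(rng.integers(1, 3)),
        protrusion_length=rng.uniform(40.0, 80.0),
        dab_od=rng.uniform(0.8, 1.2),
        nucleolus_offset=(rng.uniform(-8.0, 8.0), rng.uniform(-8.0, 8.0)),
        is_nft=True,
    )


def _sample_distractor_spec(rng: np.random.Generator, center: tuple[float, float]) -> ObjectSpec:
    # off-criteria blob: smaller, rounder, weaker stain, no protrusions
    a = rng.uniform(18.0, 32.0)
    b = rng.uniform(14.0, 26.0)
    return ObjectSpec(
        center=center,
        soma_axes=(a, b),
        orientation=rng.uniform(0.0, 2.0 * np.pi),
        n_protrusions=0,
        protrusion_length=0.0,
        dab_od=rng.uniform(0.45, 0.65),
        is_nft=False,
    )


def make_annotated_roi(
    n_nft: int,
    n_distractor: int = 0,
    dims: tuple[int, int] = (2048, 2048),
    noise: float = 0.0,
    seed: int = 0,
    min_separation: float = 300.0,
    stains: StainMatrix = RUIFROK_JOHNSTON,
) -> SyntheticScene:
    """Place tangles and distractors at random and render the ROI.

    Object centers are drawn uniformly inside a margin and kept at least
    ``min_separation`` px apart (rejection sampling with bounded retries;
    exhaustion raises :class:`PlacementError`).  Exactly ``n_nft`` point
    annotations are emitted, one inside each true tangle mask.
    """
    height, width = dims
    rng = np.random.default_rng(seed)
    margin = 160.0  # soma + longest protrusion stays on canvas
    if width <= 2 * margin or height <= 2 * margin:
        raise ValueError(f"dims {dims} too small for margin {margin}")

    centers: list[tuple[float, float]] = []
    max_tries = 200 * max(1, n_nft + n_distractor)
    tries = 0
    while len(centers) < n_nft + n_distractor:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n_nft + n_distractor} objects with "
                f"separation {min_separation} in {dims} after {max_tries} tries"
            )
        tries += 1
        cand = (rng.uniform(margin, width - margin), rng.uniform(margin, height - margin))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_separation for c in centers):
            centers.append(cand)

    specs = [_sample_nft_spec(rng, c) for c in centers[:n_nft]]
    specs += [_sample_distractor_spec(rng, c) for c in centers[n_nft:]]
    scene = render_scene(specs, dims=dims, stains=stains, noise=noise, seed=seed)
    # placement used the same seed stream before rendering; reproducibility
    # is over (arguments, seed) as a whole
    return scene


@dataclass
class SyntheticWSI:
    """A small synthetic whole-slide image: tissue on a white background.

    ``tissue_box`` is (x0, y0, x1, y1), half-open, of the tissue region.
    ``nft_mask`` is the union of true tangle masks in the slide frame.
    """

    image: np.ndarray
    points: list[tuple[int, int]]
    nft_mask: np.ndarray
    tissue_box: tuple[int, int, int, int]

    @property
    def tissue_area(self) -> int:
        x0, y0, x1, y1 = self.tissue_box
        return (x1 - x0) * (y1 - y0)


def make_synthetic_wsi(
    n_nft: int,
    dims: tuple[int, int] = (4096, 4096),
    tissue_fraction: float = 0.6,
    noise: float = 0.0,
    seed: int = 0,
) -> SyntheticWSI:
    """Compose a slide: white glass, one rectangular tissue region, tangles.

    The tissue rectangle covers ``tissue_fraction`` of the slide (centered,
    aspect matched to the slide) and is rendered with
    :func:`make_annotated_roi`; the remainder stays white.
    """
    if not 0 < tissue_fraction <= 1:
        raise ValueError("tissue_fraction must be in (0, 1]")
    height, width = dims
    scale = float(np.sqrt(tissue_fraction))
    th, tw = int(round(height * scale)), int(round(width * scale))
    y0, x0 = (height - th) // 2, (width - tw) // 2

    roi = make_annotated_roi(n_nft, dims=(th, tw), noise=noise, seed=seed)
    image = np.full((height, width, 3), 255, dtype=np.uint8)
    image[y0 : y0 + th, x0 : x0 + tw] = roi.image

    nft_mask = np.zeros((height, width), dtype=bool)
    nft_mask[y0 : y0 + th, x0 : x0 + tw] = roi.union_mask(nft_only=True)
    points = [(x + x0, y + y0) for x, y in roi.points]
    return SyntheticWSI(
        image=image,
        points=points,
        nft_mask=nft_mask,
        tissue_box=(x0, y0, x0 + tw, y0 + th),
    )


def save_scene(scene: SyntheticScene, out_dir: str | Path) -> Path:
    """Write a scene as PNG image + per-object mask PNGs + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "scene.png", scene.image)
    for i, m in enumerate(scene.masks):
        iio.imwrite(out / f"mask_{i:03d}.png", (m.astype(np.uint8) * 255))
    sidecar = {
        "seed": scene.seed,
        "noise": scene.noise,
        "overlapping": scene.overlapping,
        "points": [list(p) for p in scene.points],
        "objects": [
            {
                "center": list(s.center),
                "soma_axes": list(s.soma_axes),
                "orientation": s.orientation,
                "n_protrusions": s.n_protrusions,
                "protrusion_length": s.protrusion_length,
                "dab_od": s.dab_od,
                "nucleolus_offset": list(s.nucleolus_offset),
                "is_nft": s.is_nft,
            }
            for s in scene.objects
        ],
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_scene(scene_dir: str | Path) -> SyntheticScene:
    """Load a scene written by :func:`save_scene`."""
    d = Path(scene_dir)
    meta = json.loads((d / "scene.json").read_text())
    objects = [
        ObjectSpec(
            center=tuple(o["center"]),
            soma_axes=tuple(o["soma_axes"]),
            orientation=o["orientation"],
            n_protrusions=o["n_protrusions"],
            protrusion_length=o["protrusion_length"],
            dab_od=o["dab_od"],
            nucleolus_offset=tuple(o["nucleolus_offset"]),
            is_nft=o["is_nft"],
        )
        for o in meta["objects"]
    ]
    masks = [
        iio.imread(d / f"mask_{i:03d}.png").astype(bool) for i in range(len(objects))
    ]
    return SyntheticScene(
        image=iio.imread(d / "scene.png"),
        objects=objects,
        masks=masks,
        points=[tuple(p) for p in meta["points"]],
        noise=meta["noise"],
        seed=meta["seed"],
        overlapping=meta["overlapping"],
    )
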