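"""HSV-saturation tissue segmentation and non-overlapping patch tessellation.

The segmentation pipeline, run at a coarse pyramid level and scaled back to
level 0, is: read region -> RGB to HSV -> saturation channel -> median
filter (kernel ``mthresh``) -> binary threshold at ``sthresh`` -> contour
detection with parent/child hierarchy -> two-stage area filter (tissue
contours at ``athresh``, holes within kept tissue at ``hole_athresh``) ->
scale vertices to level 0. Background in an H&E scan is near-white and
therefore unsaturated, so the saturation channel separates tissue from
glass robustly across stain intensity.

Contours are found with subpixel marching squares; the hole/tissue role of
each closed contour is decided by the mask value at a representative
interior point, and hole parents by polygon containment. Areas are the
polygon shoelace areas of the contour vertices, computed at the
segmentation level before scaling. Tessellation keeps every grid-aligned
``patch_size`` square whose center lies inside a tissue contour and outside
every hole.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.prepared import prep
from skimage import measure
from skimage.color import rgb2hsv
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SegParams",
    "TissueMask",
    "PatchGrid",
    "ImageSource",
    "open_image",
    "choose_seg_level",
    "segment_tissue",
    "find_contours_with_hierarchy",
    "filter_contours_by_area",
    "scale_contours_to_level0",
    "tessellate",
    "rasterize_mask",
    "mask_to_geojson",
    "write_patch_manifest",
]


@dataclass
class SegParams:
    """Segmentation knobs; defaults follow the upstream pipeline's magnitudes.

    ``athresh`` and ``hole_athresh`` are in pixels *at the segmentation
    level*; callers scaling them with the downsample should do so before
    constructing the params (the CLI does).
    """

    seg_level: int = 0
    sthresh: int = 8
    mthresh: int = 7
    athresh: float = 100.0
    hole_athresh: float = 16.0

    def __post_init__(self) -> None:
        if self.mthresh < 1 or self.mthresh % 2 == 0:
            raise ValueError("mthresh must be odd and >= 1")
        if not 0 <= self.sthresh <= 255:
            raise ValueError("sthresh must lie in [0, 255]")
        if self.athresh < 0 or self.hole_athresh < 0:
            raise ValueError("area thresholds must be nonnegative")


@dataclass
class TissueMask:
    """Tissue and hole polygons in level-0 integer coordinates."""

    contours: list[np.ndarray]       # each (K, 2) int, (x, y) vertices
    holes: list[np.ndarray]
    downsample: float = 1.0
    hole_parents: list[int] = field(default_factory=list)  # index into contours


@dataclass
class PatchGrid:
    """Grid-aligned level-0 patch corners retained by tessellation."""

    coords: np.ndarray               # (M, 2) int, (x, y) top-left corners
    patch_size: int = 256
    magnification_tag: str = "20x"


class ImageSource:
    """A (possibly pyramidal) RGB image exposed level by level.

    Plain arrays and single-page images are one level with downsample 1;
    multi-page TIFFs expose each page as a level with the downsample
    inferred from the width ratio to level 0.
    """

    def __init__(self, levels: list[np.ndarray]):
        if not levels:
            raise OSError("image source has no readable levels")
        self.levels = [np.asarray(l) for l in levels]

    @classmethod
    def from_array(cls, img: np.ndarray) -> "ImageSource":
        return cls([img])

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def clamp_level(self, level: int) -> int:
        return min(max(level, 0), self.n_levels - 1)

    def read_level(self, level: int) -> np.ndarray:
        return self.levels[self.clamp_level(level)]

    def downsample(self, level: int) -> float:
        level = self.clamp_level(level)
        return self.levels[0].shape[1] / self.levels[level].shape[1]

    @property
    def extent(self) -> tuple[int, int]:
        """Level-0 (width, height)."""
        h, w = self.levels[0].shape[:2]
        return w, h


def open_image(path: str | Path) -> ImageSource:
    """Open a PNG/TIFF image; multi-page TIFFs are treated as pyramids."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
        pages.sort(key=lambda a: -a.shape[1])
        return ImageSource(pages)
    from PIL import Image

    with Image.open(path) as im:
        return ImageSource([np.asarray(im.convert("RGB"))])


def choose_seg_level(source: ImageSource, target: int = 1024) -> int:
    """Coarsest pyramid level whose longest side is still >= target pixels."""
    for level in range(source.n_levels - 1, -1, -1):
        h, w = source.levels[level].shape[:2]
        if max(h, w) >= target:
            return level
    return 0


# ---------------------------------------------------------------------------
# pipeline stages


def _saturation_channel(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(f"expected an RGB image, got shape {rgb.shape}")
    sat = rgb2hsv(rgb[:, :, :3])[:, :, 1]
    return (sat * 255.0).astype(np.uint8)


def _shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def find_contours_with_hierarchy(
    binary: np.ndarray,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Closed contours of a binary mask with parent/child nesting.

    Returns (contours, parents): each contour is a (K, 2) float array of
    (x, y) vertices; parents[i] is the index of the immediately enclosing
    contour, or -1 for an outermost (tissue) contour. A contour is a hole
    boundary iff the mask is 0 just inside it, i.e. it has an odd nesting
    depth.
    """
    padded = np.pad(binary.astype(np.uint8), 1)
    raw = measure.find_contours(padded.astype(float), 0.5)
    contours: list[np.ndarray] = []
    polys: list[Polygon] = []
    for rc in raw:
        xy = np.stack([rc[:, 1] - 1.0, rc[:, 0] - 1.0], axis=1)  # undo pad, (x, y)
        np.clip(xy, 0.0, None, out=xy)
        if len(xy) < 4:
            continue
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area == 0:
            continue
        contours.append(xy)
        polys.append(poly)
    # parent = smallest-area strictly containing contour
    areas = [p.area for p in polys]
    order = np.argsort(areas)
    parents = np.full(len(polys), -1, dtype=int)
    for i in range(len(polys)):
        best, best_area = -1, np.inf
        pt = polys[i].representative_point()
        for j in range(len(polys)):
            if j == i or areas[j] <= areas[i]:
                continue
            if polys[j].contains(pt) and areas[j] < best_area:
                best, best_area = j, areas[j]
        parents[i] = best
    del order
    return contours, parents


def _depth(parents: np.ndarray, i: int) -> int:
    d = 0
    while parents[i] != -1:
        i = parents[i]
        d += 1
    return d


def filter_contours_by_area(
    contours: list[np.ndarray],
    hierarchy: np.ndarray,
    athresh: float,
    hole_athresh: float,
) -> tuple[list[np.ndarray], list[np.ndarray], list[int]]:
    """Two-stage area filter at the segmentation level.

    Even-depth contours are tissue boundaries and are kept when their
    shoelace area is >= athresh; odd-depth contours are holes and are kept
    when their area is >= hole_athresh *and* their parent tissue contour
    survived. Returns (tissue_contours, holes, hole_parent_indices).
    """
    hierarchy = np.asarray(hierarchy)
    if len(hierarchy) != len(contours):
        raise ValueError("hierarchy length does not match contour count")
    tissue: list[np.ndarray] = []
    kept_index: dict[int, int] = {}
    for i, c in enumerate(contours):
        if _depth(hierarchy, i) % 2 == 0 and _shoelace_area(c) >= athresh:
            kept_index[i] = len(tissue)
            tissue.append(c)
    holes: list[np.ndarray] = []
    hole_parents: list[int] = []
    for i, c in enumerate(contours):
        if _depth(hierarchy, i) % 2 == 1 and _shoelace_area(c) >= hole_athresh:
            parent = hierarchy[i]
            if parent in kept_index:
                holes.append(c)
                hole_parents.append(kept_index[parent])
    return tissue, holes, hole_parents


def scale_contours_to_level0(
    contours: list[np.ndarray], downsample: float
) -> list[np.ndarray]:
    """Multiply vertices by the downsample and round half away from zero."""
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    out = []
    for c in contours:
        v = np.asarray(c, dtype=float) * float(downsample)
        out.append(np.floor(np.abs(v) + 0.5).astype(np.int64) * np.sign(v).astype(np.int64))
    return out


def segment_tissue(image_source, params: SegParams) -> TissueMask:
    """Run the full segmentation pipeline; empty scenes give empty masks."""
    if isinstance(image_source, np.ndarray):
        image_source = ImageSource.from_array(image_source)
    level = image_source.clamp_level(params.seg_level)
    rgb = image_source.read_level(level)
    sat = _saturation_channel(rgb)
    filtered = ndimage.median_filter(sat, size=params.mthresh)
    binary = filtered > params.sthresh
    contours, hierarchy = find_contours_with_hierarchy(binary)
    tissue, holes, hole_parents = filter_contours_by_area(
        contours, hierarchy, params.athresh, params.hole_athresh
    )
    ds = image_source.downsample(level)
    return TissueMask(
        contours=scale_contours_to_level0(tissue, ds),
        holes=scale_contours_to_level0(holes, ds),
        downsample=ds,
        hole_parents=hole_parents,
    )


# ---------------------------------------------------------------------------
# tessellation


def tessellate(
    mask: TissueMask,
    patch_size: int,
    image_extent: tuple[int, int],
    magnification_tag: str = "20x",
) -> PatchGrid:
    """Grid-aligned patches whose center is in tissue and outside all holes.

    ``image_extent`` is level-0 (width, height); only patches fully inside
    the extent are considered.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    w, h = image_extent
    xs = np.arange(0, w - patch_size + 1, patch_size)
    ys = np.arange(0, h - patch_size + 1, patch_size)
    if len(xs) == 0 or len(ys) == 0 or not mask.contours:
        return PatchGrid(coords=np.zeros((0, 2), dtype=np.int64),
                         patch_size=patch_size, magnification_tag=magnification_tag)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    corners = np.stack([gx.ravel(), gy.ravel()], axis=1)
    centers = corners + patch_size / 2.0

    import shapely

    keep = np.zeros(len(centers), dtype=bool)
    for poly in (Polygon(c) for c in mask.contours):
        if not poly.is_valid:
            poly = poly.buffer(0)
        keep |= shapely.contains_xy(poly, centers[:, 0], centers[:, 1])
    for hole in (Polygon(c) for c in mask.holes):
        if not hole.is_valid:
            hole = hole.buffer(0)
        keep &= ~shapely.contains_xy(hole, centers[:, 0], centers[:, 1])
    return PatchGrid(coords=corners[keep].astype(np.int64),
                     patch_size=patch_size, magnification_tag=magnification_tag)


# ---------------------------------------------------------------------------
# export helpers


def rasterize_mask(mask: TissueMask, shape_hw: tuple[int, int],
                   downsample: float | None = None) -> np.ndarray:
    """Binary raster of the mask at level 0 / shape_hw (for IoU checks, PNGs)."""
    scale = 1.0 if downsample is None else 1.0 / downsample
    out = np.zeros(shape_hw, dtype=bool)
    for c in mask.contours:
        rr, cc = draw_polygon(c[:, 1] * scale, c[:, 0] * scale, shape=shape_hw)
        out[rr, cc] = True
    for c in mask.holes:
        rr, cc = draw_polygon(c[:, 1] * scale, c[:, 0] * scale, shape=shape_hw)
        out[rr, cc] = False
    return out


def mask_to_geojson(mask: TissueMask) -> str:
    """Tissue contours with their holes as a GeoJSON FeatureCollection."""
    features = []
    for i, c in enumerate(mask.contours):
        rings = [c.tolist() + [c[0].tolist()]]
        for h, parent in zip(mask.holes, mask.hole_parents):
            if parent == i:
                rings.append(h.tolist() + [h[0].tolist()])
        features.append({
            "type": "Feature",
            "properties": {"index": i},
            "geometry": {"type": "Polygon", "coordinates": rings},
        })
    return json.dumps({"type": "FeatureCollection", "features": features})


def write_patch_manifest(grid: PatchGrid, slide_id: str, path: str | Path) -> Path:
    """Patch manifest CSV; qc_pass is a hook for patch-level quality control."""
    path = Path(path)
    lines = ["slide_id,x,y,patch_size,qc_pass"]
    for x, y in grid.coords:
        lines.append(f"{slide_id},{x},{y},{grid.patch_size},1")
    path.write_text("\n".join(lines) + "\n")
    return path
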