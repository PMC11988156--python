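"""Construction of positive (tumor-bud) and negative (non-tumor) bags.

Each annotated tumor bud is enclosed in a 512 x 512-pixel region of interest
(ROI); the ROI is the *bag* and the 96 x 96-pixel tiles cropped from it with a
stride of 32 pixels are its *instances* (196 per bag at defaults).  Negative
bags come from tessellating 512 x 512 ROIs over annotated non-tumor polygons.
Under the standard multiple-instance assumption a bag is positive iff at
least one instance contains a tumor bud.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

from .slide_io import AnnotationSet, SlideRecord, read_region

DEFAULT_ROI = 512
DEFAULT_TILE = 96
DEFAULT_STRIDE = 32


@dataclass
class BagSpec:
    """Geometry and label of one bag: an ROI plus its instance grid."""

    bag_id: str
    slide_id: str
    label: str  # "positive" | "negative"
    roi_origin: tuple[int, int]
    roi_size: int = DEFAULT_ROI
    tile_size: int = DEFAULT_TILE
    stride: int = DEFAULT_STRIDE
    instance_origins: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bag label must be 'positive'/'negative', got {self.label!r}")

    @property
    def n_instances(self) -> int:
        return len(self.instance_origins)

    def instance_rects(self) -> list[tuple[int, int, int, int]]:
        """Half-open instance rectangles as (x0, y0, x1, y1)."""
        t = self.tile_size
        return [(x, y, x + t, y + t) for x, y in self.instance_origins]


def _make_bag_id(slide_id: str, label: str, origin: tuple[int, int]) -> str:
    return f"{slide_id}:{label}:{origin[0]}_{origin[1]}"


def grid_offsets(roi_size: int, tile_size: int, stride: int) -> list[int]:
    """Tile offsets 0, stride, 2*stride, ... with offset + tile_size <= roi_size."""
    if tile_size > roi_size:
        raise ValueError(f"tile_size {tile_size} exceeds roi_size {roi_size}")
    if stride <= 0:
        raise ValueError(f"stride must be positive, got {stride}")
    return list(range(0, roi_size - tile_size + 1, stride))


def expected_instance_count(roi_size: int, tile_size: int, stride: int) -> int:
    """Closed-form instance count: (floor((roi - tile)/stride) + 1)^2."""
    return ((roi_size - tile_size) // stride + 1) ** 2


def place_positive_bag(
    tb_anchor: tuple[float, float],
    slide: SlideRecord,
    roi_size: int = DEFAULT_ROI,
    tile_size: int = DEFAULT_TILE,
    stride: int = DEFAULT_STRIDE,
) -> BagSpec:
    """Enclose a tumor-bud anchor in an ROI centred on it.

    The ROI origin is ``anchor - roi_size/2`` (floor), clamped so the ROI
    stays within the slide.
    """
    if slide.width_px < roi_size or slide.height_px < roi_size:
        raise ValueError(
            f"slide {slide.slide_id!r} ({slide.width_px}x{slide.height_px}) "
            f"is smaller than roi_size {roi_size}"
        )
    ax, ay = tb_anchor
    if not (0 <= ax < slide.width_px and 0 <= ay < slide.height_px):
        raise ValueError(f"anchor {tb_anchor} outside slide bounds")
    ox = int(np.floor(ax - roi_size / 2))
    oy = int(np.floor(ay - roi_size / 2))
    ox = min(max(ox, 0), slide.width_px - roi_size)
    oy = min(max(oy, 0), slide.height_px - roi_size)
    bag = BagSpec(
        bag_id=_make_bag_id(slide.slide_id, "positive", (ox, oy)),
        slide_id=slide.slide_id,
        label="positive",
        roi_origin=(ox, oy),
        roi_size=roi_size,
        tile_size=tile_size,
        stride=stride,
    )
    return tile_bag(bag)


def tile_bag(bag: BagSpec) -> BagSpec:
    """Populate ``instance_origins`` with the full regular grid, row-major."""
    offsets = grid_offsets(bag.roi_size, bag.tile_size, bag.stride)
    ox, oy = bag.roi_origin
    origins = [(ox + dx, oy + dy) for dy in offsets for dx in offsets]
    return replace(bag, instance_origins=origins)


def tessellate_negative_bags(
    region: BaseGeometry,
    slide: SlideRecord,
    roi_size: int = DEFAULT_ROI,
    tile_size: int = DEFAULT_TILE,
    stride: int = DEFAULT_STRIDE,
) -> list[BagSpec]:
    """Tessellate non-overlapping ROIs over a non-tumor polygon.

    The grid is aligned to the polygon's bounding box; an ROI is kept iff it
    is fully contained in the polygon (guaranteeing negatives carry no tumor
    tissue) and within slide bounds.
    """
    minx, miny, maxx, maxy = region.bounds
    x0, y0 = int(np.ceil(minx)), int(np.ceil(miny))
    bags: list[BagSpec] = []
    y = y0
    while y + roi_size <= maxy:
        x = x0
        while x + roi_size <= maxx:
            roi = box(x, y, x + roi_size, y + roi_size)
            if (
                region.contains(roi)
                and x + roi_size <= slide.width_px
                and y + roi_size <= slide.height_px
                and x >= 0
                and y >= 0
            ):
                bag = BagSpec(
                    bag_id=_make_bag_id(slide.slide_id, "negative", (x, y)),
                    slide_id=slide.slide_id,
                    label="negative",
                    roi_origin=(x, y),
                    roi_size=roi_size,
                    tile_size=tile_size,
                    stride=stride,
                )
                bags.append(tile_bag(bag))
            x += roi_size
        y += roi_size
    return bags


def _rect_contains_point(rect: tuple[int, int, int, int], px: float, py: float) -> bool:
    # half-open: a point on the right/bottom edge is NOT contained
    x0, y0, x1, y1 = rect
    return x0 <= px < x1 and y0 <= py < y1


def assign_bag_label(bag: BagSpec, annotations: AnnotationSet) -> str:
    """Label a tiled bag by the standard MIL rule.

    Positive iff at least one instance rectangle intersects at least one
    tumor-bud annotation (half-open containment for point annotations,
    interior overlap for polygons); otherwise negative.
    """
    if not bag.instance_origins:
        raise ValueError(f"bag {bag.bag_id!r} is not tiled")
    tb_regions = annotations.by_label("tumor_bud")
    if not tb_regions:
        return "negative"
    rects = bag.instance_rects()
    for region in tb_regions:
        geom = region.geometry
        if geom.geom_type == "Point":
            if any(_rect_contains_point(r, geom.x, geom.y) for r in rects):
                return "positive"
        else:
            for x0, y0, x1, y1 in rects:
                if box(x0, y0, x1, y1).intersection(geom).area > 0:
                    return "positive"
    return "negative"


def build_bags(
    slide: SlideRecord,
    annotations: AnnotationSet,
    roi_size: int = DEFAULT_ROI,
    tile_size: int = DEFAULT_TILE,
    stride: int = DEFAULT_STRIDE,
    min_tissue_fraction: float | None = None,
) -> list[BagSpec]:
    """Build all bags for one slide: one positive bag per tumor-bud
    annotation (polygons reduced to their centroid as anchor) plus the
    tessellated negative bags of every non-tumor polygon.

    ``min_tissue_fraction`` optionally drops bags whose ROI contains less
    than that fraction of non-background (brightness < 240) pixels; off by
    default.
    """
    bags: list[BagSpec] = []
    for region in annotations.by_label("tumor_bud"):
        geom = region.geometry
        anchor = (geom.x, geom.y) if geom.geom_type == "Point" else (
            geom.centroid.x,
            geom.centroid.y,
        )
        bags.append(place_positive_bag(anchor, slide, roi_size, tile_size, stride))
    for region in annotations.by_label("non_tumor"):
        bags.extend(
            tessellate_negative_bags(region.geometry, slide, roi_size, tile_size, stride)
        )
    if min_tissue_fraction is not None:
        bags = [
            b
            for b in bags
            if _tissue_fraction(slide, b) >= min_tissue_fraction
        ]
    return bags


def _tissue_fraction(slide: SlideRecord, bag: BagSpec) -> float:
    roi = read_region(slide, *bag.roi_origin, bag.roi_size, bag.roi_size)
    return float(np.mean(roi.mean(axis=2) < 240))


# ---------------------------------------------------------------------------
# Manifest and tile export


def write_manifest(bags: list[BagSpec], path: str | Path) -> None:
    """Write the bag manifest CSV (bag_id, slide_id, label, origin_x, origin_y,
    roi_size, tile_size, stride)."""
    rows = [
        {
            "bag_id": b.bag_id,
            "slide_id": b.slide_id,
            "label": b.label,
            "origin_x": b.roi_origin[0],
            "origin_y": b.roi_origin[1],
            "roi_size": b.roi_size,
            "tile_size": b.tile_size,
            "stride": b.stride,
        }
        for b in bags
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[BagSpec]:
    df = pd.read_csv(path)
    bags = []
    for row in df.itertuples(index=False):
        bag = BagSpec(
            bag_id=row.bag_id,
            slide_id=row.slide_id,
            label=row.label,
            roi_origin=(int(row.origin_x), int(row.origin_y)),
            roi_size=int(row.roi_size),
            tile_size=int(row.tile_size),
            stride=int(row.stride),
        )
        bags.append(tile_bag(bag))
    return bags


def extract_tiles(slide: SlideRecord, bag: BagSpec) -> list[np.ndarray]:
    """Crop every instance tile of a bag from the slide, in grid order."""
    return [
        read_region(slide, x, y, bag.tile_size, bag.tile_size)
        for x, y in bag.instance_origins
    ]


def export_tiles_png(slide: SlideRecord, bag: BagSpec, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, tile in enumerate(extract_tiles(slide, bag)):
        p = out_dir / f"{bag.bag_id.replace(':', '_')}_tile{k:03d}.png"
        Image.fromarray(tile).save(p)
        paths.append(p)
    return paths


__all__ = [
    "BagSpec",
    "assign_bag_label",
    "build_bags",
    "expected_instance_count",
    "export_tiles_png",
    "extract_tiles",
    "grid_offsets",
    "place_positive_bag",
    "read_manifest",
    "tessellate_negative_bags",
    "tile_bag",
    "write_manifest",
]
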