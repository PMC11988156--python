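"""Slide and annotation IO with a uniform pixel coordinate model.

Coordinates are 0-based with the origin at the top-left corner, x rightward
and y downward.  Rectangles are half-open: ``[x, x + w) x [y, y + h)``, the
convention used by common slide readers.  Slides may be tiled TIFF (including
the generic-TIFF flavor of SVS files) or plain raster images (PNG/JPEG)
standing in for slide regions.

Annotations are GeoJSON feature collections in slide pixel coordinates; each
feature carries a ``label`` property restricted to the vocabulary used during
annotation of the invasive front: ``tumor_bud``, ``tumor``, ``non_tumor`` and
``invasive_front``.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("budmil")

#: Labels accepted in annotation files.
ANNOTATION_LABELS = frozenset({"tumor_bud", "tumor", "non_tumor", "invasive_front"})

_TIFF_SUFFIXES = {".tif", ".tiff", ".svs"}
_RASTER_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}


class SlideFormatError(ValueError):
    """Raised when a slide file cannot be read as a supported raster format."""


class AnnotationError(ValueError):
    """Raised for malformed or invalid annotation files."""


@dataclass
class SlideRecord:
    """Header-level description of one slide image."""

    slide_id: str
    width_px: int
    height_px: int
    magnification: float | None = None
    mpp: float | None = None  # microns per pixel; opaque metadata, never computed with
    source_path: str | None = None
    _image: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError(
                f"slide {self.slide_id!r}: dimensions must be positive, "
                f"got {self.width_px}x{self.height_px}"
            )

    @property
    def bounds(self) -> Polygon:
        """Slide extent as a shapely box (half-open semantics by convention)."""
        return box(0, 0, self.width_px, self.height_px)


@dataclass
class Region:
    """One annotated region: a label plus a point or polygon geometry."""

    label: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.label not in ANNOTATION_LABELS:
            raise AnnotationError(
                f"unknown annotation label {self.label!r}; "
                f"allowed: {sorted(ANNOTATION_LABELS)}"
            )


@dataclass
class AnnotationSet:
    """All annotated regions of one slide."""

    slide_id: str
    regions: list[Region] = field(default_factory=list)

    def label_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.regions))

    def by_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# Slide reading


def _decode_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in _TIFF_SUFFIXES:
            import tifffile

            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise SlideFormatError(f"cannot read slide image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise SlideFormatError(
            f"slide {path} decoded to shape {arr.shape}; expected HxWx3 RGB"
        )
    return np.ascontiguousarray(arr[:, :, :3])


def read_slide(path: str | Path) -> SlideRecord:
    """Read slide header information from a raster file.

    The pixel data are decoded lazily on the first :func:`read_region` call
    and cached on the record.
    """
    path = Path(path)
    if not path.exists():
        raise SlideFormatError(f"slide file does not exist: {path}")
    suffix = path.suffix.lower()
    if suffix not in _TIFF_SUFFIXES | _RASTER_SUFFIXES:
        raise SlideFormatError(f"unsupported slide format {suffix!r}: {path}")
    if suffix in _TIFF_SUFFIXES:
        import tifffile

        try:
            with tifffile.TiffFile(path) as tif:
                page = tif.pages[0]
                height, width = page.shape[:2]
        except Exception as exc:  # noqa: BLE001
            raise SlideFormatError(f"cannot read slide header {path}: {exc}") from exc
    else:
        try:
            with Image.open(path) as im:
                width, height = im.size
        except Exception as exc:  # noqa: BLE001
            raise SlideFormatError(f"cannot read slide header {path}: {exc}") from exc
    return SlideRecord(
        slide_id=path.stem,
        width_px=int(width),
        height_px=int(height),
        source_path=str(path),
    )


def slide_from_array(slide_id: str, image: np.ndarray, **meta) -> SlideRecord:
    """Wrap an in-memory RGB array as a slide record (synthetic pipelines)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise SlideFormatError(f"expected HxWx3 RGB array, got shape {image.shape}")
    rec = SlideRecord(
        slide_id=slide_id,
        width_px=int(image.shape[1]),
        height_px=int(image.shape[0]),
        **meta,
    )
    rec._image = np.asarray(image, dtype=np.uint8)
    return rec


def read_region(
    slide: SlideRecord,
    x: int,
    y: int,
    w: int,
    h: int,
    edge_policy: str = "error",
) -> np.ndarray:
    """Read the window ``[x, x+w) x [y, y+h)`` as an ``h x w x 3`` uint8 array.

    ``edge_policy`` controls out-of-bounds windows: ``"error"`` (default)
    raises, ``"pad_white"`` fills pixels outside the slide with 255.
    """
    if w <= 0 or h <= 0:
        raise ValueError(f"region size must be positive, got {w}x{h}")
    if edge_policy not in ("error", "pad_white"):
        raise ValueError(f"edge_policy must be 'error' or 'pad_white', got {edge_policy!r}")
    inside = 0 <= x and 0 <= y and x + w <= slide.width_px and y + h <= slide.height_px
    if not inside and edge_policy == "error":
        raise ValueError(
            f"region ({x},{y},{w},{h}) exceeds slide bounds "
            f"{slide.width_px}x{slide.height_px} (edge_policy='error')"
        )
    if slide._image is None:
        if slide.source_path is None:
            raise SlideFormatError(f"slide {slide.slide_id!r} has no pixel source")
        slide._image = _decode_image(Path(slide.source_path))
    img = slide._image
    if inside:
        return img[y : y + h, x : x + w].copy()
    out = np.full((h, w, 3), 255, dtype=np.uint8)
    sx0, sy0 = max(x, 0), max(y, 0)
    sx1, sy1 = min(x + w, slide.width_px), min(y + h, slide.height_px)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y : sy1 - y, sx0 - x : sx1 - x] = img[sy0:sy1, sx0:sx1]
    return out


# ---------------------------------------------------------------------------
# Annotation reading / writing


def _clip_to_slide(geom: BaseGeometry, slide: SlideRecord) -> BaseGeometry | None:
    clipped = geom.intersection(slide.bounds)
    if clipped.is_empty:
        return None
    # Intersection can yield multi-geometries at slide corners; keep the
    # largest polygon part so downstream code sees simple geometries.
    if clipped.geom_type in ("MultiPolygon", "GeometryCollection"):
        polys = [g for g in clipped.geoms if g.geom_type == "Polygon"]
        if not polys:
            return None
        clipped = max(polys, key=lambda g: g.area)
    return clipped


def read_annotations(path: str | Path, slide: SlideRecord) -> AnnotationSet:
    """Parse a GeoJSON feature collection into an :class:`AnnotationSet`.

    Polygons are clipped to the slide bounds; tumor-bud point annotations are
    kept as points.  Features with labels outside :data:`ANNOTATION_LABELS`
    make the whole file invalid.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    features = doc.get("features", [])
    if not features:
        warnings.warn(f"annotation file {path} contains no features", stacklevel=2)
        return AnnotationSet(slide_id=slide.slide_id)

    unknown = [
        f.get("properties", {}).get("label")
        for f in features
        if f.get("properties", {}).get("label") not in ANNOTATION_LABELS
    ]
    if unknown:
        raise AnnotationError(
            f"{path}: unknown annotation labels {sorted(set(map(str, unknown)))}; "
            f"allowed: {sorted(ANNOTATION_LABELS)}"
        )

    regions: list[Region] = []
    for feat in features:
        label = feat["properties"]["label"]
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon" and not geom.is_valid:
            raise AnnotationError(
                f"{path}: self-intersecting polygon in feature labeled {label!r}"
            )
        clipped = _clip_to_slide(geom, slide)
        if clipped is None:
            warnings.warn(
                f"{path}: {label} feature lies entirely outside slide bounds; dropped",
                stacklevel=2,
            )
            continue
        regions.append(Region(label=label, geometry=clipped))

    ann = AnnotationSet(slide_id=slide.slide_id, regions=regions)
    logger.info("read %s: label counts %s", path, ann.label_counts())
    return ann


def write_annotations(path: str | Path, annotations: AnnotationSet) -> None:
    """Write an :class:`AnnotationSet` back to GeoJSON (round-trip safe)."""
    features = [
        {
            "type": "Feature",
            "properties": {"label": r.label},
            "geometry": mapping(r.geometry),
        }
        for r in annotations.regions
    ]
    doc = {
        "type": "FeatureCollection",
        "properties": {"slide_id": annotations.slide_id},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


__all__ = [
    "ANNOTATION_LABELS",
    "AnnotationError",
    "AnnotationSet",
    "Region",
    "SlideFormatError",
    "SlideRecord",
    "read_annotations",
    "read_region",
    "read_slide",
    "slide_from_array",
    "write_annotations",
    "Point",
    "Polygon",
]
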