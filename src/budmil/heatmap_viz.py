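"""Attention heatmaps and attention-annotation agreement scoring.

Per-instance attention weights are painted back onto the bag's ROI: every
pixel takes the mean (or max) attention of the tiles covering it — with the
default 96-px tiles at stride 32 a pixel can sit under up to 9 tiles — and
the map is min-max rescaled to [0,1] for display while the raw accumulation
is kept for scoring.  Agreement with tumor-bud annotations is scored on the
thresholded map: each 8-connected hot component that covers at least
``min_overlap`` of an annotated bud makes that bud a true positive; a bud no
component covers enough is a false negative; a component touching no bud at
all is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

from .bag_builder import BagSpec
from .slide_io import AnnotationSet

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class AttentionMap:
    """Pixel-level attention over one ROI.

    ``grid`` is the display map in [0,1] (min-max rescaled; constant raw
    maps become all-zero); ``raw`` keeps the unscaled per-pixel attention and
    ``coverage`` the number of tiles covering each pixel.
    """

    bag_id: str
    grid: np.ndarray
    raw: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("non-finite attention map")


@dataclass
class RegionScore:
    """Region-level agreement between the heatmap and bud annotations."""

    tp: int
    fp: int
    fn: int
    detected_regions: list[np.ndarray] = field(default_factory=list, repr=False)


def attention_to_map(bag: BagSpec, a: np.ndarray, accumulate: str = "mean") -> AttentionMap:
    """Rasterize per-instance attention onto the bag's ROI.

    Each pixel's raw value is the mean (or max) of ``a_k`` over the tiles
    covering it; the display grid is min-max rescaled over the ROI.
    """
    a = np.asarray(a, dtype=np.float64)
    if len(a) != bag.n_instances:
        raise ValueError(
            f"{len(a)} attention weights for {bag.n_instances} instances"
        )
    if accumulate not in ("mean", "max"):
        raise ValueError(f"accumulate must be 'mean' or 'max', got {accumulate!r}")
    size, t = bag.roi_size, bag.tile_size
    ox, oy = bag.roi_origin
    acc = np.zeros((size, size), dtype=np.float64)
    cov = np.zeros((size, size), dtype=np.int64)
    for (x, y), ak in zip(bag.instance_origins, a):
        rx, ry = x - ox, y - oy
        if accumulate == "mean":
            acc[ry : ry + t, rx : rx + t] += ak
        else:
            np.maximum(acc[ry : ry + t, rx : rx + t], ak,
                       out=acc[ry : ry + t, rx : rx + t])
        cov[ry : ry + t, rx : rx + t] += 1
    if accumulate == "mean":
        raw = np.where(cov > 0, acc / np.maximum(cov, 1), 0.0)
    else:
        raw = acc
    lo, hi = raw.min(), raw.max()
    grid = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    return AttentionMap(bag_id=bag.bag_id, grid=grid, raw=raw, coverage=cov)


def _draw_tb_outlines(img: Image.Image, annotations: AnnotationSet | None,
                      roi_origin: tuple[int, int], point_radius: int) -> None:
    if annotations is None:
        return
    draw = ImageDraw.Draw(img)
    ox, oy = roi_origin
    for region in annotations.by_label("tumor_bud"):
        geom = region.geometry
        if geom.geom_type == "Point":
            x, y = geom.x - ox, geom.y - oy
            r = point_radius
            draw.ellipse([x - r, y - r, x + r, y + r], outline=(0, 255, 0), width=2)
        else:
            coords = [(px - ox, py - oy) for px, py in geom.exterior.coords]
            draw.line(coords + [coords[0]], fill=(0, 255, 0), width=2)


def overlay(
    amap: AttentionMap,
    image: np.ndarray,
    annotations: AnnotationSet | None = None,
    roi_origin: tuple[int, int] = (0, 0),
    alpha: float = 0.4,
    cmap: str = "jet",
    point_radius: int = 8,
) -> np.ndarray:
    """Alpha-blend the colormapped attention over the ROI image and outline
    tumor-bud annotations in green.  Deterministic for identical inputs."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps

    image = np.asarray(image)
    if image.shape[:2] != amap.grid.shape:
        raise ValueError(
            f"image {image.shape[:2]} does not match attention map {amap.grid.shape}"
        )
    colors = (colormaps[cmap](amap.grid)[:, :, :3] * 255).astype(np.float64)
    blended = ((1.0 - alpha) * image.astype(np.float64) + alpha * colors).round()
    out = Image.fromarray(blended.clip(0, 255).astype(np.uint8))
    _draw_tb_outlines(out, annotations, roi_origin, point_radius)
    return np.asarray(out)


def _rasterize_tb(annotations: AnnotationSet, shape: tuple[int, int],
                  roi_origin: tuple[int, int], point_radius: int) -> list[np.ndarray]:
    """One boolean mask per tumor-bud annotation, in ROI-local pixels."""
    ox, oy = roi_origin
    masks = []
    for region in annotations.by_label("tumor_bud"):
        geom = region.geometry
        img = Image.new("1", (shape[1], shape[0]), 0)
        draw = ImageDraw.Draw(img)
        if geom.geom_type == "Point":
            x, y, r = geom.x - ox, geom.y - oy, point_radius
            draw.ellipse([x - r, y - r, x + r, y + r], fill=1)
        else:
            coords = [(px - ox, py - oy) for px, py in geom.exterior.coords]
            draw.polygon(coords, fill=1)
        mask = np.asarray(img, dtype=bool)
        if mask.any():
            masks.append(mask)
    return masks


def score_regions(
    amap: AttentionMap,
    annotations: AnnotationSet,
    attn_threshold: float = 0.5,
    min_overlap: float = 0.25,
    roi_origin: tuple[int, int] = (0, 0),
    point_radius: int = 8,
) -> RegionScore:
    """Score heatmap-annotation agreement as TP/FP/FN region counts.

    The display grid is thresholded at ``attn_threshold`` and split into
    8-connected components.  An annotated bud is a TP when a single component
    covers at least ``min_overlap`` of its area, otherwise an FN; a component
    overlapping no bud pixel at all is an FP.  Point annotations are scored
    on a disc of ``point_radius`` pixels.
    """
    if not (0.0 < attn_threshold < 1.0):
        raise ValueError(f"attn_threshold must be in (0,1), got {attn_threshold}")
    if not (0.0 < min_overlap <= 1.0):
        raise ValueError(f"min_overlap must be in (0,1], got {min_overlap}")
    hot = amap.grid >= attn_threshold
    labeled, n_comp = ndimage.label(hot, structure=_EIGHT_CONN)
    components = [labeled == i for i in range(1, n_comp + 1)]
    tb_masks = _rasterize_tb(annotations, amap.grid.shape, roi_origin, point_radius)

    tp = fn = 0
    for mask in tb_masks:
        area = mask.sum()
        hit = any((comp & mask).sum() >= min_overlap * area for comp in components)
        tp += hit
        fn += not hit
    fp = sum(
        1
        for comp in components
        if not any((comp & mask).any() for mask in tb_masks)
    )
    return RegionScore(tp=tp, fp=fp, fn=fn, detected_regions=components)


__all__ = [
    "AttentionMap",
    "RegionScore",
    "attention_to_map",
    "overlay",
    "score_regions",
]
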