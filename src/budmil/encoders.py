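"""Per-instance embedding via a pluggable encoder interface.

Four histopathology foundation models are registered as metadata only
(backbone, parameter count, training paradigm); their inference runs through
optional plugins discovered by entry-point name, since the package never
ships or downloads pretrained weights.  A deterministic handcrafted "toy"
encoder (colour histograms + moments + gradient energy, 32 dims) makes the
whole pipeline runnable offline and is what the test-suite uses.

All encoders are frozen feature extractors: ``embed_bag`` is a pure function
of its inputs and encoder weights are never updated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np


class UnknownEncoderError(KeyError):
    """Raised when a name is looked up that is not in the registry."""


@dataclass(frozen=True)
class EncoderInfo:
    """Static metadata for one feature-extractor model."""

    name: str
    operation_type: str  # "CNN-SA" | "SA" | "handcrafted"
    backbone: str
    param_count_m: float  # millions of parameters
    training_paradigm: str
    embed_dim: int | None = None  # None: determined by the loaded plugin

    def __post_init__(self) -> None:
        if self.embed_dim is not None and self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")


#: Foundation-model registry.  Published figures for the four models compared
#: as tumor-bud feature extractors, plus the offline toy encoder.  CHIEF's
#: CLIP text tower (~63 M parameters) is metadata only; the vision encoder is
#: the CTransPath SwinT backbone.
REGISTRY: dict[str, EncoderInfo] = {
    info.name: info
    for info in [
        EncoderInfo("CTransPath", "CNN-SA", "SwinT", 27.5, "MoCO-v3"),
        EncoderInfo("Phikon-v2", "SA", "ViT-L", 307.0, "DINOv2"),
        EncoderInfo("CHIEF", "CNN-SA", "SwinT", 27.5, "Multiple"),
        EncoderInfo("UNI", "SA", "ViT-L", 307.0, "DINOv2"),
        EncoderInfo("toy", "handcrafted", "histogram+moments", 0.0, "none", embed_dim=32),
    ]
}


def registry_lookup(name: str) -> EncoderInfo:
    """Return encoder metadata by exact name."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise UnknownEncoderError(
            f"unknown encoder {name!r}; registered encoders: {sorted(REGISTRY)}"
        ) from None


@dataclass
class EmbeddingMatrix:
    """K x D matrix of instance embeddings h_k for one bag."""

    bag_id: str
    H: np.ndarray
    encoder_name: str
    label: int | None = None  # 1 positive, 0 negative, None unknown

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2:
            raise ValueError(f"H must be K x D, got shape {self.H.shape}")
        if not np.all(np.isfinite(self.H)):
            raise ValueError(f"bag {self.bag_id!r}: non-finite embedding entries")

    @property
    def K(self) -> int:
        return self.H.shape[0]

    @property
    def D(self) -> int:
        return self.H.shape[1]


# ---------------------------------------------------------------------------
# Toy encoder

TOY_DIM = 32
_HIST_BINS = 8


def toy_encode(tile: np.ndarray) -> np.ndarray:
    """Handcrafted 32-dim feature vector of one RGB tile, each entry in [0,1].

    Layout: per-channel 8-bin intensity histograms (24, normalised to sum 1
    per channel), per-channel mean (3) and variance scaled by 4 (3, since the
    variance of values in [0,1] is at most 1/4), then mean absolute
    horizontal and vertical gradient over all channels (2).
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB tile, got shape {tile.shape}")
    x = tile.astype(np.float64) / 255.0
    feats = np.empty(TOY_DIM)
    n_px = x.shape[0] * x.shape[1]
    for c in range(3):
        hist, _ = np.histogram(x[:, :, c], bins=_HIST_BINS, range=(0.0, 1.0))
        feats[c * _HIST_BINS : (c + 1) * _HIST_BINS] = hist / n_px
    feats[24:27] = x.mean(axis=(0, 1))
    feats[27:30] = np.minimum(4.0 * x.var(axis=(0, 1)), 1.0)
    feats[30] = np.abs(np.diff(x, axis=1)).mean() if x.shape[1] > 1 else 0.0
    feats[31] = np.abs(np.diff(x, axis=0)).mean() if x.shape[0] > 1 else 0.0
    return feats


class ToyEncoder:
    """Deterministic offline encoder applying :func:`toy_encode` per tile."""

    name = "toy"
    embed_dim = TOY_DIM

    def __call__(self, tiles: list[np.ndarray]) -> np.ndarray:
        return np.stack([toy_encode(t) for t in tiles], axis=0)


def load_encoder(name: str):
    """Load an encoder handle by registry name.

    The toy encoder is always available.  Foundation models resolve through
    the ``budmil.encoders`` entry-point group; a missing plugin produces an
    actionable error rather than a silent fallback.
    """
    info = registry_lookup(name)
    if info.name == "toy":
        return ToyEncoder()
    from importlib.metadata import entry_points

    eps = entry_points(group="budmil.encoders")
    for ep in eps:
        if ep.name.lower() == name.lower():
            return ep.load()()
    raise RuntimeError(
        f"encoder {name!r} requires the external plugin entry point "
        f"'budmil.encoders:{name.lower()}' providing the pretrained weights; "
        f"install the plugin package or use the offline 'toy' encoder"
    )


def resize_tiles(tiles: list[np.ndarray], size: int) -> list[np.ndarray]:
    """Bilinearly resize RGB tiles to ``size`` x ``size`` pixels.

    Optional preprocessing for encoder plugins trained at a different
    magnification than the 96-px native tiles; off by default everywhere.
    """
    from PIL import Image

    return [
        np.asarray(Image.fromarray(t).resize((size, size), Image.BILINEAR))
        for t in tiles
    ]


def embed_bag(tiles: list[np.ndarray], encoder, bag_id: str = "",
              label: int | None = None, resize_to: int | None = None) -> EmbeddingMatrix:
    """Embed a bag of tiles, one row per tile in input order.

    All tiles must share a shape; the encoder is applied frozen.
    ``resize_to`` optionally rescales tiles first (see :func:`resize_tiles`).
    """
    if not tiles:
        raise ValueError("cannot embed an empty bag")
    shapes = {t.shape for t in tiles}
    if len(shapes) > 1:
        raise ValueError(f"tiles have mismatched shapes: {sorted(shapes)}")
    if resize_to is not None:
        tiles = resize_tiles(tiles, resize_to)
    H = np.asarray(encoder(tiles), dtype=np.float64)
    if H.shape[0] != len(tiles):
        raise ValueError(
            f"encoder returned {H.shape[0]} rows for {len(tiles)} tiles"
        )
    return EmbeddingMatrix(
        bag_id=bag_id, H=H, encoder_name=getattr(encoder, "name", "unknown"), label=label
    )


# ---------------------------------------------------------------------------
# HDF5 persistence: one group per bag, dataset "H", attrs label/encoder.


def save_embeddings(path: str | Path, bags: list[EmbeddingMatrix]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "budmil-embeddings-v1"
        for bag in bags:
            grp = f.create_group(bag.bag_id)
            grp.create_dataset("H", data=bag.H)
            grp.attrs["encoder_name"] = bag.encoder_name
            if bag.label is not None:
                grp.attrs["label"] = int(bag.label)


def load_embeddings(path: str | Path) -> list[EmbeddingMatrix]:
    bags = []
    with h5py.File(path, "r") as f:
        for bag_id in sorted(f.keys()):
            grp = f[bag_id]
            label = int(grp.attrs["label"]) if "label" in grp.attrs else None
            bags.append(
                EmbeddingMatrix(
                    bag_id=bag_id,
                    H=grp["H"][()],
                    encoder_name=str(grp.attrs.get("encoder_name", "unknown")),
                    label=label,
                )
            )
    return bags


__all__ = [
    "REGISTRY",
    "TOY_DIM",
    "EmbeddingMatrix",
    "EncoderInfo",
    "ToyEncoder",
    "UnknownEncoderError",
    "embed_bag",
    "load_embeddings",
    "load_encoder",
    "registry_lookup",
    "save_embeddings",
    "toy_encode",
]
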