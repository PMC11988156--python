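import numpy as np
import pytest

from budmil import AnnotationSet, Region, slide_from_array
from budmil.slide_io import Point, Polygon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_slide():
    """Uniform white 2048x2048 in-memory slide."""
    img = np.full((2048, 2048, 3), 255, dtype=np.uint8)
    return slide_from_array("white", img)


@pytest.fixture
def gradient_slide():
    """Slide with per-pixel-distinct values so crops are position-sensitive."""
    h = w = 512
    base = (np.arange(h)[:, None] * w + np.arange(w)[None, :]) % 251
    img = np.stack([base, (base * 7) % 251, (base * 13) % 251], axis=-1).astype(np.uint8)
    return slide_from_array("grad", img)


def make_annotations(slide_id="s", tb_points=(), non_tumor_boxes=()):
    regions = [Region("tumor_bud", Point(x, y)) for x, y in tb_points]
    regions += [
        Region("non_tumor", Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]))
        for x0, y0, x1, y1 in non_tumor_boxes
    ]
    return AnnotationSet(slide_id=slide_id, regions=regions)
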