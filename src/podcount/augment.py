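"""Training-time augmentation: background-height crop, 4-image Mosaic, MixUp.

Each training iteration takes exactly one of two mutually exclusive branches:
with probability ``p_crop`` (0.4) the sample's empty top/bottom background
strips are randomly cropped away; otherwise (0.6) four randomly scaled
samples are tiled into a Mosaic, which is then blended 50/50 with a fifth
sample with probability ``p_mixup`` (0.5). Box labels follow every geometric
transform; MixUp pools the two box lists unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from .boxes import Box

__all__ = [
    "AugmentSample",
    "AugmentConfig",
    "random_height_crop",
    "mosaic4",
    "mixup",
    "augment_pipeline",
    "resize_sample",
]

# a box clipped by the mosaic canvas is kept only if it retains this much area
MIN_VISIBLE_FRACTION = 0.2
# rows kept above/below the tight vertical span of the boxes when cropping
CROP_MARGIN = 2
# with no boxes to constrain it, a crop never goes below this height fraction
MIN_HEIGHT_FRACTION = 0.5


@dataclass
class AugmentSample:
    image: np.ndarray  # H x W x 3 uint8
    boxes: list[Box] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def height(self) -> int:
        return int(self.image.shape[0])

    @property
    def width(self) -> int:
        return int(self.image.shape[1])

    def validate(self) -> None:
        for b in self.boxes:
            if not (0 <= b.x_min < b.x_max <= self.width):
                raise ValueError(f"box {b} outside image width {self.width}")
            if not (0 <= b.y_min < b.y_max <= self.height):
                raise ValueError(f"box {b} outside image height {self.height}")


@dataclass(frozen=True)
class AugmentConfig:
    p_crop: float = 0.4
    p_mosaic: float = 0.6
    p_mixup: float = 0.5
    target_size: int = 1024
    scale_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        for p in (self.p_crop, self.p_mosaic, self.p_mixup):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_crop + self.p_mosaic - 1.0) > 1e-9:
            raise ValueError("p_crop and p_mosaic must sum to 1 (exclusive branches)")


def _resize_image(img: np.ndarray, w: int, h: int) -> np.ndarray:
    return np.asarray(Image.fromarray(img).resize((w, h), Image.BILINEAR))


def resize_sample(sample: AugmentSample, w: int, h: int) -> AugmentSample:
    """Resize image and boxes to exactly (w, h); aspect is not preserved."""
    sx, sy = w / sample.width, h / sample.height
    return AugmentSample(
        image=_resize_image(sample.image, w, h),
        boxes=[b.scaled(sx, sy) for b in sample.boxes],
        provenance=sample.provenance + [f"resize({w}x{h})"],
    )


def random_height_crop(sample: AugmentSample, rng: np.random.Generator) -> AugmentSample:
    """Randomly remove background rows above and below the objects.

    Only rows strictly outside the tight vertical span of all boxes (plus a
    small margin) are candidates, so the crop never removes or truncates a
    box and the object count is invariant. With no boxes the crop is bounded
    by a minimum height fraction instead.
    """
    H = sample.height
    if sample.boxes:
        top_limit = int(np.floor(min(b.y_min for b in sample.boxes))) - CROP_MARGIN
        bottom_limit = int(np.ceil(max(b.y_max for b in sample.boxes))) + CROP_MARGIN
        top_limit = max(top_limit, 0)
        bottom_limit = min(bottom_limit, H)
    else:
        spare = H - int(H * MIN_HEIGHT_FRACTION)
        top_limit, bottom_limit = spare // 2, H - (spare - spare // 2)
    crop_top = int(rng.integers(0, top_limit + 1)) if top_limit > 0 else 0
    max_bottom = H - bottom_limit
    crop_bottom = int(rng.integers(0, max_bottom + 1)) if max_bottom > 0 else 0
    if crop_top == 0 and crop_bottom == 0:
        return AugmentSample(sample.image, list(sample.boxes), sample.provenance + ["crop(0,0)"])
    out = AugmentSample(
        image=sample.image[crop_top : H - crop_bottom],
        boxes=[b.shifted(0.0, -crop_top) for b in sample.boxes],
        provenance=sample.provenance + [f"crop({crop_top},{crop_bottom})"],
    )
    out.validate()
    return out


def mosaic4(
    samples: Sequence[AugmentSample],
    rng: np.random.Generator,
    target_size: int,
    scale_range: tuple[float, float] = (0.5, 1.5),
) -> AugmentSample:
    """Tile four randomly scaled samples 2x2 around a random centre.

    The working canvas is twice ``target_size``; boxes follow each tile's
    scale-and-shift, get clipped to the canvas, and are dropped when less
    than ``MIN_VISIBLE_FRACTION`` of their area survives. The canvas is then
    resized down to ``target_size``.
    """
    if len(samples) != 4:
        raise ValueError(f"mosaic4 needs exactly 4 samples, got {len(samples)}")
    S = target_size
    canvas = np.full((2 * S, 2 * S, 3), 114, dtype=np.uint8)
    cx = int(rng.uniform(0.5 * S, 1.5 * S))
    cy = int(rng.uniform(0.5 * S, 1.5 * S))
    boxes: list[Box] = []
    for idx, sample in enumerate(samples):
        scale = rng.uniform(*scale_range) * S / max(sample.width, sample.height)
        w = max(int(round(sample.width * scale)), 1)
        h = max(int(round(sample.height * scale)), 1)
        img = _resize_image(sample.image, w, h)
        # tiles anchor at the centre: TL ends at (cx,cy), TR starts at cx, ...
        if idx == 0:
            x0, y0 = cx - w, cy - h
        elif idx == 1:
            x0, y0 = cx, cy - h
        elif idx == 2:
            x0, y0 = cx - w, cy
        else:
            x0, y0 = cx, cy
        sx0, sy0 = max(0, -x0), max(0, -y0)
        sx1 = min(w, 2 * S - x0)
        sy1 = min(h, 2 * S - y0)
        if sx1 <= sx0 or sy1 <= sy0:
            continue
        canvas[y0 + sy0 : y0 + sy1, x0 + sx0 : x0 + sx1] = img[sy0:sy1, sx0:sx1]
        for b in sample.boxes:
            moved = b.scaled(w / sample.width, h / sample.height).shifted(x0, y0)
            clipped = moved.clipped(2 * S, 2 * S)
            # also clip to the visible part of this tile
            if clipped is not None:
                tile = Box(x0 + sx0, y0 + sy0, x0 + sx1, y0 + sy1)
                clipped = clipped.clipped(tile.x_max, tile.y_max)
            if clipped is not None and clipped.area >= MIN_VISIBLE_FRACTION * moved.area:
                boxes.append(clipped)
    out = AugmentSample(
        image=canvas,
        boxes=boxes,
        provenance=[f"mosaic(c=({cx},{cy}))"],
    )
    return resize_sample(out, S, S)


def mixup(a: AugmentSample, b: AugmentSample, rng: np.random.Generator) -> AugmentSample:
    """Blend two equal-sized samples 50/50 and pool their box lists."""
    if a.image.shape != b.image.shape:
        raise ValueError(f"mixup dimension mismatch: {a.image.shape} vs {b.image.shape}")
    blended = ((a.image.astype(np.float32) + b.image.astype(np.float32)) / 2.0).astype(np.uint8)
    return AugmentSample(
        image=blended,
        boxes=list(a.boxes) + list(b.boxes),
        provenance=a.provenance + b.provenance + ["mixup"],
    )


def augment_pipeline(
    sample_source: Callable[[], AugmentSample],
    config: AugmentConfig,
    rng: np.random.Generator,
) -> AugmentSample:
    """Draw one augmented training sample.

    Branch selection: crop with probability ``p_crop``, else Mosaic; after a
    Mosaic, MixUp with a freshly drawn fifth sample is applied with
    probability ``p_mixup``.
    """
    if rng.random() < config.p_crop:
        out = random_height_crop(sample_source(), rng)
        out.provenance.append("branch=crop")
        return out
    tiles = [sample_source() for _ in range(4)]
    out = mosaic4(tiles, rng, config.target_size, config.scale_range)
    if rng.random() < config.p_mixup:
        extra = resize_sample(sample_source(), config.target_size, config.target_size)
        out = mixup(out, extra, rng)
        out.provenance.append("branch=mosaic+mixup")
    else:
        out.provenance.append("branch=mosaic")
    return out
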