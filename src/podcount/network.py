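"""The pod-counting detector.

Anchor-free single-class detector in the YOLOX-L mould: a CSP backbone with
spatial-pyramid pooling, a PAN feature-fusion neck, and three decoupled
heads at strides 8/16/32. On top of the stock design this model

* replaces the Focus (pixel-unshuffle) stem with a single k=6, s=2
  convolution of identical output geometry and cost,
* replaces parallel-kernel SPP {5, 9, 13} with the sequential SPPF
  (three chained k=5 poolings — identical pre-projection by max nesting),
* inserts a CBAM attention block (channel then spatial) after each head's
  stem convolution, and
* wires a train-time-only count head: per scale, a decoupled branch of two
  3x3 convolutions followed by 1x1 channel compression; the three maps are
  flattened, concatenated, and fused by fully-connected layers into 300
  count-class logits (counts 0..299). The branch is absent from the
  inference graph, so it costs nothing at deployment.

``count_parameters`` and ``count_flops`` provide the architecture
accounting. FLOPs are counted by tracing an actual forward pass:
2 FLOPs per multiply-accumulate in convolutions and linear layers, 1 FLOP
per element for sigmoid/SiLU activations, batch-norm folded into its
convolution, and pooling/upsampling/concatenation free.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import autograd as ag
from .autograd import (
    Tensor,
    _stable_sigmoid,
    concat,
    max_pool_same,
    space_to_depth2,
    upsample_nearest2x,
)
from .boxes import Box, greedy_nms
from .layers import BatchNorm2d, Conv2d, Linear, Module, Sequential

__all__ = [
    "ModelConfig",
    "PodDetector",
    "build_model",
    "build_baseline_coco",
    "count_parameters",
    "count_flops",
    "decode_predictions",
    "sppf_forward",
    "spp_forward",
    "CBAM",
]

COUNT_CLASSES = 300


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters. Defaults give the full "L" size model."""

    depth_multiplier: float = 1.0
    width_multiplier: float = 1.0
    num_classes: int = 1
    strides: tuple[int, int, int] = (8, 16, 32)
    count_classes: int = COUNT_CLASSES
    input_resolution: int = 1024
    mode: str = "training"  # training | inference
    cbam_reduction: int = 16
    number_head_hidden: int = 956
    stem: str = "conv"  # conv (k6 s2) | focus
    spp_variant: str = "sppf"  # sppf | spp
    use_cbam: bool = True
    conf_threshold: float = 0.25
    nms_iou: float = 0.65
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.strides != (8, 16, 32):
            raise ValueError("strides are fixed at (8, 16, 32)")
        if self.count_classes != COUNT_CLASSES:
            raise ValueError(f"count_classes is fixed at {COUNT_CLASSES}")
        if self.mode not in ("training", "inference"):
            raise ValueError("mode must be 'training' or 'inference'")
        if self.depth_multiplier <= 0 or self.width_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if self.input_resolution % 32 != 0:
            raise ValueError("input_resolution must be divisible by 32")


class _Rng:
    """Deterministic per-layer init streams derived from one seed."""

    def __init__(self, seed: int):
        self._seq = np.random.SeedSequence(seed)
        self._count = 0

    def next(self) -> np.random.Generator:
        self._count += 1
        return np.random.default_rng(
            np.random.SeedSequence([int(self._seq.entropy) % (2**31), self._count])
        )


class BaseConv(Module):
    """Conv (no bias) + BatchNorm + SiLU."""

    def __init__(self, cin: int, cout: int, k: int, s: int, rng: _Rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, s, bias=False, rng=rng.next())
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class Bottleneck(Module):
    def __init__(self, c: int, shortcut: bool, rng: _Rng):
        super().__init__()
        self.conv1 = BaseConv(c, c, 1, 1, rng)
        self.conv2 = BaseConv(c, c, 3, 1, rng)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x))
        return x + y if self.shortcut else y


class CSPLayer(Module):
    """Cross-stage-partial block: split, bottleneck stack, merge."""

    def __init__(self, cin: int, cout: int, n: int, shortcut: bool, rng: _Rng):
        super().__init__()
        hidden = cout // 2
        self.conv1 = BaseConv(cin, hidden, 1, 1, rng)
        self.conv2 = BaseConv(cin, hidden, 1, 1, rng)
        self.blocks = Sequential(*[Bottleneck(hidden, shortcut, rng) for _ in range(n)])
        self.conv3 = BaseConv(2 * hidden, cout, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        a = self.blocks(self.conv1(x))
        b = self.conv2(x)
        return self.conv3(concat([a, b], axis=1))


def sppf_forward(x: Tensor) -> tuple[Tensor, ...]:
    """Three chained k=5 same-size max poolings (the fast pyramid)."""
    y1 = max_pool_same(x, 5)
    y2 = max_pool_same(y1, 5)
    y3 = max_pool_same(y2, 5)
    return x, y1, y2, y3


def spp_forward(x: Tensor) -> tuple[Tensor, ...]:
    """Parallel max poolings with kernels 5/9/13 (the classic pyramid)."""
    return x, max_pool_same(x, 5), max_pool_same(x, 9), max_pool_same(x, 13)


class SPPBlock(Module):
    """Pyramid pooling bottleneck; ``variant`` picks spp or sppf pooling.

    The two variants are exactly equivalent before the projection conv
    because chained k=5 max poolings reproduce k=9 and k=13 windows.
    """

    def __init__(self, cin: int, cout: int, variant: str, rng: _Rng):
        super().__init__()
        hidden = cin // 2
        self.conv1 = BaseConv(cin, hidden, 1, 1, rng)
        self.conv2 = BaseConv(hidden * 4, cout, 1, 1, rng)
        self.variant = variant

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        pooled = sppf_forward(h) if self.variant == "sppf" else spp_forward(h)
        return self.conv2(concat(pooled, axis=1))


class Focus(Module):
    """Pixel-unshuffle stem: space-to-depth 2x then a 3x3 conv."""

    def __init__(self, cin: int, cout: int, rng: _Rng):
        super().__init__()
        self.conv = BaseConv(cin * 4, cout, 3, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(space_to_depth2(x))


class CSPDarknet(Module):
    def __init__(self, cfg: ModelConfig, rng: _Rng):
        super().__init__()
        w, d = cfg.width_multiplier, cfg.depth_multiplier
        base = int(64 * w)
        depth = max(round(3 * d), 1)
        self.channels = (base * 2, base * 4, base * 8, base * 16)
        if cfg.stem == "focus":
            self.stem = Focus(3, base, rng)
        else:
            self.stem = _ConvStem(base, rng)
        c2, c3, c4, c5 = self.channels
        self.dark2 = Sequential(BaseConv(base, c2, 3, 2, rng), CSPLayer(c2, c2, depth, True, rng))
        self.dark3 = Sequential(BaseConv(c2, c3, 3, 2, rng), CSPLayer(c3, c3, depth * 3, True, rng))
        self.dark4 = Sequential(BaseConv(c3, c4, 3, 2, rng), CSPLayer(c4, c4, depth * 3, True, rng))
        self.dark5 = Sequential(
            BaseConv(c4, c5, 3, 2, rng),
            SPPBlock(c5, c5, cfg.spp_variant, rng),
            CSPLayer(c5, c5, depth, False, rng),
        )

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        x = self.stem(x)
        x = self.dark2(x)
        p3 = self.dark3(x)
        p4 = self.dark4(p3)
        p5 = self.dark5(p4)
        return p3, p4, p5


class _ConvStem(Module):
    """k=6, s=2 strided-conv stem, geometry-equivalent to the Focus block."""

    def __init__(self, cout: int, rng: _Rng):
        super().__init__()
        self.conv = Conv2d(3, cout, 6, 2, padding=2, bias=False, rng=rng.next())
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class PAFPN(Module):
    """Path-aggregation neck over the three backbone scales."""

    def __init__(self, cfg: ModelConfig, rng: _Rng):
        super().__init__()
        w, d = cfg.width_multiplier, cfg.depth_multiplier
        depth = max(round(3 * d), 1)
        c3, c4, c5 = int(256 * w), int(512 * w), int(1024 * w)
        self.out_channels = (c3, c4, c5)
        self.lateral5 = BaseConv(c5, c4, 1, 1, rng)
        self.csp_p4 = CSPLayer(2 * c4, c4, depth, False, rng)
        self.lateral4 = BaseConv(c4, c3, 1, 1, rng)
        self.csp_p3 = CSPLayer(2 * c3, c3, depth, False, rng)
        self.down3 = BaseConv(c3, c3, 3, 2, rng)
        self.csp_n3 = CSPLayer(2 * c3, c4, depth, False, rng)
        self.down4 = BaseConv(c4, c4, 3, 2, rng)
        self.csp_n4 = CSPLayer(2 * c4, c5, depth, False, rng)

    def forward(self, feats: tuple[Tensor, Tensor, Tensor]):
        p3, p4, p5 = feats
        l5 = self.lateral5(p5)
        m4 = self.csp_p4(concat([upsample_nearest2x(l5), p4], axis=1))
        l4 = self.lateral4(m4)
        o3 = self.csp_p3(concat([upsample_nearest2x(l4), p3], axis=1))
        o4 = self.csp_n3(concat([self.down3(o3), l4], axis=1))
        o5 = self.csp_n4(concat([self.down4(o4), l5], axis=1))
        return o3, o4, o5


class CBAM(Module):
    """Convolutional Block Attention: channel then spatial gating.

    Channel weights come from a shared two-layer MLP applied to global
    average- and max-pooled descriptors; spatial weights from a 7x7 conv
    over the channel-wise mean and max maps. Both gates are sigmoids, so
    every attention weight lies in (0, 1).
    """

    def __init__(self, channels: int, reduction: int, rng: _Rng):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError("channels must be divisible by cbam_reduction")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng=rng.next())
        self.fc2 = Linear(hidden, channels, rng=rng.next())
        self.spatial = Conv2d(2, 1, 7, 1, bias=True, rng=rng.next())
        self.channels = channels

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        ch_att = (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(n, c, 1, 1)
        x = x * ch_att
        sp_mean = x.mean(axis=1, keepdims=True)
        sp_max = x.max(axis=1, keepdims=True)
        sp_att = self.spatial(concat([sp_mean, sp_max], axis=1)).sigmoid()
        return x * sp_att


class DetectionHead(Module):
    """Per-scale decoupled head: stem, optional CBAM, cls / reg+IoU stacks."""

    def __init__(self, cin: int, head_ch: int, num_classes: int, cfg: ModelConfig, rng: _Rng):
        super().__init__()
        self.stem = BaseConv(cin, head_ch, 1, 1, rng)
        self.cbam = CBAM(head_ch, cfg.cbam_reduction, rng) if cfg.use_cbam else None
        self.cls_convs = Sequential(
            BaseConv(head_ch, head_ch, 3, 1, rng), BaseConv(head_ch, head_ch, 3, 1, rng)
        )
        self.reg_convs = Sequential(
            BaseConv(head_ch, head_ch, 3, 1, rng), BaseConv(head_ch, head_ch, 3, 1, rng)
        )
        self.cls_pred = Conv2d(head_ch, num_classes, 1, 1, bias=True, rng=rng.next())
        self.reg_pred = Conv2d(head_ch, 4, 1, 1, bias=True, rng=rng.next())
        self.obj_pred = Conv2d(head_ch, 1, 1, 1, bias=True, rng=rng.next())
        # objectness starts at a low prior so early training is not swamped
        # by false positives
        self.obj_pred.bias.data[:] = -4.0
        self.cls_pred.bias.data[:] = -2.0

    def shared(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        if self.cbam is not None:
            x = self.cbam(x)
        return x

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        x = self.shared(x)
        c = self.cls_convs(x)
        r = self.reg_convs(x)
        return {
            "cls": self.cls_pred(c),
            "reg": self.reg_pred(r),
            "obj": self.obj_pred(r),
            "shared": x,
        }


class NumberHead(Module):
    """Train-time count branch ("Number Prediction Module").

    Decoupled from classification/localization: its own two-conv stack per
    scale, 1x1 compression to a single channel, flatten + concatenation
    across scales, then fully-connected fusion into 300 count logits. The
    final layer is zero-initialized so the initial count distribution is
    uniform.
    """

    def __init__(self, head_ch: int, flat_elems: int, hidden: int, rng: _Rng):
        super().__init__()
        self.branches = Sequential(
            *[
                Sequential(
                    BaseConv(head_ch, head_ch, 3, 1, rng),
                    BaseConv(head_ch, head_ch, 3, 1, rng),
                    Conv2d(head_ch, 1, 1, 1, bias=True, rng=rng.next()),
                )
                for _ in range(3)
            ]
        )
        self.fuse1 = Linear(flat_elems, hidden, rng=rng.next())
        self.fuse2 = Linear(hidden, COUNT_CLASSES, rng=rng.next(), zero_init=True)
        self.flat_elems = flat_elems

    def forward(self, feats: list[Tensor]) -> Tensor:
        flats = []
        for branch, f in zip(self.branches, feats):
            flats.append(branch(f).flatten_from(1))
        flat = concat(flats, axis=1)
        if flat.shape[1] != self.flat_elems:
            raise ValueError(
                f"count head was built for {self.flat_elems} flattened elements, "
                f"got {flat.shape[1]}; input resolution mismatch"
            )
        return self.fuse2(self.fuse1(flat).silu())


class PodDetector(Module):
    """Full model; ``config.mode`` decides whether the count head exists."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = _Rng(config.init_seed)
        self.backbone = CSPDarknet(config, rng)
        self.neck = PAFPN(config, rng)
        head_ch = int(256 * config.width_multiplier)
        self.head_ch = head_ch
        heads = [
            DetectionHead(cin, head_ch, config.num_classes, config, rng)
            for cin in self.neck.out_channels
        ]
        self.heads = Sequential(*heads)
        if config.mode == "training":
            res = config.input_resolution
            flat = sum((res // s) ** 2 for s in config.strides)
            self.number_head = NumberHead(head_ch, flat, config.number_head_hidden, rng)
        else:
            self.number_head = None

    def forward(self, x: Tensor, with_count: Optional[bool] = None) -> dict:
        """Run the detector; returns per-scale raw maps and count logits.

        ``with_count`` defaults to True exactly when the model was built in
        training mode. Requesting count logits on an inference-mode model is
        an error: the count head is not part of that graph.
        """
        if with_count is None:
            with_count = self.number_head is not None
        if with_count and self.number_head is None:
            raise RuntimeError("count head requested but model is in inference mode")
        feats = self.neck(self.backbone(x))
        scales = []
        shared = []
        for head, f in zip(self.heads, feats):
            out = head(f)
            shared.append(out.pop("shared"))
            scales.append(out)
        result = {"scales": scales, "count_logits": None}
        if with_count:
            result["count_logits"] = self.number_head(shared)
        return result

    def detection_parameters(self) -> list:
        """Everything except the count head (useful for freeze logic)."""
        ps = list(self.backbone.parameters()) + list(self.neck.parameters())
        ps += list(self.heads.parameters())
        return ps

    def head_parameters(self) -> list:
        """Head-stage trainable set: detection heads, CBAM, count head."""
        ps = list(self.heads.parameters())
        if self.number_head is not None:
            ps += list(self.number_head.parameters())
        return ps


def build_model(config: ModelConfig) -> PodDetector:
    return PodDetector(config)


def build_baseline_coco(resolution: int = 1024) -> PodDetector:
    """The unmodified reference detector: Focus stem, SPP {5,9,13}, no CBAM,
    no count head, 80-class COCO vocabulary. Used as the accounting baseline.
    """
    cfg = ModelConfig(
        num_classes=80,
        mode="inference",
        stem="focus",
        spp_variant="spp",
        use_cbam=False,
        input_resolution=resolution,
    )
    return PodDetector(cfg)


def count_parameters(model: Module) -> int:
    """Exact total number of scalar weights in the model."""
    return model.num_parameters()


def count_flops(model: PodDetector, resolution: Optional[int] = None) -> float:
    """Analytic FLOPs of one forward pass at the given square resolution.

    Counts 2 FLOPs per conv/linear multiply-accumulate and 1 FLOP per
    sigmoid/SiLU element, with batch-norm folded and pooling/upsampling
    free; measured by tracing an actual batch-1 forward pass.
    """
    res = resolution or model.config.input_resolution
    if res % 32 != 0:
        raise ValueError("resolution must be divisible by 32")
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, res, res), dtype=np.float32))
    with ag.no_grad(), ag.trace_ops() as rec:
        model.forward(x)
    if was_training:
        model.train()
    return 2.0 * rec["macs"] + 1.0 * rec["act_elems"]


def decode_predictions(
    raw: dict,
    conf_threshold: float = 0.25,
    nms_iou: float = 0.65,
    strides: tuple[int, ...] = (8, 16, 32),
    image_size: Optional[tuple[int, int]] = None,
) -> list[list[Box]]:
    """Turn raw per-scale maps into scored, NMS-filtered boxes per image.

    Anchor-free decoding: at each location, the regression map holds centre
    offsets (grid units) and log-sizes; score = sigmoid(cls) * sigmoid(obj).
    """
    if not (0 <= conf_threshold <= 1 and 0 <= nms_iou <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    scales = raw["scales"]
    n_img = scales[0]["cls"].shape[0]
    results: list[list[Box]] = []
    per_scale = []
    for s, maps in zip(strides, scales):
        reg = maps["reg"].data if isinstance(maps["reg"], Tensor) else maps["reg"]
        obj = maps["obj"].data if isinstance(maps["obj"], Tensor) else maps["obj"]
        cls = maps["cls"].data if isinstance(maps["cls"], Tensor) else maps["cls"]
        n, _, h, w = reg.shape
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx = (reg[:, 0] + gx) * s
        cy = (reg[:, 1] + gy) * s
        bw = np.exp(np.clip(reg[:, 2], -20, 10)) * s
        bh = np.exp(np.clip(reg[:, 3], -20, 10)) * s
        score = _sigmoid(obj[:, 0]) * _sigmoid(cls).max(axis=1)
        per_scale.append(
            (
                np.stack([cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2], axis=-1),
                score,
            )
        )
    for i in range(n_img):
        cands: list[Box] = []
        for boxes, score in per_scale:
            bs, ss = boxes[i].reshape(-1, 4), score[i].reshape(-1)
            keep = ss >= conf_threshold
            for (x0, y0, x1, y1), sc in zip(bs[keep], ss[keep]):
                if image_size is not None:
                    w_img, h_img = image_size
                    x0, y0 = max(x0, 0.0), max(y0, 0.0)
                    x1, y1 = min(x1, w_img), min(y1, h_img)
                if x1 - x0 > 1e-3 and y1 - y0 > 1e-3:
                    cands.append(Box(x0, y0, x1, y1, score=min(float(sc), 1.0)))
        results.append(greedy_nms(cands, nms_iou))
    return results


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return _stable_sigmoid(x)


def inference_variant(config: ModelConfig) -> ModelConfig:
    return replace(config, mode="inference")
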