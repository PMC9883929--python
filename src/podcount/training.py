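"""Two-stage training with AdamW and per-epoch exponential LR decay.

Stage 1 trains only the heads (detection branches, attention blocks, and
the count head) with the backbone and neck frozen; stage 2 fine-tunes the
whole model. Defaults mirror the published schedule: stage 1 = 5 epochs,
lr 1e-3, gamma 0.92, batch 8; stage 2 = 55 epochs, lr 1e-4, gamma 0.90,
batch 2. Every epoch visits each training image exactly once, re-drawing
the augmentation on every read.

All randomness (data order, augmentation, init) derives from one master
seed through independent named streams, so full-precision runs are
bit-reproducible and epoch-boundary checkpoints resume exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
from PIL import Image

from . import autograd as ag
from .annotations_io import DatasetIndex, ImageAnnotation, read_voc_dir
from .augment import AugmentConfig, AugmentSample, augment_pipeline, resize_sample
from .autograd import Tensor
from .boxes import Box
from .losses import (
    NumberLossInputs,
    clip_counts,
    detection_loss,
    number_loss,
    total_loss,
)
from .network import ModelConfig, PodDetector, build_model

__all__ = [
    "StageConfig",
    "TrainState",
    "ImageDataset",
    "AdamW",
    "lr_at",
    "run_stage",
    "train_full",
    "save_checkpoint",
    "load_checkpoint",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class StageConfig:
    stage_id: int
    epochs: int
    initial_lr: float
    gamma: float
    batch_size: int
    trainable_scope: str  # "heads-only" | "full-model"

    def __post_init__(self) -> None:
        if self.stage_id not in (1, 2):
            raise ValueError("stage_id must be 1 or 2")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.trainable_scope not in ("heads-only", "full-model"):
            raise ValueError("trainable_scope must be heads-only or full-model")


def default_stage1() -> StageConfig:
    return StageConfig(1, 5, 1e-3, 0.92, 8, "heads-only")


def default_stage2() -> StageConfig:
    return StageConfig(2, 55, 1e-4, 0.90, 2, "full-model")


def lr_at(stage: StageConfig, epoch_index: int) -> float:
    """Learning rate in a stage: initial_lr * gamma ** epoch_index."""
    if not 0 <= epoch_index < stage.epochs:
        raise IndexError(f"epoch {epoch_index} outside stage of {stage.epochs} epochs")
    return stage.initial_lr * stage.gamma**epoch_index


@dataclass
class TrainState:
    epoch: int = 0
    iteration: int = 0
    precision: str = "full"  # full | mixed
    loss_history: list = field(default_factory=list)
    optimizer_state: Optional[dict] = None
    seed: int = 0


class ImageDataset:
    """In-memory (image, annotation) pairs used by the training loop."""

    def __init__(self, samples: list[tuple[np.ndarray, ImageAnnotation]]):
        if not samples:
            raise ValueError("empty dataset")
        self.samples = samples

    @classmethod
    def from_directory(cls, root: PathLike) -> "ImageDataset":
        """Load a generated dataset laid out as images/ + annotations/."""
        root = Path(root)
        index = read_voc_dir(root / "annotations")
        samples = []
        for ann in index.items:
            img = np.asarray(Image.open(root / "images" / f"{ann.image_id}.png").convert("RGB"))
            samples.append((img, ann))
        return cls(samples)

    @classmethod
    def from_scenes(cls, scenes) -> "ImageDataset":
        return cls([(s.image, s.annotation) for s in scenes])

    def __len__(self) -> int:
        return len(self.samples)

    def as_augment_sample(self, i: int) -> AugmentSample:
        img, ann = self.samples[i]
        return AugmentSample(image=img, boxes=list(ann.boxes))


class AdamW:
    """AdamW with decoupled weight decay, excluded for 1-D params (bias/BN)."""

    def __init__(
        self,
        params: Sequence,
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None or not p.requires_grad:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay and p.data.ndim > 1:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]


def _clip_grad_norm(params, max_norm: float = 10.0) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _set_stage_freeze(model: PodDetector, scope: str) -> list:
    """Apply the stage's freeze policy; returns the trainable parameters."""
    if scope == "heads-only":
        model.backbone.freeze(True)
        model.neck.freeze(True)
        for p in model.head_parameters():
            p.requires_grad = True
        return model.head_parameters()
    model.backbone.freeze(False)
    model.neck.freeze(False)
    for p in model.head_parameters():
        p.requires_grad = True
    return list(model.parameters())


def _make_batch(samples: list[AugmentSample], resolution: int):
    imgs, anns = [], []
    for s in samples:
        s = resize_sample(s, resolution, resolution)
        imgs.append(s.image.astype(np.float32) / 255.0)
        boxes = [b.clipped(resolution, resolution) for b in s.boxes]
        boxes = [b for b in boxes if b is not None]
        anns.append(ImageAnnotation("batch", resolution, resolution, boxes))
    x = np.stack(imgs).transpose(0, 3, 1, 2)
    return Tensor(x), anns


def run_stage(
    model: PodDetector,
    data: Union[ImageDataset, DatasetIndex],
    stage: StageConfig,
    augment: AugmentConfig,
    seed: int,
    assigner: str = "simota",
    log_path: Optional[PathLike] = None,
    state: Optional[TrainState] = None,
    mixed_precision: bool = False,
    resolution: Optional[int] = None,
) -> TrainState:
    """Train one stage; each epoch visits every image once, augmented per read."""
    if model.config.mode != "training":
        raise ValueError("model must be built in training mode")
    if isinstance(data, DatasetIndex):
        raise TypeError(
            "run_stage needs pixel data; wrap your DatasetIndex with "
            "ImageDataset.from_directory(...)"
        )
    if len(data) == 0:
        raise ValueError("empty dataset")

    res = resolution or model.config.input_resolution
    trainable = _set_stage_freeze(model, stage.trainable_scope)
    model.train()
    opt = AdamW(trainable, lr=stage.initial_lr)
    state = state or TrainState(seed=seed)
    if state.optimizer_state is not None:
        opt.load_state(state.optimizer_state)
    state.precision = "mixed" if mixed_precision else "full"
    ag.set_mixed_precision(mixed_precision)

    log_fh = open(log_path, "a") if log_path else None
    try:
        start_epoch = state.epoch
        for epoch in range(start_epoch, stage.epochs):
            opt.lr = lr_at(stage, epoch)
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, stage.stage_id, epoch])
            )
            order = rng.permutation(len(data))
            epoch_losses = []
            batch: list[AugmentSample] = []
            for idx in order:
                primary_used = {"flag": False}

                def sampler() -> AugmentSample:
                    if not primary_used["flag"]:
                        primary_used["flag"] = True
                        return data.as_augment_sample(int(idx))
                    return data.as_augment_sample(int(rng.integers(len(data))))

                batch.append(augment_pipeline(sampler, augment, rng))
                if len(batch) < stage.batch_size and int(idx) != int(order[-1]):
                    continue
                x, anns = _make_batch(batch, res)
                batch = []
                raw = model.forward(x)
                det = detection_loss(raw, anns, model.config.strides, assigner=assigner)
                counts = clip_counts(np.array([a.count() for a in anns]))
                l_num = number_loss(NumberLossInputs(raw["count_logits"], counts))
                loss = total_loss(l_num, det["l_yolo"])
                opt.zero_grad()
                loss.backward()
                _clip_grad_norm(trainable)
                opt.step()
                state.iteration += 1
                rec = {
                    "stage": stage.stage_id,
                    "epoch": epoch,
                    "iter": state.iteration,
                    "lr": opt.lr,
                    "loss": float(loss.data),
                    "l_num": float(l_num.data),
                    "l_yolo": float(det["l_yolo"].data),
                    "iou": float(det["iou"].data),
                    "obj": float(det["obj"].data),
                    "cls": float(det["cls"].data),
                    "num_fg": det["num_fg"],
                }
                epoch_losses.append(rec["loss"])
                if log_fh:
                    log_fh.write(json.dumps(rec) + "\n")
                    log_fh.flush()
            state.epoch = epoch + 1
            state.loss_history.append(
                {"stage": stage.stage_id, "epoch": epoch, "mean_loss": float(np.mean(epoch_losses))}
            )
    finally:
        if log_fh:
            log_fh.close()
        ag.set_mixed_precision(False)
    state.optimizer_state = opt.state()
    return state


def save_checkpoint(
    model: PodDetector,
    path: PathLike,
    state: Optional[TrainState] = None,
) -> None:
    """Serialize model weights (+ optional train state) with embedded config."""
    payload = {f"model/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    if state is not None:
        meta = {
            "epoch": state.epoch,
            "iteration": state.iteration,
            "precision": state.precision,
            "seed": state.seed,
            "loss_history": state.loss_history,
        }
        payload["state_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        if state.optimizer_state is not None:
            payload["opt/t"] = np.array(state.optimizer_state["t"])
            for i, m in enumerate(state.optimizer_state["m"]):
                payload[f"opt/m{i}"] = m
            for i, v in enumerate(state.optimizer_state["v"]):
                payload[f"opt/v{i}"] = v
    np.savez(str(path), **payload)


def load_checkpoint(path: PathLike) -> tuple[PodDetector, Optional[TrainState]]:
    """Rebuild a model (and train state, if present) from a checkpoint."""
    with np.load(str(path), allow_pickle=False) as zf:
        raw_cfg = json.loads(bytes(zf["config_json"]).decode())
        # json turns tuples into lists; restore before validation
        raw_cfg["strides"] = tuple(raw_cfg["strides"])
        cfg = ModelConfig(**raw_cfg)
        model = build_model(cfg)
        model.load_state_dict(
            {k[len("model/"):]: zf[k] for k in zf.files if k.startswith("model/")}
        )
        state = None
        if "state_json" in zf.files:
            meta = json.loads(bytes(zf["state_json"]).decode())
            state = TrainState(
                epoch=meta["epoch"],
                iteration=meta["iteration"],
                precision=meta["precision"],
                seed=meta["seed"],
                loss_history=meta["loss_history"],
            )
            if "opt/t" in zf.files:
                ms = sorted(
                    (k for k in zf.files if k.startswith("opt/m")),
                    key=lambda s: int(s[5:]),
                )
                vs = sorted(
                    (k for k in zf.files if k.startswith("opt/v")),
                    key=lambda s: int(s[5:]),
                )
                state.optimizer_state = {
                    "t": int(zf["opt/t"]),
                    "m": [zf[k] for k in ms],
                    "v": [zf[k] for k in vs],
                }
    return model, state


def train_full(
    model_config: ModelConfig,
    data: ImageDataset,
    stages: tuple[StageConfig, StageConfig] = None,
    seed: int = 0,
    out_dir: PathLike = "runs",
    augment: Optional[AugmentConfig] = None,
    assigner: str = "simota",
    mixed_precision: bool = False,
    resolution: Optional[int] = None,
) -> Path:
    """Run stage 1 then stage 2; returns the final checkpoint path."""
    stages = stages or (default_stage1(), default_stage2())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    augment = augment or AugmentConfig(target_size=model_config.input_resolution)
    model = build_model(model_config)
    manifest = {
        "model_config": asdict(model_config),
        "stages": [asdict(s) for s in stages],
        "augment": asdict(augment),
        "seed": seed,
        "assigner": assigner,
        "mixed_precision": mixed_precision,
        "n_images": len(data),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    state = None
    for stage in stages:
        state = run_stage(
            model,
            data,
            stage,
            augment,
            seed,
            assigner=assigner,
            log_path=out_dir / "train_log.jsonl",
            mixed_precision=mixed_precision,
            resolution=resolution,
        )
        save_checkpoint(model, out_dir / f"stage{stage.stage_id}.npz", state)
        state.epoch = 0  # next stage starts its own epoch count
    final = out_dir / "final.npz"
    save_checkpoint(model, final, state)
    return final
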