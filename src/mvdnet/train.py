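"""Training protocol, inference, evaluation harness and checkpointing.

The optimization recipe is mini-batch SGD (batch 8, momentum 0.9,
weight decay 1e-4) under the "poly" learning-rate policy
``lr = base_lr * (1 - step/total_steps)^power`` with base 0.16 and
power 0.9, stepped per iteration; the loss is the plain mean of
per-pixel cross-entropy; training crops are 512x512 by default and the
augmentations are random horizontal flip, random Gaussian blur and
per-channel standardization.  Validation runs at full resolution with
no cropping and no multi-scale/multi-crop tricks.

One master seed fans out to the per-epoch data order and augmentation
stream, so runs are bit-reproducible and a run interrupted at an epoch
boundary resumes to identical weights.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arch import MVDNet, MVDNetSpec, build_mvdnet
from .data import AugmentationConfig, Corpus, LabelSchema, SceneSample, augment, standardize, write_mask
from .errors import InvalidInputError
from .metrics import ConfusionMatrix, EvalReport, iou_and_miou, stratified_report
from .nn import SGD

__all__ = [
    "TrainConfig",
    "TrainResult",
    "poly_lr",
    "pixel_mean_cross_entropy",
    "train",
    "evaluate",
    "predict",
    "fps_benchmark",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """The optimization recipe; defaults are the full-scale protocol."""

    batch_size: int = 8
    momentum: float = 0.9
    weight_decay: float = 1e-4
    base_lr: float = 0.16
    lr_power: float = 0.9
    epochs: int = 100
    crop: int = 512
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.crop) < 1:
            raise InvalidInputError("batch_size, epochs and crop must be positive")
        if self.base_lr <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise InvalidInputError("optimizer hyperparameters must be nonnegative")
        if not 0.0 < self.lr_power <= 1.0:
            raise InvalidInputError("lr_power must lie in (0, 1]")


def poly_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Poly learning-rate policy: ``base_lr * (1 - step/total)^power``."""
    if not 0 <= step <= total_steps:
        raise InvalidInputError(f"step {step} outside [0, {total_steps}]")
    return cfg.base_lr * (1.0 - step / total_steps) ** cfg.lr_power


def pixel_mean_cross_entropy(scores: np.ndarray, targets: np.ndarray,
                             return_grad: bool = False):
    """Mean over all pixels of the negative log softmax probability of
    the target class.  Accepts ``C x H x W`` or ``N x C x H x W`` scores.
    """
    z = np.asarray(scores, dtype=np.float64)
    t = np.asarray(targets)
    if z.ndim == 3:
        z = z[None]
        t = t[None]
    N, C, H, W = z.shape
    if t.shape != (N, H, W):
        raise InvalidInputError(f"target shape {t.shape} does not match scores")
    if t.min() < 0 or t.max() >= C:
        raise InvalidInputError(f"labels outside [0, {C})")
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - lse
    ni, yi, xi = np.meshgrid(np.arange(N), np.arange(H), np.arange(W), indexing="ij")
    picked = logp[ni, t, yi, xi]
    loss = float(-picked.mean())
    if not return_grad:
        return loss
    grad = np.exp(logp)
    grad[ni, t, yi, xi] -= 1.0
    grad /= N * H * W
    return loss, grad


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, net: MVDNet, optimizer: SGD | None = None,
                    meta: dict | None = None) -> None:
    """Framework-native serialized weights with the architecture spec
    embedded as JSON, plus optional optimizer state and run metadata."""
    arrays = {"net/" + k: v for k, v in net.state_dict().items()}
    if optimizer is not None:
        arrays.update({"opt/" + k: v for k, v in optimizer.state_dict().items()})
    header = {"spec": net.spec.to_dict(), "meta": meta or {}}
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[MVDNet, dict, dict]:
    """Rebuild the network from an embedded spec and load its weights.
    Returns ``(net, optimizer_state, meta)``."""
    with np.load(path) as zf:
        header = json.loads(bytes(zf["header"]).decode())
        net = build_mvdnet(MVDNetSpec.from_dict(header["spec"]))
        net.load_state_dict(
            {k[4:]: zf[k] for k in zf.files if k.startswith("net/")}
        )
        opt_state = {k[4:]: zf[k] for k in zf.files if k.startswith("opt/")}
    return net, opt_state, header["meta"]


# ---------------------------------------------------------------------------
# evaluation and inference
# ---------------------------------------------------------------------------

def _forward_labels(net: MVDNet, image: np.ndarray, mean, std) -> np.ndarray:
    """Standardize one H x W x 3 image, forward in eval mode, argmax."""
    x = (np.asarray(image, dtype=np.float64) - mean) / std
    x = x.transpose(2, 0, 1)[None]
    was_training = net.training
    net.eval()
    scores = net(x)
    if was_training:
        net.train()
    return np.argmax(scores[0], axis=0)


def evaluate(net: MVDNet, samples: list[SceneSample], normalization,
             include_background: bool = True,
             schema: LabelSchema | None = None,
             group_key: str | None = None) -> EvalReport:
    """Full-resolution evaluation (no cropping, no multi-scale) of a
    sample list; optionally stratified by a metadata key."""
    mean, std = normalization
    preds = [_forward_labels(net, s.image, mean, std) for s in samples]
    if group_key is not None:
        return stratified_report(samples, preds, group_key,
                                 net.spec.num_classes, include_background, schema)
    cm = ConfusionMatrix(net.spec.num_classes)
    for s, p in zip(samples, preds):
        cm.add(p, s.mask)
    return iou_and_miou(cm, include_background, schema)


def predict(net: MVDNet, image: np.ndarray, normalization,
            schema: LabelSchema | None = None, overlay_path=None) -> np.ndarray:
    """Segment one H x W x 3 image (H, W divisible by 8) into a label map;
    optionally write the palette-indexed overlay PNG."""
    mean, std = normalization
    labels = _forward_labels(net, image, mean, std)
    if overlay_path is not None:
        write_mask(labels, schema or LabelSchema.default(), overlay_path)
    return labels


def fps_benchmark(net: MVDNet, size: tuple[int, int] = (576, 768),
                  repeats: int = 10, warmup: int = 2) -> dict:
    """Wall-clock inference latency at a given resolution (report-only;
    entirely hardware-dependent)."""
    h, w = size
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 3, h, w))
    net.eval()
    for _ in range(warmup):
        net(x)
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        net(x)
        times.append((time.perf_counter() - t0) * 1000.0)
    mean_ms = float(np.mean(times))
    return {
        "resolution": [h, w],
        "repeats": repeats,
        "mean_ms": mean_ms,
        "median_ms": float(np.median(times)),
        "fps": 1000.0 / mean_ms,
        "samples_ms": times,
    }


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    net: MVDNet
    loss_log: list[float]
    val_miou_log: list[float]
    checkpoint: Path | None = None
    final_report: EvalReport | None = None


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng([seed, 7919, epoch])


def train(net: MVDNet, corpus: Corpus, cfg: TrainConfig, out_dir=None,
          resume=None, validate_each_epoch: bool = True,
          include_background: bool = True, verbose: bool = False,
          stop_after: int | None = None) -> TrainResult:
    """Run the SGD/poly protocol on the corpus' train split.

    Deterministic under ``cfg.seed``; checkpoints (written per epoch when
    ``out_dir`` is given) carry optimizer state so resuming from an epoch
    boundary reproduces an uninterrupted run bit for bit.
    """
    train_samples = corpus.samples("train")
    val_samples = corpus.samples("val")
    if not train_samples:
        raise InvalidInputError("corpus has no training samples")
    mean, std = corpus.normalization
    aug = AugmentationConfig(mean=tuple(mean), std=tuple(std), crop_size=cfg.crop)

    n = len(train_samples)
    batches = (n + cfg.batch_size - 1) // cfg.batch_size
    total_steps = cfg.epochs * batches

    opt = SGD(net.parameters(), cfg.momentum, cfg.weight_decay)
    loss_log: list[float] = []
    val_log: list[float] = []
    start_epoch = 0
    if resume is not None:
        net2, opt_state, meta = load_checkpoint(resume)
        net.load_state_dict(net2.state_dict())
        opt.load_state_dict(opt_state)
        start_epoch = int(meta["epoch"])
        loss_log = list(meta.get("loss_log", []))
        val_log = list(meta.get("val_miou_log", []))

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    ckpt_path = None

    net.train()
    for epoch in range(start_epoch, cfg.epochs):
        rng = _epoch_rng(cfg.seed, epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for b in range(batches):
            idxs = order[b * cfg.batch_size: (b + 1) * cfg.batch_size]
            xs, ts = [], []
            for i in idxs:
                s = augment(train_samples[int(i)], aug, rng)
                xs.append(s.image.transpose(2, 0, 1))
                ts.append(s.mask)
            x = np.stack(xs)
            t = np.stack(ts)
            scores = net(x)
            loss, grad = pixel_mean_cross_entropy(scores, t, return_grad=True)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss} at epoch "
                    f"{epoch + 1}, batch {b + 1} (lr="
                    f"{poly_lr(epoch * batches + b, total_steps, cfg):.4g})"
                )
            net.zero_grad()
            net.backward(grad)
            opt.step(poly_lr(epoch * batches + b, total_steps, cfg))
            epoch_losses.append(loss)
        loss_log.append(float(np.mean(epoch_losses)))

        if validate_each_epoch and val_samples:
            report = evaluate(net, val_samples, (mean, std), include_background,
                              corpus.schema)
            val_log.append(report.miou)
            net.train()
        if verbose:
            vm = f" val mIoU {val_log[-1]:.3f}" if val_log else ""
            print(f"epoch {epoch + 1}/{cfg.epochs} loss {loss_log[-1]:.4f}{vm}")
        if out_dir is not None:
            ckpt_path = out_dir / "checkpoint.npz"
            save_checkpoint(ckpt_path, net, opt,
                            meta={"epoch": epoch + 1, "loss_log": loss_log,
                                  "val_miou_log": val_log,
                                  "config": cfg.__dict__,
                                  "normalization": {"mean": list(mean),
                                                    "std": list(std)}})
        if stop_after is not None and epoch + 1 >= stop_after:
            break

    net.eval()
    final = None
    if val_samples:
        final = evaluate(net, val_samples, (mean, std), include_background,
                         corpus.schema)
    return TrainResult(net=net, loss_log=loss_log, val_miou_log=val_log,
                       checkpoint=ckpt_path, final_report=final)
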