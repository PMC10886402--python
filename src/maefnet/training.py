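"""Training protocol, losses and segmentation metrics.

Training minimizes mean per-pixel cross-entropy with SGD (momentum 0.9,
weight decay 1e-4, constant learning rate 0.01, batch size 8 by default);
validation is monitored with the dice loss on hard (argmax) predictions and
with precision / recall / IoU / DSC in percent.  The checkpoint with the best
validation IoU is retained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MAEFNet, normalize_image
from .nn import core
from .nn.core import Tensor
from .nn.modules import SGD

_EPS = 1e-12  # probability clamp in the cross-entropy


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 0.01
    optimizer: str = "sgd"
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be "
                             "positive")
        if self.optimizer != "sgd":
            raise ValueError("only SGD is supported")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int


@dataclass(frozen=True)
class SegMetrics:
    pre: float  # percent
    rec: float
    iou: float
    dsc: float


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_ce_loss: float       # nats
    val_dice_loss: float       # in [0, 1]
    val_metrics: SegMetrics


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy (nats) of class probabilities vs integer labels.

    ``probs`` has the class axis last ((..., C), rows summing to 1); zero
    probabilities are clamped at 1e-12 rather than producing NaN.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    picked = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
    return float(-np.log(np.maximum(picked, _EPS)).mean())


def dice_loss(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """1 - 2|A n B| / (|A| + |B|) on hard masks; both empty counts as 0."""
    pred = np.asarray(pred_mask) > 0
    true = np.asarray(true_mask) > 0
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {true.shape}")
    denom = int(pred.sum()) + int(true.sum())
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * int((pred & true).sum()) / denom


def confusion_counts(pred_mask: np.ndarray,
                     true_mask: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {true.shape}")
    for arr, name in ((pred, "pred"), (true, "true")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred.astype(bool)
    t = true.astype(bool)
    return ConfusionCounts(TP=int((p & t).sum()), FP=int((p & ~t).sum()),
                           FN=int((~p & t).sum()), TN=int((~p & ~t).sum()))


def seg_metrics(counts: ConfusionCounts) -> SegMetrics:
    """Precision / recall / IoU / DSC in percent.

    Degenerate conventions: with no foreground anywhere (TP=FP=FN=0) the
    prediction is perfect, all metrics 100; with TP=0 but some foreground
    involved, all metrics 0.
    """
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    if tp + fp + fn == 0:
        return SegMetrics(100.0, 100.0, 100.0, 100.0)
    if tp == 0:
        return SegMetrics(0.0, 0.0, 0.0, 0.0)
    return SegMetrics(
        pre=100.0 * tp / (tp + fp),
        rec=100.0 * tp / (tp + fn),
        iou=100.0 * tp / (tp + fp + fn),
        dsc=100.0 * 2 * tp / (2 * tp + fp + fn),
    )


def _micro_metrics(pairs) -> tuple[SegMetrics, float]:
    """Pooled-pixel metrics and mean per-image dice loss over (pred, true)."""
    tp = fp = fn = tn = 0
    dl = []
    for pred, true in pairs:
        c = confusion_counts(pred, true)
        tp, fp, fn, tn = tp + c.TP, fp + c.FP, fn + c.FN, tn + c.TN
        dl.append(dice_loss(pred, true))
    return seg_metrics(ConfusionCounts(tp, fp, fn, tn)), float(np.mean(dl))


def _predict_batch(model: MAEFNet, images: list[np.ndarray],
                   batch_size: int = 8) -> list[np.ndarray]:
    model.eval()
    preds = []
    with core.no_grad():
        for start in range(0, len(images), batch_size):
            chunk = images[start:start + batch_size]
            x = Tensor(np.stack([normalize_image(im) for im in chunk]))
            logits = model(x).data
            preds.extend(list((logits[:, 1] > logits[:, 0]).astype(np.uint8)))
    return preds


def train(model: MAEFNet, train_samples, val_samples,
          config: TrainConfig | None = None,
          augment_fn=None) -> list[EpochRecord]:
    """Train in place and return per-epoch records.

    ``train_samples`` / ``val_samples`` are sequences with ``.image`` (uint8)
    and ``.mask`` ({0,1}) attributes, or (image, mask) tuples.  The model is
    left holding the weights of the epoch with the best validation IoU.
    """
    config = config or TrainConfig()

    def unpack(samples):
        out = []
        for s in samples:
            if hasattr(s, "image"):
                out.append((s.image, s.mask))
            else:
                out.append((s[0], s[1]))
        return out

    train_pairs = unpack(train_samples)
    val_pairs = unpack(val_samples)
    if not train_pairs or not val_pairs:
        raise ValueError("train and val splits must both be non-empty")

    rng = np.random.default_rng(config.seed)
    optimizer = SGD(model.parameters(), lr=config.learning_rate,
                    momentum=config.momentum,
                    weight_decay=config.weight_decay)
    records: list[EpochRecord] = []
    best_iou = -1.0
    best_state = None

    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            imgs, msks = [], []
            for i in idx:
                img, msk = train_pairs[i]
                if augment_fn is not None:
                    img, msk = augment_fn(img, msk, rng)
                imgs.append(normalize_image(img))
                msks.append(msk.astype(np.int64))
            x = Tensor(np.stack(imgs))
            labels = np.stack(msks)
            logits = model(x)
            loss = core.softmax_cross_entropy(logits, labels)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))

        preds = _predict_batch(model, [p[0] for p in val_pairs],
                               config.batch_size)
        metrics, val_dice = _micro_metrics(
            zip(preds, [p[1] for p in val_pairs]))
        records.append(EpochRecord(epoch=epoch,
                                   train_ce_loss=float(np.mean(losses)),
                                   val_dice_loss=val_dice,
                                   val_metrics=metrics))
        if metrics.iou > best_iou:
            best_iou = metrics.iou
            best_state = copy.deepcopy(model.state_dict())

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return records


def evaluate(model: MAEFNet, samples, batch_size: int = 8) -> dict:
    """Per-image and micro/macro aggregate Pre/Rec/IoU/DSC on a split."""
    pairs = [(s.image, s.mask) if hasattr(s, "image") else (s[0], s[1])
             for s in samples]
    preds = _predict_batch(model, [p[0] for p in pairs], batch_size)
    per_image = []
    for (img, true), pred in zip(pairs, preds):
        m = seg_metrics(confusion_counts(pred, true))
        per_image.append({"pre": m.pre, "rec": m.rec, "iou": m.iou,
                          "dsc": m.dsc})
    micro, mean_dice = _micro_metrics(zip(preds, [p[1] for p in pairs]))
    macro = {k: float(np.mean([r[k] for r in per_image]))
             for k in ("pre", "rec", "iou", "dsc")}
    return {
        "per_image": per_image,
        "micro": {"pre": micro.pre, "rec": micro.rec, "iou": micro.iou,
                  "dsc": micro.dsc},
        "macro": macro,
        "mean_dice_loss": mean_dice,
    }


def records_to_frame(records: list[EpochRecord]) -> pd.DataFrame:
    """Per-epoch log (epoch, train_loss, val_dice_loss, val metrics)."""
    return pd.DataFrame([{
        "epoch": r.epoch,
        "train_loss": r.train_ce_loss,
        "val_dice_loss": r.val_dice_loss,
        "val_pre": r.val_metrics.pre,
        "val_rec": r.val_metrics.rec,
        "val_iou": r.val_metrics.iou,
        "val_dsc": r.val_metrics.dsc,
    } for r in records])
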