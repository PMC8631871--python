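"""Segmentation evaluation metrics, training losses, augmentation, a small
CPU-trainable segmenter harness, and mask refinement.

Hard metrics (IoU, precision, recall, F-beta) operate on thresholded binary
masks; the training losses are the soft (probabilistic) variants computed on
the model's probability map:

* dice loss  = 1 - soft F-beta, with soft TP/FP/FN summing probabilities;
* focal loss = mean over pixels of -alpha_t * (1 - p_t)^gamma * log(p_t),
  with p_t = p for foreground pixels and 1-p otherwise (alpha=0.25, gamma=2
  defaults), down-weighting easy pixels to counter the strong class imbalance
  of small early-stage plants;
* combined loss = dice + focal, exactly additive.

The trainable segmenter is a deliberately small encoder-decoder: a 3x3-patch
feature encoder feeding a per-pixel MLP decoder head, trained full-image by
Adam on the combined loss with analytic gradients.  It is sized for synthetic
crops on one CPU; the backbone-comparison question for large real datasets is
out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

logger = logging.getLogger(__name__)

_EPS = 1e-7


# ---------------------------------------------------------------------------
# hard metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegScore:
    iou: float
    precision: float
    recall: float
    fbeta: float
    beta: float = 1.0


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-level contingency counts between predicted and true masks."""
    pred, truth = _as_bool(pred), _as_bool(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of the two foregrounds.

    Two empty masks agree that there is no plant; that case is defined as 1.0
    (and logged), rather than 0/0.
    """
    c = confusion_counts(pred, truth)
    union = c.tp + c.fp + c.fn
    if union == 0:
        logger.info("IoU of two empty masks defined as 1.0")
        return 1.0
    return c.tp / union


def seg_score(pred: np.ndarray, truth: np.ndarray, beta: float = 1.0) -> SegScore:
    """Precision, recall, F-beta and IoU from pixel confusion counts.

    Degenerate denominators (no predicted or no true foreground) yield 0 for
    the affected ratio, logged.
    """
    c = confusion_counts(pred, truth)
    if c.tp + c.fp == 0:
        logger.info("no predicted foreground; precision defined as 0")
        p = 0.0
    else:
        p = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        logger.info("no true foreground; recall defined as 0")
        r = 0.0
    else:
        r = c.tp / (c.tp + c.fn)
    denom = beta * beta * p + r
    fb = 0.0 if denom == 0 else (1 + beta * beta) * p * r / denom
    union = c.tp + c.fp + c.fn
    i = 1.0 if union == 0 else c.tp / union
    return SegScore(iou=i, precision=p, recall=r, fbeta=fb, beta=beta)


# ---------------------------------------------------------------------------
# soft losses


@dataclass(frozen=True)
class LossConfig:
    beta: float = 1.0
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def _check_probs(prob: np.ndarray) -> np.ndarray:
    prob = np.asarray(prob, dtype=float)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    return prob


def soft_counts(prob: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """Soft TP/FP/FN where probabilities replace indicator values."""
    prob = _check_probs(prob)
    y = _as_bool(truth).astype(float)
    if prob.shape != y.shape:
        raise ValueError("shape mismatch")
    tp = float((prob * y).sum())
    fp = float((prob * (1 - y)).sum())
    fn = float(((1 - prob) * y).sum())
    return tp, fp, fn


def dice_loss(prob: np.ndarray, truth: np.ndarray, beta: float = 1.0) -> float:
    """1 minus the soft F-beta overlap between probabilities and truth."""
    tp, fp, fn = soft_counts(prob, truth)
    b2 = beta * beta
    denom = (1 + b2) * tp + b2 * fn + fp
    if denom == 0:
        return 0.0  # empty truth, all-zero prediction: perfect agreement
    return 1.0 - (1 + b2) * tp / denom


def focal_loss(
    prob: np.ndarray,
    truth: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
    balanced: bool = True,
    eps: float = _EPS,
) -> float:
    """Mean focal loss over pixels.

    ``balanced=True`` (default) uses the class-balanced weight alpha_t =
    alpha for foreground and 1-alpha for background pixels, the convention of
    the focal-loss literature.  ``balanced=False`` applies alpha as a
    constant weight to every pixel; in that form gamma=0, alpha=1 reduces
    exactly to mean binary cross-entropy.
    """
    prob = np.clip(_check_probs(prob), eps, 1.0 - eps)
    y = _as_bool(truth).astype(float)
    if prob.shape != y.shape:
        raise ValueError("shape mismatch")
    pt = np.where(y > 0, prob, 1.0 - prob)
    if balanced:
        at = np.where(y > 0, alpha, 1.0 - alpha)
    else:
        at = np.full_like(pt, alpha)
    return float(np.mean(-at * (1.0 - pt) ** gamma * np.log(pt)))


def combined_loss(
    prob: np.ndarray, truth: np.ndarray, config: LossConfig = LossConfig()
) -> float:
    """Dice loss plus focal loss, exactly additive."""
    return dice_loss(prob, truth, beta=config.beta) + focal_loss(
        prob, truth, alpha=config.alpha, gamma=config.gamma
    )


def combined_loss_grad(
    prob: np.ndarray, truth: np.ndarray, config: LossConfig = LossConfig()
) -> np.ndarray:
    """Analytic d(combined loss)/d(prob) for the training harness."""
    prob = np.clip(np.asarray(prob, dtype=float), _EPS, 1.0 - _EPS)
    y = _as_bool(truth).astype(float)
    b2 = config.beta**2
    tp = float((prob * y).sum())
    fp = float((prob * (1 - y)).sum())
    fn = float(((1 - prob) * y).sum())
    denom = (1 + b2) * tp + b2 * fn + fp
    # d denom / dp_i = (1+b2) y_i + (1 - y_i) - b2 y_i = 1 + (b2... ) simplify:
    ddenom = (1 + b2) * y + (1 - y) - b2 * y
    if denom > 0:
        g_dice = -((1 + b2) * y * denom - (1 + b2) * tp * ddenom) / denom**2
    else:
        g_dice = np.zeros_like(prob)

    a, g = config.alpha, config.gamma
    n = prob.size
    p, q = prob, 1.0 - prob
    # foreground: f = -a (1-p)^g log p
    gf = a * g * q ** max(g - 1, 0) * np.log(p) - a * q**g / p
    # background: f = -(1-a) p^g log(1-p)
    gb = -(1 - a) * g * p ** max(g - 1, 0) * np.log(q) + (1 - a) * p**g / q
    g_focal = np.where(y > 0, gf, gb) / n
    return g_dice + g_focal


# ---------------------------------------------------------------------------
# augmentation

_AUG_OPS = ("flip_h", "flip_v", "pad", "blur", "sharpen")


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    ops: tuple[str, ...] = _AUG_OPS,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """One augmented (image, mask) pair per op.

    Geometric ops (flips, pad) transform image and mask identically;
    photometric ops (blur, sharpen) touch only the image.  Padding inserts a
    random border and resizes back to the original shape.
    """
    rng = np.random.default_rng(seed)
    unknown = set(ops) - set(_AUG_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops {sorted(unknown)}")
    out = []
    for op in ops:
        if op == "flip_h":
            out.append((image[:, ::-1].copy(), mask[:, ::-1].copy()))
        elif op == "flip_v":
            out.append((image[::-1].copy(), mask[::-1].copy()))
        elif op == "pad":
            p = int(rng.integers(2, max(3, image.shape[0] // 8)))
            img_p = np.pad(image, ((p, p), (p, p), (0, 0)), mode="edge")
            msk_p = np.pad(mask, p, mode="constant")
            out.append((img_p, msk_p))
        elif op == "blur":
            sigma = float(rng.uniform(0.5, 1.5))
            img_b = ndimage.gaussian_filter(
                image.astype(float), sigma=(sigma, sigma, 0)
            )
            out.append((np.clip(img_b, 0, 255).astype(image.dtype), mask.copy()))
        elif op == "sharpen":
            img_f = image.astype(float)
            blur = ndimage.gaussian_filter(img_f, sigma=(1.0, 1.0, 0))
            img_s = np.clip(img_f + 0.8 * (img_f - blur), 0, 255)
            out.append((img_s.astype(image.dtype), mask.copy()))
    return out


# ---------------------------------------------------------------------------
# mask refinement


def refine_mask(
    x: np.ndarray, min_area: int = 16, max_hole: int = 16, threshold: float = 0.5
) -> np.ndarray:
    """Deterministic post-processing of a probability map or mask.

    Thresholds at 0.5, removes connected components smaller than ``min_area``
    pixels, and fills holes smaller than ``max_hole`` pixels.  Idempotent.
    The refiner contract is a plain ``array -> bool array`` callable, so a
    dense-CRF (or any other) refiner can be substituted.
    """
    x = np.asarray(x)
    mask = x if x.dtype == bool else x > threshold
    # max_size removes components <= its value; keep "smaller than min_area"
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    mask = morphology.remove_small_holes(mask, max_size=max_hole)
    return mask


# ---------------------------------------------------------------------------
# tiny trainable segmenter


def _patch_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel 3x3 RGB patch features, shape (H*W, 27), scaled to [0,1]."""
    img = image.astype(np.float32) / 255.0
    h, w, _ = img.shape
    padded = np.pad(img, ((1, 1), (1, 1), (0, 0)), mode="edge")
    feats = [
        padded[dy : dy + h, dx : dx + w, :] for dy in range(3) for dx in range(3)
    ]
    return np.concatenate(feats, axis=2).reshape(h * w, 27)


class TinySegmenter:
    """Small encoder-decoder: 3x3-patch encoder + hidden-layer decoder head.

    Trained with full-batch Adam on the combined dice+focal loss.  All state
    is numpy; with a fixed seed, training is bit-reproducible.
    """

    def __init__(self, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = rng.normal(0.0, 0.3, size=(27, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0.0, 0.3, size=hidden)
        self.b2 = 0.0
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._t = 0

    def _forward(self, feats: np.ndarray):
        pre = feats @ self.w1 + self.b1
        hid = np.maximum(pre, 0.0)
        z = hid @ self.w2 + self.b2
        prob = 1.0 / (1.0 + np.exp(-z))
        return prob, hid, pre

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        feats = _patch_features(image)
        prob, _, _ = self._forward(feats)
        return prob.reshape(image.shape[:2])

    def predict(self, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(image) > threshold

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        if self._adam_state is None:
            self._adam_state = {
                k: (np.zeros_like(np.asarray(getattr(self, k), dtype=float)),) * 2
                for k in grads
            }
        self._t += 1
        for k, g in grads.items():
            m, v = self._adam_state[k]
            m = b1m * m + (1 - b1m) * g
            v = b2m * v + (1 - b2m) * g * g
            self._adam_state[k] = (m, v)
            mh = m / (1 - b1m**self._t)
            vh = v / (1 - b2m**self._t)
            val = np.asarray(getattr(self, k), dtype=float)
            val = val - lr * mh / (np.sqrt(vh) + eps)
            setattr(self, k, val if val.ndim else float(val))

    def train_step(
        self, feats: np.ndarray, truth_flat: np.ndarray, config: LossConfig, lr: float
    ) -> float:
        prob, hid, pre = self._forward(feats)
        loss = combined_loss(prob, truth_flat, config)
        dldp = combined_loss_grad(prob, truth_flat, config)
        dldz = dldp * prob * (1.0 - prob)
        gw2 = hid.T @ dldz
        gb2 = float(dldz.sum())
        dhid = np.outer(dldz, self.w2) * (pre > 0)
        gw1 = feats.T @ dhid
        gb1 = dhid.sum(axis=0)
        self._adam_step({"w1": gw1, "b1": gb1, "w2": gw2, "b2": gb2}, lr)
        return loss


def train_segmenter(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    val_fraction: float = 0.1,
    epochs: int = 20,
    learner_spec: str = "tiny",
    seed: int = 0,
    loss_config: LossConfig = LossConfig(),
    lr: float = 0.05,
    batch_images: int = 16,
) -> tuple[TinySegmenter, list[SegScore]]:
    """Train a registered segmenter on (image, mask) pairs.

    Random train/validation split (default 90/10) with the given seed; trains
    with the combined dice+focal loss; logs hard IoU/F1 on the validation
    split at the end of every epoch; returns the best-validation-F1
    checkpoint together with the per-epoch score log.  ``epochs=0`` returns
    the untrained model and an empty log.
    """
    if learner_spec not in SEGMENTER_REGISTRY:
        raise ValueError(f"unknown learner_spec {learner_spec!r}")
    if epochs > 0 and len(pairs) < 10:
        raise ValueError("need at least 10 image/mask pairs")
    rng = np.random.default_rng(seed)
    model = SEGMENTER_REGISTRY[learner_spec](seed)
    if epochs == 0:
        return model, []

    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(val_fraction * len(pairs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_feats = [
        (_patch_features(pairs[i][0]), _as_bool(pairs[i][1]).ravel())
        for i in train_idx
    ]
    val_pairs = [pairs[i] for i in val_idx]

    log: list[SegScore] = []
    best: tuple[float, dict] | None = None
    for _epoch in range(epochs):
        perm = rng.permutation(len(train_feats))
        for start in range(0, len(perm), batch_images):
            chunk = perm[start : start + batch_images]
            feats = np.concatenate([train_feats[i][0] for i in chunk])
            truth = np.concatenate([train_feats[i][1] for i in chunk])
            loss = model.train_step(feats, truth, loss_config, lr)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss {loss}) at epoch {_epoch}"
                )
        scores = [seg_score(model.predict(img), msk) for img, msk in val_pairs]
        epoch_score = SegScore(
            iou=float(np.mean([s.iou for s in scores])),
            precision=float(np.mean([s.precision for s in scores])),
            recall=float(np.mean([s.recall for s in scores])),
            fbeta=float(np.mean([s.fbeta for s in scores])),
        )
        log.append(epoch_score)
        state = {
            "w1": model.w1.copy(),
            "b1": model.b1.copy(),
            "w2": model.w2.copy(),
            "b2": model.b2,
        }
        if best is None or epoch_score.fbeta > best[0]:
            best = (epoch_score.fbeta, state)
    for k, v in best[1].items():
        setattr(model, k, v)
    return model, log


SEGMENTER_REGISTRY = {"tiny": lambda seed: TinySegmenter(hidden=16, seed=seed)}
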