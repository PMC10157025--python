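"""Desk-scale neural models for white-matter segmentation and WMI risk.

Two models operate on normalized grayscale frames:

* ``SegNet`` — an encoder-decoder with skip connections (a down-sampling
  path for semantics, an up-sampling path for localization, transverse
  connections between them) trained with combined Dice + cross-entropy
  loss; it emits a per-pixel ROI probability map.
* ``MtlNet`` — the multi-task sibling: the same encoder feeds three heads
  emitting a segmentation mask, a subject-status classification score and
  a bounding box.  The box head regresses the tight box of the reference
  mask; the emitted box is clamped to contain the support of the predicted
  binarized mask, which is the contract of the output type.

Training follows the imbalanced-cohort scheme: the minority (WMI) class is
cyclically oversampled to a target ratio each epoch, frames are augmented
by random translation/rotation/flip applied jointly to image and mask, and
parameters are updated with Adam (defaults lr 1e-3 for segmentation, 2e-4
for the multi-task model, batch 4).  The implementation is pure NumPy, so
fixed seeds reproduce training exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .errors import ConfigurationError, DegenerateLabelError


@dataclass
class AugmentConfig:
    translate_frac: float = 0.10  # max shift, fraction of image size
    rotate_deg: float = 15.0
    flip_prob: float = 0.5
    enabled: bool = True


@dataclass
class SegTrainConfig:
    """Training settings.  The full-scale clinical profile (100 epochs,
    batch 4, Adam 1e-3 / 2e-4) is available via :func:`reference_profile`;
    the desk defaults are sized for CPU minutes."""

    epochs: int = 20
    batch_size: int = 4
    lr: float = 1e-3
    base_channels: int = 8
    cls_hidden: int = 16
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 0.5)  # mask, label, box
    oversample_ratio: float = 1.0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0


def reference_profile(multitask: bool = False) -> SegTrainConfig:
    """The full-scale clinical training profile (epochs 100, batch 4)."""
    return SegTrainConfig(epochs=100, lr=2e-4 if multitask else 1e-3)


@dataclass
class MtlOutput:
    mask: np.ndarray  # probabilities in [0, 1]
    class_score: float  # higher = more WMI-like (sigmoid of the logit)
    box: tuple[int, int, int, int]  # (r0, c0, r1, c1), 0-based half-open


# ---------------------------------------------------------------------------
# sampling & augmentation


def oversample_schedule(
    labels, epochs: int, ratio: float = 1.0, seed: int = 0
) -> list[np.ndarray]:
    """Per-epoch index sequences with cyclic minority oversampling.

    Each epoch contains every majority-class index once plus minority
    indices drawn by cycling through a fixed shuffled rotation, continued
    across epochs, until the epoch's minority count reaches
    ``ratio * majority count``.  Cycling guarantees that minority usage
    counts never differ by more than one over any horizon.
    """
    y = np.asarray(labels).astype(int).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DegenerateLabelError("oversampling needs two classes")
    minority = classes[np.argmin(counts)]
    maj_idx = np.flatnonzero(y != minority)
    min_idx = np.flatnonzero(y == minority)
    rng = np.random.default_rng(seed)
    rotation = min_idx.copy()
    rng.shuffle(rotation)
    pointer = 0
    n_min_per_epoch = int(round(ratio * len(maj_idx)))
    epochs_out = []
    for _ in range(epochs):
        take = []
        for _ in range(n_min_per_epoch):
            take.append(rotation[pointer])
            pointer += 1
            if pointer == len(rotation):
                pointer = 0
        epoch = np.concatenate([maj_idx, np.array(take, dtype=int)])
        rng.shuffle(epoch)
        epochs_out.append(epoch)
    return epochs_out


def augment(
    image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One random geometric transform applied jointly to image and mask.

    Translation is integer-pixel within +-translate_frac of the size,
    rotation within +-rotate_deg (bilinear for the image, nearest for the
    mask), horizontal flip with probability flip_prob.
    """
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask, dtype=bool)
    if not cfg.enabled:
        return img, msk
    h, w = img.shape
    ang = rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)
    if abs(ang) > 1e-9:
        img = ndimage.rotate(img, ang, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(
            msk.astype(np.uint8), ang, reshape=False, order=0, mode="constant"
        ).astype(bool)
    dr = int(rng.integers(-int(cfg.translate_frac * h), int(cfg.translate_frac * h) + 1))
    dc = int(rng.integers(-int(cfg.translate_frac * w), int(cfg.translate_frac * w) + 1))
    if dr or dc:
        img = ndimage.shift(img, (dr, dc), order=0, mode="nearest")
        msk = ndimage.shift(msk.astype(np.uint8), (dr, dc), order=0, mode="constant").astype(bool)
    if rng.random() < cfg.flip_prob:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    return img, msk


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight (r0, c0, r1, c1) half-open box of a boolean mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return (0, 0, 0, 0)
    return (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


# ---------------------------------------------------------------------------
# networks


class _Encoder:
    """Two pooling stages plus bottleneck; returns skip activations."""

    def __init__(self, rng, c_in: int, c: int):
        self.params = []
        self.w = {}
        spec = {
            "e1a": (c, c_in), "e1b": (c, c),
            "e2a": (2 * c, c), "e2b": (2 * c, 2 * c),
            "ba": (4 * c, 2 * c), "bb": (4 * c, 4 * c),
        }
        for name, (co, ci) in spec.items():
            w = nn.he_conv(rng, co, ci, 3)
            b = nn.parameter(np.zeros(co))
            self.w[name] = (w, b)
            self.params += [w, b]

    def _block(self, x, n1, n2):
        x = nn.relu(nn.conv2d(x, *self.w[n1], k=3, pad=1))
        return nn.relu(nn.conv2d(x, *self.w[n2], k=3, pad=1))

    def forward(self, x: nn.Tensor):
        e1 = self._block(x, "e1a", "e1b")
        e2 = self._block(nn.maxpool2(e1), "e2a", "e2b")
        bott = self._block(nn.maxpool2(e2), "ba", "bb")
        return e1, e2, bott


class _Decoder:
    def __init__(self, rng, c: int):
        self.params = []
        self.w = {}
        spec = {
            "d2a": (2 * c, 6 * c), "d2b": (2 * c, 2 * c),
            "d1a": (c, 3 * c), "d1b": (c, c),
        }
        for name, (co, ci) in spec.items():
            w = nn.he_conv(rng, co, ci, 3)
            b = nn.parameter(np.zeros(co))
            self.w[name] = (w, b)
            self.params += [w, b]
        self.head_w = nn.he_conv(rng, 1, c, 1)
        self.head_b = nn.parameter(np.zeros(1))
        self.params += [self.head_w, self.head_b]

    def forward(self, e1, e2, bott):
        d2 = nn.concat(nn.upsample2(bott), e2)
        d2 = nn.relu(nn.conv2d(d2, *self.w["d2a"], k=3, pad=1))
        d2 = nn.relu(nn.conv2d(d2, *self.w["d2b"], k=3, pad=1))
        d1 = nn.concat(nn.upsample2(d2), e1)
        d1 = nn.relu(nn.conv2d(d1, *self.w["d1a"], k=3, pad=1))
        d1 = nn.relu(nn.conv2d(d1, *self.w["d1b"], k=3, pad=1))
        return nn.conv2d(d1, self.head_w, self.head_b, k=1, pad=0)


class SegNet:
    """Encoder-decoder segmentation network with skip connections."""

    def __init__(self, base_channels: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = _Encoder(rng, 1, base_channels)
        self.decoder = _Decoder(rng, base_channels)
        self.params = self.encoder.params + self.decoder.params

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.decoder.forward(*self.encoder.forward(x))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """ROI probability map for one normalized or uint8 frame."""
        x = nn.Tensor(_to_input(image))
        return nn.sigmoid(self.forward(x).data[0, 0])


class MtlNet:
    """Shared encoder, three heads: mask decoder, classifier, box regressor."""

    def __init__(self, base_channels: int = 8, cls_hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.encoder = _Encoder(rng, 1, c)
        self.decoder = _Decoder(rng, c)
        self.cls_w1 = nn.he_dense(rng, cls_hidden, 4 * c)
        self.cls_b1 = nn.parameter(np.zeros(cls_hidden))
        self.cls_w2 = nn.he_dense(rng, 1, cls_hidden)
        self.cls_b2 = nn.parameter(np.zeros(1))
        self.box_w1 = nn.he_dense(rng, cls_hidden, 4 * c)
        self.box_b1 = nn.parameter(np.zeros(cls_hidden))
        self.box_w2 = nn.he_dense(rng, 4, cls_hidden)
        self.box_b2 = nn.parameter(np.zeros(4))
        self.params = (
            self.encoder.params + self.decoder.params
            + [self.cls_w1, self.cls_b1, self.cls_w2, self.cls_b2,
               self.box_w1, self.box_b1, self.box_w2, self.box_b2]
        )

    def forward(self, x: nn.Tensor):
        e1, e2, bott = self.encoder.forward(x)
        mask_logits = self.decoder.forward(e1, e2, bott)
        pooled = nn.global_avg_pool(bott)
        cls_logit = nn.dense(
            nn.relu(nn.dense(pooled, self.cls_w1, self.cls_b1)),
            self.cls_w2, self.cls_b2,
        )
        box_pred = nn.dense(
            nn.relu(nn.dense(pooled, self.box_w1, self.box_b1)),
            self.box_w2, self.box_b2,
        )
        return mask_logits, cls_logit, box_pred

    def infer(self, image: np.ndarray) -> MtlOutput:
        x = nn.Tensor(_to_input(image))
        mask_logits, cls_logit, box_pred = self.forward(x)
        prob = nn.sigmoid(mask_logits.data[0, 0])
        h, w = prob.shape
        raw = np.clip(nn.sigmoid(box_pred.data[0]), 0, 1)
        box = [raw[0] * h, raw[1] * w, raw[2] * h, raw[3] * w]
        r0, c0 = int(np.floor(min(box[0], box[2]))), int(np.floor(min(box[1], box[3])))
        r1, c1 = int(np.ceil(max(box[0], box[2]))), int(np.ceil(max(box[1], box[3])))
        support = mask_bbox(prob >= 0.5)
        if support != (0, 0, 0, 0):  # the box must contain the mask support
            r0, c0 = min(r0, support[0]), min(c0, support[1])
            r1, c1 = max(r1, support[2]), max(c1, support[3])
        return MtlOutput(
            mask=prob,
            class_score=float(nn.sigmoid(cls_logit.data)[0, 0]),
            box=(r0, c0, r1, c1),
        )


def _to_input(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:  # uint8 range
        img = img / 255.0
    return img[None, None]


# ---------------------------------------------------------------------------
# training loops


def _batches(idx_epoch: np.ndarray, batch_size: int):
    for s in range(0, len(idx_epoch), batch_size):
        yield idx_epoch[s : s + batch_size]


def _prep_batch(images, masks, batch, cfg, rng):
    ims, mks = [], []
    for i in batch:
        im, mk = augment(images[i], masks[i], cfg.augment, rng)
        ims.append(im)
        mks.append(mk)
    x = np.stack([_to_input(im)[0] for im in ims])
    m = np.stack(mks).astype(np.float64)[:, None]
    return x, m, mks


def train_seg_net(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    labels=None,
    cfg: SegTrainConfig | None = None,
) -> tuple[SegNet, list[float]]:
    """Train the segmentation net; returns (model, per-epoch loss curve).

    ``labels`` activates minority oversampling of the epoch schedule; with
    labels omitted (or single-class) every epoch is a plain shuffle.
    """
    cfg = cfg or SegTrainConfig()
    if not images:
        raise ConfigurationError("empty training cohort")
    model = SegNet(cfg.base_channels, seed=cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    schedule = _schedule(labels, len(images), cfg, seed=cfg.seed + 2)
    curve = []
    for epoch_idx in schedule:
        losses = []
        for batch in _batches(epoch_idx, cfg.batch_size):
            x, m, _ = _prep_batch(images, masks, batch, cfg, rng)
            xt = nn.Tensor(x)
            logits = model.forward(xt)
            l_bce, g_bce = nn.bce_with_logits(logits.data, m)
            l_dice, g_dice = nn.soft_dice_loss(logits.data, m)
            nn.zero_grad(model.params)
            nn.backward([(logits, g_bce + g_dice)])
            opt.step()
            losses.append(l_bce + l_dice)
        curve.append(float(np.mean(losses)))
    return model, curve


def train_mtl_net(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    labels,
    cfg: SegTrainConfig | None = None,
) -> tuple[MtlNet, list[float]]:
    """Jointly train mask, label and box heads; returns (model, loss curve)."""
    cfg = cfg or SegTrainConfig(lr=2e-4)
    if not images:
        raise ConfigurationError("empty training cohort")
    y = np.asarray(labels).astype(int).ravel()
    model = MtlNet(cfg.base_channels, cfg.cls_hidden, seed=cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    schedule = _schedule(y, len(images), cfg, seed=cfg.seed + 2)
    w_mask, w_cls, w_box = cfg.loss_weights
    curve = []
    for epoch_idx in schedule:
        losses = []
        for batch in _batches(epoch_idx, cfg.batch_size):
            x, m, mks = _prep_batch(images, masks, batch, cfg, rng)
            h, w = x.shape[2:]
            ybatch = y[batch].astype(np.float64)[:, None]
            boxes = np.array(
                [np.asarray(mask_bbox(mk), dtype=np.float64) / (h, w, h, w) for mk in mks]
            )
            xt = nn.Tensor(x)
            mask_logits, cls_logit, box_pred = model.forward(xt)
            l_m, g_m = nn.bce_with_logits(mask_logits.data, m)
            l_d, g_d = nn.soft_dice_loss(mask_logits.data, m)
            l_c, g_c = nn.bce_with_logits(cls_logit.data, ybatch)
            box_sig = nn.sigmoid(box_pred.data)
            l_b, g_b = nn.smooth_l1_loss(box_sig, boxes)
            g_b = g_b * box_sig * (1 - box_sig)  # through the sigmoid squash
            nn.zero_grad(model.params)
            nn.backward([
                (mask_logits, w_mask * (g_m + g_d)),
                (cls_logit, w_cls * g_c),
                (box_pred, w_box * g_b),
            ])
            opt.step()
            losses.append(w_mask * (l_m + l_d) + w_cls * l_c + w_box * l_b)
        curve.append(float(np.mean(losses)))
    return model, curve


def _schedule(labels, n: int, cfg: SegTrainConfig, seed: int):
    if labels is not None and len(np.unique(np.asarray(labels).astype(int))) == 2:
        return oversample_schedule(labels, cfg.epochs, cfg.oversample_ratio, seed)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(cfg.epochs):
        idx = np.arange(n)
        rng.shuffle(idx)
        out.append(idx)
    return out
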