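"""Sampling schedule, joint augmentation, and network contracts."""

import numpy as np
import pytest

from wmius.errors import DegenerateLabelError
from wmius.mtl import (AugmentConfig, MtlNet, SegNet, SegTrainConfig, augment,
                       mask_bbox, oversample_schedule, reference_profile,
                       train_seg_net)


def test_oversample_ratio_exact_when_divisible():
    labels = np.array([0] * 88 + [1] * 22)
    sched = oversample_schedule(labels, epochs=2, ratio=1.0, seed=0)
    for epoch in sched:
        assert len(epoch) == 176
        counts = np.bincount(epoch, minlength=110)
        assert (counts[:88] == 1).all()  # every majority frame once
        assert (counts[88:] == 4).all()  # every minority frame exactly 4x


def test_balanced_input_gives_plain_epoch():
    labels = np.array([0] * 10 + [1] * 10)
    sched = oversample_schedule(labels, epochs=3, ratio=1.0, seed=0)
    for epoch in sched:
        assert len(epoch) == 20
        assert sorted(epoch) == list(range(20))


def test_cyclic_fairness_when_not_divisible():
    labels = np.array([0] * 10 + [1] * 3)
    sched = oversample_schedule(labels, epochs=3, ratio=1.0, seed=0)
    usage = np.zeros(13, int)
    for epoch in sched:
        usage += np.bincount(epoch, minlength=13)
    minority_usage = usage[10:]
    assert minority_usage.max() - minority_usage.min() <= 1


def test_single_class_schedule_rejected():
    with pytest.raises(DegenerateLabelError):
        oversample_schedule(np.zeros(5), epochs=1)


def test_augment_disabled_is_identity():
    rng = np.random.default_rng(0)
    img = rng.random((32, 32)) * 255
    mask = np.zeros((32, 32), bool)
    mask[10:20, 12:22] = True
    out_img, out_mask = augment(img, mask, AugmentConfig(enabled=False), rng)
    assert np.array_equal(out_img, img) and np.array_equal(out_mask, mask)


def test_flip_twice_with_same_seed_is_identity():
    rng = np.random.default_rng(3)
    img = np.random.default_rng(1).random((16, 16))
    mask = np.zeros((16, 16), bool)
    mask[4:9, 5:11] = True
    cfg = AugmentConfig(translate_frac=0.0, rotate_deg=0.0, flip_prob=1.0)
    i1, m1 = augment(img, mask, cfg, rng)
    i2, m2 = augment(i1, m1, cfg, rng)
    assert np.array_equal(i2, img) and np.array_equal(m2, mask)


def test_mask_area_preserved_under_flip_and_interior_translation():
    rng = np.random.default_rng(7)
    img = rng.random((40, 40))
    mask = np.zeros((40, 40), bool)
    mask[16:24, 15:25] = True  # interior ROI with margin > max shift
    cfg = AugmentConfig(translate_frac=0.10, rotate_deg=0.0, flip_prob=0.5)
    for _ in range(20):
        _, out_mask = augment(img, mask, cfg, rng)
        assert out_mask.sum() == mask.sum()


def test_joint_transform_moves_image_and_mask_together():
    rng = np.random.default_rng(9)
    img = np.zeros((32, 32))
    img[10:16, 8:14] = 1.0
    mask = img > 0.5
    cfg = AugmentConfig(rotate_deg=0.0)
    for _ in range(10):
        out_img, out_mask = augment(img, mask, cfg, rng)
        assert np.array_equal(out_img > 0.5, out_mask)


def test_mask_bbox_tight_half_open():
    m = np.zeros((10, 10), bool)
    m[2:5, 3:8] = True
    assert mask_bbox(m) == (2, 3, 5, 8)
    assert mask_bbox(np.zeros((4, 4), bool)) == (0, 0, 0, 0)


def test_untrained_segnet_near_chance_and_infer_contract():
    rng = np.random.default_rng(0)
    img = (rng.random((64, 64)) * 255).astype(np.uint8)
    mask = np.zeros((64, 64), bool)
    mask[20:40, 25:45] = True  # ~10% foreground
    net = SegNet(base_channels=4, seed=0)
    from wmius.metrics import seg_overlap

    dice, _, _ = seg_overlap(net.predict(img) >= 0.5, mask)
    assert 0.0 <= dice <= 0.45  # chance level for an untrained model
    mtl = MtlNet(base_channels=4, seed=0)
    out = mtl.infer(img)
    assert out.mask.shape == img.shape
    assert np.all((out.mask >= 0) & (out.mask <= 1))
    assert 0.0 <= out.class_score <= 1.0
    r0, c0, r1, c1 = out.box
    support = mask_bbox(out.mask >= 0.5)
    if support != (0, 0, 0, 0):
        assert r0 <= support[0] and c0 <= support[1]
        assert r1 >= support[2] and c1 >= support[3]


def test_training_loss_decreases_on_tiny_overfit():
    rng = np.random.default_rng(1)
    img = (rng.random((32, 32)) * 255).astype(np.uint8)
    mask = np.zeros((32, 32), bool)
    mask[8:20, 10:24] = True
    cfg = SegTrainConfig(epochs=30, batch_size=1, seed=0,
                         augment=AugmentConfig(enabled=False))
    _, curve = train_seg_net([img], [mask], cfg=cfg)
    first = np.mean(curve[:5])
    last = np.mean(curve[-5:])
    assert last < first


def test_training_reproducible_given_seed():
    rng = np.random.default_rng(2)
    imgs = [(rng.random((32, 32)) * 255).astype(np.uint8) for _ in range(4)]
    masks = []
    for _ in range(4):
        m = np.zeros((32, 32), bool)
        m[8:18, 8:18] = True
        masks.append(m)
    cfg = SegTrainConfig(epochs=2, seed=7)
    _, c1 = train_seg_net(imgs, masks, cfg=cfg)
    _, c2 = train_seg_net(imgs, masks, cfg=cfg)
    assert np.allclose(c1, c2, atol=1e-12)


def test_reference_profile_mirrors_clinical_settings():
    seg = reference_profile()
    mtl = reference_profile(multitask=True)
    assert seg.epochs == 100 and seg.batch_size == 4 and seg.lr == 1e-3
    assert mtl.lr == 2e-4
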