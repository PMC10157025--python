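"""Evaluation battery: AUC oracle, report identities, overlap measures."""

import numpy as np
import pandas as pd
import pytest

from oracles import auc_bf
from wmius.errors import DegenerateLabelError, ShapeError
from wmius.metrics import (classification_report, crossval, report_from_counts,
                           roc_auc, seg_overlap, subject_folds)


def test_auc_perfect_and_tied():
    assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5


def test_auc_equals_pairwise_oracle_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 40))
        scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=n)  # force ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        assert np.isclose(roc_auc(scores, labels), auc_bf(scores, labels))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    s = rng.standard_normal(100)
    y = rng.integers(0, 2, 100)
    assert np.isclose(roc_auc(s, y), roc_auc(np.exp(2 * s + 1), y))


def test_single_class_rejected():
    with pytest.raises(DegenerateLabelError):
        roc_auc([0.1, 0.2], [1, 1])


def test_printed_table_rows_reproduce_from_counts():
    r = report_from_counts(tp=34, fn=11, tn=189, fp=7)
    assert round(r.sens, 2) == 75.56
    assert round(r.spec, 2) == 96.43
    assert round(r.lr_pos, 2) == 21.16
    assert round(r.lr_neg, 2) == 0.25
    r2 = report_from_counts(tp=29, fn=16, tn=188, fp=8)
    assert round(r2.sens, 2) == 64.44
    assert round(r2.spec, 2) == 95.92
    assert round(r2.lr_pos, 2) == 15.79
    r3 = report_from_counts(tp=31, fn=14, tn=190, fp=6)
    assert round(r3.sens, 2) == 68.89
    assert round(r3.spec, 2) == 96.94
    assert round(r3.lr_pos, 2) == 22.50


def test_perfect_classifier_boundary_conventions():
    r = report_from_counts(tp=10, fn=0, tn=20, fp=0)
    assert r.spec == 100.0
    assert r.lr_pos_capped and r.lr_pos == 1e6
    assert r.lr_neg == 0.0


def test_report_self_consistency_identities():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = 60
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        s = rng.standard_normal(n) + y
        rep = classification_report(s, y)
        n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
        assert rep.tp + rep.fn == n_pos and rep.tn + rep.fp == n_neg
        assert np.isclose(rep.acc, 100 * (rep.tp + rep.tn) / n)
        assert np.isclose(rep.sens, 100 * rep.tp / n_pos)
        assert np.isclose(rep.spec, 100 * rep.tn / n_neg)
        assert 0 <= rep.auc <= 1 and rep.lr_pos >= 0


def test_explicit_threshold_is_respected():
    s = np.array([0.1, 0.4, 0.6, 0.9])
    y = np.array([0, 0, 1, 1])
    rep = classification_report(s, y, threshold_rule=0.5)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 0, 2, 0)


def test_dice_iou_hand_values_and_identity():
    a = np.zeros((8, 8), bool)
    b = np.zeros((8, 8), bool)
    a[0, :4] = True
    b[0, 2:6] = True
    dice, iou, _ = seg_overlap(a, b)
    assert np.isclose(dice, 0.5) and np.isclose(iou, 1 / 3)
    assert seg_overlap(a, a) == (1.0, 1.0, 1.0)
    assert seg_overlap(np.zeros((4, 4)), np.zeros((4, 4)))[:2] == (1.0, 1.0)
    rng = np.random.default_rng(2)
    for _ in range(100):
        m1 = rng.random((10, 10)) > 0.5
        m2 = rng.random((10, 10)) > 0.5
        dice, iou, _ = seg_overlap(m1, m2)
        assert abs(dice - 2 * iou / (1 + iou)) < 1e-12


def test_mask_shape_mismatch_rejected():
    with pytest.raises(ShapeError):
        seg_overlap(np.zeros((4, 4)), np.zeros((5, 5)))


def _subject_manifest(n=20, wmi_every=4):
    rows = []
    for i in range(n):
        label = "wmi" if i % wmi_every == 0 else "normal"
        for k in range(2):
            rows.append((f"S{i}", f"i{i}_{k}", f"m{i}_{k}", label, "unassigned"))
    return pd.DataFrame(rows, columns=[
        "subject_id", "image_path", "mask_path", "label", "split"])


def test_subject_folds_partition_and_stratify():
    m = _subject_manifest()
    folds = subject_folds(m, k=5, seed=0)
    sizes = sorted(len(f) for f in folds)
    assert sizes == [4, 4, 4, 4, 4]
    all_subjects = np.concatenate(folds)
    assert len(set(all_subjects)) == 20
    for seed in range(10):
        folds = subject_folds(m, k=5, seed=seed)
        for i, a in enumerate(folds):
            for b in folds[i + 1:]:
                assert not set(a) & set(b)


def test_crossval_runs_pipeline_on_disjoint_folds():
    m = _subject_manifest()
    seen = []

    def run_fold(train_m, test_m, i):
        assert not set(train_m["subject_id"]) & set(test_m["subject_id"])
        assert set(train_m["label"]) == {"normal", "wmi"}
        seen.append(i)
        return len(test_m)

    results = crossval(m, run_fold, k=5, seed=1)
    assert seen == [0, 1, 2, 3, 4]
    assert np.isclose(np.mean(results), np.mean([float(r) for r in results]))
    assert sum(results) == len(m)
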