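"""Diagnostic and segmentation evaluation battery.

Classification is summarized by ROC AUC plus confusion-derived indexes at
an operating threshold: accuracy (ACC), sensitivity (SENS), specificity
(SPEC) — reported in percent — and the positive/negative diagnostic
likelihood ratios LR+ = SENS/(1-SPEC), LR- = (1-SENS)/SPEC.  Segmentation
is summarized per image by the Dice coefficient, Intersection over Union
and pixel accuracy.  A subject-level k-fold cross-validation harness runs
an arbitrary pipeline callable on subject-disjoint folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ConfigurationError, DegenerateLabelError, ShapeError

EPS = 1e-6


@dataclass
class EvalReport:
    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float  # percent
    sens: float  # percent
    spec: float  # percent
    lr_pos: float
    lr_neg: float
    lr_pos_capped: bool = False
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "auc", "threshold", "tp", "fp", "tn", "fn",
            "acc", "sens", "spec", "lr_pos", "lr_neg", "lr_pos_capped",
        )}
        d["roc_points"] = self.roc_points
        return d


@dataclass
class SegReport:
    dice: list[float]
    iou: list[float]
    pixel_acc: list[float]

    @property
    def mean_dice(self) -> float:
        return float(np.mean(self.dice))

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.iou))

    @property
    def mean_pixel_acc(self) -> float:
        return float(np.mean(self.pixel_acc))


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int).ravel()
    if len(np.unique(y)) != 2:
        raise DegenerateLabelError("both classes must be present")
    return y


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute one half."""
    y = _check_labels(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64).ravel()))


def youden_threshold(scores, labels) -> float:
    """Operating point maximizing SENS + SPEC - 1 on the given scores."""
    y = _check_labels(labels)
    fpr, tpr, thr = roc_curve(y, scores)
    return float(thr[int(np.argmax(tpr - fpr))])


def report_from_counts(tp: int, fp: int, tn: int, fn: int,
                       auc: float = float("nan"),
                       threshold: float = float("nan")) -> EvalReport:
    """Build the full index battery from confusion counts alone.

    SENS, SPEC, ACC are percentages rounded at reporting time, LR+/LR- are
    computed from the unrounded proportions.  SPEC = 100% makes LR+
    formally infinite; it is capped at 1/EPS and flagged.
    """
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelError("confusion counts lack one class")
    sens = tp / n_pos
    spec = tn / n_neg
    capped = (1.0 - spec) < EPS
    lr_pos = sens / (1.0 - spec) if not capped else 1.0 / EPS
    lr_neg = (1.0 - sens) / spec if spec > EPS else 1.0 / EPS
    return EvalReport(
        auc=auc,
        threshold=threshold,
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        acc=100.0 * (tp + tn) / (n_pos + n_neg),
        sens=100.0 * sens,
        spec=100.0 * spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        lr_pos_capped=capped,
    )


def classification_report(
    scores, labels, threshold_rule: str | float = "youden"
) -> EvalReport:
    """Full diagnostic report at an operating threshold.

    ``threshold_rule`` is either an explicit score threshold (frozen on a
    training cohort, the leak-free protocol) or ``"youden"`` to place the
    threshold at the Youden-optimal point of these scores.  Predictions
    are positive when score >= threshold.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if s.shape != y.shape:
        raise ShapeError(f"scores {s.shape} vs labels {y.shape}")
    thr = youden_threshold(s, y) if threshold_rule == "youden" else float(threshold_rule)
    pred = s >= thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    fpr, tpr, _ = roc_curve(y, s)
    rep = report_from_counts(tp, fp, tn, fn, auc=roc_auc(s, y), threshold=thr)
    rep.roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return rep


def seg_overlap(pred_mask, true_mask) -> tuple[float, float, float]:
    """(Dice, IoU, pixel accuracy) of one predicted/reference mask pair.

    Empty-vs-empty is a perfect match by convention (1, 1, 1).
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    size = int(a.sum() + b.sum())
    dice = 2.0 * inter / size if size else 1.0
    iou = inter / union if union else 1.0
    pix = float(np.mean(a == b))
    return dice, iou, pix


def seg_report(pred_masks, true_masks) -> SegReport:
    triples = [seg_overlap(p, t) for p, t in zip(pred_masks, true_masks)]
    return SegReport(
        dice=[t[0] for t in triples],
        iou=[t[1] for t in triples],
        pixel_acc=[t[2] for t in triples],
    )


def subject_folds(
    manifest: pd.DataFrame, k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Label-stratified, subject-disjoint partition into k folds.

    Returns a list of k arrays of subject ids.  Every class must have at
    least k subjects so each fold's training side keeps both classes.
    """
    subjects = manifest.drop_duplicates("subject_id")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for lab in sorted(subjects["label"].unique()):
        sids = np.array(sorted(subjects.loc[subjects["label"] == lab, "subject_id"]))
        if len(sids) < k:
            raise ConfigurationError(
                f"class {lab!r} has {len(sids)} subjects, fewer than k={k}"
            )
        rng.shuffle(sids)
        for i, sid in enumerate(sids):
            folds[i % k].append(sid)
    return [np.array(f) for f in folds]


def crossval(manifest: pd.DataFrame, run_fold, k: int = 5, seed: int = 0):
    """Subject-level k-fold cross-validation of a pipeline callable.

    ``run_fold(train_manifest, test_manifest, fold_index)`` returns any
    report object; the list of k results is returned together with the
    mean of every numeric attribute exposed via ``auc`` or ``mean_dice``.
    """
    folds = subject_folds(manifest, k=k, seed=seed)
    results = []
    for i, test_subjects in enumerate(folds):
        is_test = manifest["subject_id"].isin(test_subjects)
        train_m = manifest[~is_test].reset_index(drop=True)
        test_m = manifest[is_test].reset_index(drop=True)
        results.append(run_fold(train_m, test_m, i))
    return results
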