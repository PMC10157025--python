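"""End-to-end orchestration of the diagnostic strategy.

Three run modes from a single YAML config:

* ``radiomics-golden`` — features from reference (manually delineated)
  masks: extraction -> sparse-representation ranking -> top-k C-SVC.
* ``radiomics-auto`` — the same radiomics system, but test-cohort features
  are extracted from masks predicted by the segmentation net (the
  label-free deployment mode).
* ``mtl-direct`` — the multi-task net segments and classifies directly.

A single global seed fans out to per-stage seeds by fixed offsets so every
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, predict_scores, train_classifier
from .dataio import load_image, load_mask, split_by_subject
from .errors import ConfigurationError
from .metrics import classification_report, seg_report, youden_threshold
from .mtl import SegTrainConfig, train_mtl_net, train_seg_net
from .src_select import rank_features, select_top
from .synthgen import CohortConfig, cohort_in_memory
from .texture import TextureConfig, extract_feature_vector, feature_names

MODES = ("radiomics-golden", "radiomics-auto", "mtl-direct")

STAGE_SEED_OFFSETS = {
    "synth": 0, "split": 1, "ranking": 2, "classifier": 3,
    "segnet": 4, "mtlnet": 5, "degrade": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 131 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


# ---------------------------------------------------------------------------
# feature tables


def features_from_arrays(rows: pd.DataFrame, images: dict, masks: dict,
                         cfg: TextureConfig | None = None) -> pd.DataFrame:
    """350-column feature table for manifest rows with in-memory rasters."""
    cfg = cfg or TextureConfig()
    out = []
    for _, row in rows.iterrows():
        vec = extract_feature_vector(images[row["image_path"]],
                                     masks[row["mask_path"]], cfg)
        vec_row = {"subject_id": row["subject_id"], "label": row["label"]}
        vec_row.update(vec)
        out.append(vec_row)
    return pd.DataFrame(out, columns=["subject_id", "label"] + feature_names())


def features_from_disk(manifest: pd.DataFrame, root, cfg: TextureConfig | None = None
                       ) -> pd.DataFrame:
    root = Path(root)
    images = {p: load_image(root / p) for p in manifest["image_path"].unique()}
    masks = {p: load_mask(root / p) for p in manifest["mask_path"].unique()}
    return features_from_arrays(manifest, images, masks, cfg)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[feature_names()].to_numpy(dtype=np.float64)
    y = (table["label"] == "wmi").to_numpy(dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# radiomics fit/eval


def radiomics_fit_eval(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    n_bootstrap: int = 100,
    k: int | None = None,
    fraction: float | None = 0.2,
    seed: int = 0,
    classifier_cfg: ClassifierConfig | None = None,
):
    """Rank on train, retain top features, fit C-SVC, evaluate on test.

    The operating threshold for the confusion-derived indexes is frozen at
    the Youden point of the training scores.  Returns (EvalReport,
    ranking, model, test scores).
    """
    X_tr, y_tr = feature_matrix(train_table)
    X_te, y_te = feature_matrix(test_table)
    ranking = rank_features(X_tr, y_tr, B=n_bootstrap, seed=seed,
                            feature_names=feature_names())
    sel = select_top(ranking, fraction=fraction, k=k)
    model = train_classifier(X_tr, y_tr, classifier_cfg, seed=seed, selected=sel)
    thr = youden_threshold(predict_scores(model, X_tr), y_tr)
    scores = predict_scores(model, X_te)
    report = classification_report(scores, y_te, threshold_rule=thr)
    return report, ranking, model, scores


def _sanitize_mask(pred: np.ndarray, min_pixels: int = 16) -> np.ndarray:
    """Largest connected component of a predicted mask, or a whole-image
    fallback when the prediction is empty or degenerately small (texture
    matrices need co-occurring in-mask pixel pairs)."""
    from scipy import ndimage

    if pred.any():
        lab, n = ndimage.label(pred, structure=np.ones((3, 3), dtype=int))
        sizes = np.bincount(lab.ravel())[1:]
        pred = lab == (int(np.argmax(sizes)) + 1)
        if pred.sum() >= min_pixels:
            return pred
    return np.ones_like(pred, dtype=bool)


def degrade_mask(mask: np.ndarray, radius: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly erode or dilate the mask boundary by ``radius`` pixels.

    Emulates automatic-segmentation error of increasing severity; radius 0
    is the identity.  If erosion would empty the mask it falls back to
    dilation.
    """
    from scipy import ndimage

    if radius <= 0:
        return np.asarray(mask, dtype=bool)
    m = np.asarray(mask, dtype=bool)
    if rng.random() < 0.5:
        er = ndimage.binary_erosion(m, iterations=radius)
        return er if er.any() else ndimage.binary_dilation(m, iterations=radius)
    return ndimage.binary_dilation(m, iterations=radius)


# ---------------------------------------------------------------------------
# full runs


def _load_run_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return yaml.safe_load(fh)
    return dict(source)


def run(config, out_dir: str | Path | None = None) -> dict:
    """Execute one full strategy run; returns the report bundle as a dict.

    ``config`` is a YAML path or a mapping with keys ``mode``, ``seed``,
    ``cohort`` (CohortConfig fields), and optional ``selection``
    (n_bootstrap, fraction, k), ``texture`` (n_gray, wavelet_family),
    ``net`` (SegTrainConfig fields).  If ``out_dir`` is given the bundle
    (feature table, ranking, reports, figures, log) is written there.
    """
    cfg = _load_run_config(config)
    mode = cfg.get("mode", "radiomics-golden")
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    seed = int(cfg.get("seed", 0))
    t0 = time.time()
    log: list[str] = []

    cohort_kwargs = dict(cfg.get("cohort", {}))
    cohort_kwargs.setdefault("seed", stage_seed(seed, "synth"))
    if "image_size" in cohort_kwargs:
        cohort_kwargs["image_size"] = tuple(cohort_kwargs["image_size"])
    if "images_per_subject_range" in cohort_kwargs:
        cohort_kwargs["images_per_subject_range"] = tuple(
            cohort_kwargs["images_per_subject_range"])
    ccfg = CohortConfig(**cohort_kwargs)
    records, images, masks = cohort_in_memory(ccfg)
    from .dataio import build_manifest

    manifest = build_manifest(records)
    log.append(f"synth: {len(records)} subjects, {len(manifest)} images")
    train_m, test_m = split_by_subject(manifest, cfg.get("train_fraction", 0.7),
                                       seed=stage_seed(seed, "split"))
    log.append(f"split: {train_m['subject_id'].nunique()} train / "
               f"{test_m['subject_id'].nunique()} test subjects")

    tex_cfg = TextureConfig(**cfg.get("texture", {}))
    sel_cfg = dict(cfg.get("selection", {}))
    net_cfg = SegTrainConfig(**{**cfg.get("net", {}),
                                "seed": stage_seed(seed, "segnet")})
    bundle: dict = {"mode": mode, "seed": seed, "package_version": __version__,
                    "config_hash": _hash_config(cfg),
                    "n_train_subjects": int(train_m["subject_id"].nunique()),
                    "n_test_subjects": int(test_m["subject_id"].nunique())}

    if mode in ("radiomics-golden", "radiomics-auto"):
        test_masks = masks
        if mode == "radiomics-auto":
            seg_model, _ = train_seg_net(
                [images[p] for p in train_m["image_path"]],
                [masks[p] for p in train_m["mask_path"]],
                cfg=net_cfg,
            )
            test_masks = dict(masks)
            for _, row in test_m.iterrows():
                pred = seg_model.predict(images[row["image_path"]]) >= 0.5
                test_masks[row["mask_path"]] = _sanitize_mask(pred)
            gold = [masks[p] for p in test_m["mask_path"]]
            pred_list = [test_masks[p] for p in test_m["mask_path"]]
            seg = seg_report(pred_list, gold)
            bundle["segmentation"] = {"mean_dice": seg.mean_dice,
                                      "mean_iou": seg.mean_iou}
            log.append(f"segnet: test mean Dice {seg.mean_dice:.3f}")
        train_table = features_from_arrays(train_m, images, masks, tex_cfg)
        test_table = features_from_arrays(test_m, images, test_masks, tex_cfg)
        k = sel_cfg.get("k")
        fraction = sel_cfg.get("fraction")
        if k is None and fraction is None:
            fraction = 0.2
        report, ranking, model, scores = radiomics_fit_eval(
            train_table, test_table,
            n_bootstrap=sel_cfg.get("n_bootstrap", 100),
            k=k, fraction=fraction,
            seed=stage_seed(seed, "ranking"),
        )
        bundle["classification"] = report.as_dict()
        bundle["n_selected"] = int(len(model.selected))
        log.append(f"radiomics: test AUC {report.auc:.3f}")
        artifacts = {"features_train": train_table, "features_test": test_table,
                     "ranking": ranking}
    else:  # mtl-direct
        net_cfg = SegTrainConfig(**{**cfg.get("net", {}), "lr": cfg.get("net", {}).get("lr", 2e-4),
                                    "seed": stage_seed(seed, "mtlnet")})
        y_train = (train_m["label"] == "wmi").to_numpy(int)
        model, curve = train_mtl_net(
            [images[p] for p in train_m["image_path"]],
            [masks[p] for p in train_m["mask_path"]],
            y_train, cfg=net_cfg,
        )
        outs = [model.infer(images[p]) for p in test_m["image_path"]]
        y_test = (test_m["label"] == "wmi").to_numpy(int)
        scores = np.array([o.class_score for o in outs])
        seg = seg_report([o.mask >= 0.5 for o in outs],
                         [masks[p] for p in test_m["mask_path"]])
        train_outs = [model.infer(images[p]) for p in train_m["image_path"]]
        thr = youden_threshold([o.class_score for o in train_outs], y_train)
        report = classification_report(scores, y_test, threshold_rule=thr)
        bundle["classification"] = report.as_dict()
        bundle["segmentation"] = {"mean_dice": seg.mean_dice, "mean_iou": seg.mean_iou}
        log.append(f"mtl: test AUC {report.auc:.3f}, mean Dice {seg.mean_dice:.3f}")
        artifacts = {"loss_curve": curve}

    log.append(f"total wall time {time.time() - t0:.1f}s")
    if out_dir is not None:
        _write_bundle(Path(out_dir), bundle, artifacts, log, cfg)
    return bundle


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_bundle(out: Path, bundle: dict, artifacts: dict, log: list[str],
                  cfg: dict) -> None:
    for sub in ("features", "rankings", "models", "reports", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    with open(out / "reports" / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    with open(out / "reports" / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    for name in ("features_train", "features_test"):
        if name in artifacts:
            artifacts[name].to_csv(out / "features" / f"{name}.csv", index=False)
    if "ranking" in artifacts:
        r = artifacts["ranking"]
        pd.DataFrame({
            "feature_name": r.feature_names,
            "importance": r.importance,
            "rank": r.rank,
        }).to_csv(out / "rankings" / "ranking.csv", index=False)
    if "classification" in bundle and bundle["classification"].get("roc_points"):
        _plot_roc(out / "figures" / "roc.png", bundle["classification"]["roc_points"])


def _plot_roc(path: Path, points) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr, tpr = zip(*points)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, marker=".", lw=1)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
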