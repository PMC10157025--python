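"""Cohort manifest I/O, raster loading, and subject-level splitting.

The manifest is a plain CSV with header
``subject_id,image_path,mask_path,label,split`` (label in {normal, wmi};
split in {train, test, unassigned}).  Splitting always operates on
subjects, never on images: all frames of an infant travel together, so no
image-level information leaks between the train and test cohorts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, ConsistencyError, FormatError

MANIFEST_COLUMNS = ["subject_id", "image_path", "mask_path", "label", "split"]
VALID_LABELS = {"normal", "wmi"}
VALID_SPLITS = {"train", "test", "unassigned"}


def build_manifest(records) -> pd.DataFrame:
    """Manifest DataFrame from SubjectRecord-like objects."""
    rows = [
        (rec.subject_id, ip, mp, rec.label, "unassigned")
        for rec in records
        for ip, mp in zip(rec.image_paths, rec.mask_paths)
    ]
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    validate_manifest(manifest)
    return manifest


def validate_manifest(manifest: pd.DataFrame, root: str | Path | None = None) -> None:
    """Check schema, label consistency and (optionally) file existence."""
    if list(manifest.columns) != MANIFEST_COLUMNS:
        raise FormatError(
            f"manifest header {list(manifest.columns)} != {MANIFEST_COLUMNS}"
        )
    bad_labels = set(manifest["label"]) - VALID_LABELS
    if bad_labels:
        raise FormatError(f"unknown labels {sorted(bad_labels)}")
    bad_splits = set(manifest["split"]) - VALID_SPLITS
    if bad_splits:
        raise FormatError(f"unknown split tags {sorted(bad_splits)}")
    per_subject = manifest.groupby("subject_id")["label"].nunique()
    conflicted = per_subject[per_subject > 1]
    if len(conflicted):
        raise ConsistencyError(
            f"subjects with conflicting labels: {list(conflicted.index)}"
        )
    if manifest.duplicated().any():
        raise ConsistencyError("duplicated manifest rows")
    if root is not None:
        root = Path(root)
        for col in ("image_path", "mask_path"):
            missing = [p for p in manifest[col] if not (root / p).exists()]
            if missing:
                raise ConsistencyError(f"missing files: {missing[:5]} ...")


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    manifest = pd.read_csv(path, dtype=str)
    validate_manifest(manifest)
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def load_image(path: str | Path) -> np.ndarray:
    """8-bit grayscale raster as a 2D uint8 array."""
    return np.asarray(Image.open(path).convert("L"))


def load_mask(path: str | Path) -> np.ndarray:
    """Binary mask; strictly {0, 255} pixels after thresholding at 128."""
    arr = np.asarray(Image.open(path).convert("L"))
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 255}:
        raise FormatError(f"mask {path} is not strictly binary: values {sorted(uniq)}")
    return arr >= 128


def split_by_subject(
    manifest: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle subjects and assign floor(train_fraction * n) of them to train.

    With 158 subjects at fraction 0.7 this reproduces the 110/48 cohort
    arithmetic.  ``stratify=True`` applies the same floor rule within each
    label group instead (the unstratified rule is the default).  Returns
    (train, test) manifests with the split column updated.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(f"train_fraction {train_fraction} outside (0,1)")
    subjects = manifest["subject_id"].unique()
    if len(subjects) < 2:
        raise ConfigurationError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)

    def _pick(subs: np.ndarray) -> set[str]:
        subs = np.array(sorted(subs))
        rng.shuffle(subs)
        return set(subs[: int(np.floor(train_fraction * len(subs)))])

    if stratify:
        train_subjects: set[str] = set()
        labels = manifest.drop_duplicates("subject_id").set_index("subject_id")["label"]
        for lab in sorted(labels.unique()):
            train_subjects |= _pick(labels.index[labels == lab].to_numpy())
    else:
        train_subjects = _pick(subjects)
    if not train_subjects or len(train_subjects) == len(subjects):
        raise ConfigurationError("split leaves an empty cohort")
    out = manifest.copy()
    in_train = out["subject_id"].isin(train_subjects)
    out.loc[in_train, "split"] = "train"
    out.loc[~in_train, "split"] = "test"
    return (
        out[in_train].reset_index(drop=True),
        out[~in_train].reset_index(drop=True),
    )


def manifest_arrays(manifest: pd.DataFrame, root: str | Path):
    """Load all (image, mask) pairs of a manifest.

    Yields (row, image, mask) with paths resolved against ``root``.
    """
    root = Path(root)
    for _, row in manifest.iterrows():
        yield row, load_image(root / row["image_path"]), load_mask(root / row["mask_path"])
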