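"""Synthetic B-mode-like cranial ultrasound cohorts.

Real cranial-ultrasound cohorts of preterm infants are not publicly
deposited, so every downstream stage is exercised on synthetic frames that
emulate the statistical structure of such a study: speckle-textured 8-bit
grayscale images, one periventricular white-matter ROI per frame, 3-6
frames per subject, and roughly 20% subject-level prevalence of white
matter injury (WMI).

Image model
-----------
A frame is built in display (gray-level) units as

    B(x) = M(x) + noise_sigma * u(x),   clipped to [0, 255], uint8

where ``M`` is a smooth anatomy field (base brightness plus a low-frequency
Gaussian random surface, plus an ``effect_echo`` bump inside the ROI for
WMI subjects) and ``u`` is standardized log-compressed speckle: the log of
the magnitude of a correlated complex Gaussian field (a Rayleigh-like
envelope), standardized to zero mean / unit variance per field.  For WMI
frames the in-ROI speckle comes from an envelope whose correlation length
is scaled by ``effect_texture``, so the class signal lives in texture as
well as echogenicity.  Calibrating the echo effect in display units keeps
``effect_echo`` directly interpretable: it is the expected within-ROI mean
intensity shift between classes in final gray levels.

The ROI is a connected elliptical band (outer ellipse minus a concentric
inner one), placed off-center and jittered per subject and per frame,
covering 5-20% of pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError

LABELS = ("normal", "wmi")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic study.

    Defaults emulate the cohort structure being modeled: 158 subjects at
    20.3% WMI prevalence (32/158) with 3-6 coronal frames each.
    """

    n_subjects: int = 158
    wmi_prevalence: float = 0.203
    images_per_subject_range: tuple[int, int] = (3, 6)
    image_size: tuple[int, int] = (256, 256)
    effect_echo: float = 25.0
    effect_texture: float = 1.6
    roi_base_echo: float = 12.0
    noise_sigma: float = 18.0
    speckle_corr_len: float = 1.5
    base_level: float = 105.0
    anatomy_amplitude: float = 12.0
    anatomy_corr_len: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.wmi_prevalence <= 1.0:
            raise ConfigurationError(f"prevalence {self.wmi_prevalence} outside [0,1]")
        if min(self.image_size) < 32:
            raise ConfigurationError(f"image_size {self.image_size} below 32 pixels")
        lo, hi = self.images_per_subject_range
        if lo > hi or lo < 1:
            raise ConfigurationError(
                f"empty images_per_subject_range {self.images_per_subject_range}"
            )
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")


@dataclass
class SubjectRecord:
    subject_id: str
    label: str
    image_paths: list[str] = field(default_factory=list)
    mask_paths: list[str] = field(default_factory=list)


def _correlated_field(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with given correlation length."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr_len, mode="wrap")
    return (f - f.mean()) / f.std()


def _log_speckle(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Standardized log-envelope of a correlated complex Gaussian field."""
    re = ndimage.gaussian_filter(rng.standard_normal(shape), corr_len, mode="wrap")
    im = ndimage.gaussian_filter(rng.standard_normal(shape), corr_len, mode="wrap")
    env = np.hypot(re, im)  # Rayleigh-like magnitude
    u = np.log(env + 1e-12)  # log compression
    return (u - u.mean()) / u.std()


def _roi_band(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float],
    angle: float, inner_frac: float = 0.45
) -> np.ndarray:
    """Connected elliptical band (outer minus concentric inner ellipse)."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    q = (u / axes[0]) ** 2 + (v / axes[1]) ** 2
    return (q <= 1.0) & (q >= inner_frac**2)


def _subject_geometry(rng: np.random.Generator, shape) -> dict:
    """Per-subject base placement of the periventricular band."""
    h, w = shape
    return {
        "center": (h * rng.uniform(0.42, 0.50), w * rng.uniform(0.36, 0.44)),
        "axes": (h * rng.uniform(0.26, 0.32), w * rng.uniform(0.15, 0.19)),
        "angle": rng.uniform(-0.35, 0.35),
    }


def synthesize_image(
    subject_label: str, cfg: CohortConfig, rng: np.random.Generator,
    geometry: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair for a subject of the given label.

    Returns an 8-bit grayscale frame and a boolean ROI mask.  The same
    ``(label, cfg, rng state)`` always produces the same pair.
    """
    cfg.validate()
    if subject_label not in LABELS:
        raise ConfigurationError(f"unknown label {subject_label!r}")
    shape = tuple(cfg.image_size)
    geo = geometry or _subject_geometry(rng, shape)
    # per-frame jitter of the band
    center = (
        geo["center"][0] + rng.uniform(-3, 3),
        geo["center"][1] + rng.uniform(-3, 3),
    )
    angle = geo["angle"] + rng.uniform(-0.17, 0.17)
    mask = _roi_band(shape, center, geo["axes"], angle)
    frac = mask.mean()
    if not 0.02 <= frac <= 0.25 or not _is_connected(mask):
        raise ConfigurationError(
            f"degenerate ROI geometry (area fraction {frac:.3f})"
        )

    is_wmi = subject_label == "wmi"
    anatomy = cfg.base_level + cfg.anatomy_amplitude * _correlated_field(
        rng, shape, cfg.anatomy_corr_len
    )
    # the white-matter band is mildly echogenic in every subject (it must be
    # visible to delineate); injury adds effect_echo on top for WMI frames.
    # Soft edge, normalized so the in-ROI mean shift is exact in gray levels.
    bump = ndimage.gaussian_filter(mask.astype(np.float64), 2.0)
    bump /= bump[mask].mean()
    echo = cfg.roi_base_echo + (cfg.effect_echo if is_wmi else 0.0)
    anatomy = anatomy + echo * bump
    u_bg = _log_speckle(rng, shape, cfg.speckle_corr_len)
    roi_len = cfg.speckle_corr_len * (cfg.effect_texture if is_wmi else 1.0)
    u_roi = _log_speckle(rng, shape, roi_len)
    u = np.where(mask, u_roi, u_bg)
    img = np.clip(anatomy + cfg.noise_sigma * u, 0, 255)
    return img.astype(np.uint8), mask


def _is_connected(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1


def assign_labels(cfg: CohortConfig, rng: np.random.Generator) -> list[str]:
    """Subject labels with round-half-up(n * prevalence) WMI cases."""
    n_wmi = int(math.floor(cfg.n_subjects * cfg.wmi_prevalence + 0.5))
    labels = ["wmi"] * n_wmi + ["normal"] * (cfg.n_subjects - n_wmi)
    rng.shuffle(labels)
    return labels


def generate_cohort(cfg: CohortConfig, out_dir: str | Path):
    """Write a full synthetic cohort (PNGs + manifest) under ``out_dir``.

    Returns the manifest DataFrame.  Layout: ``images/<sid>_<k>.png`` and
    ``masks/<sid>_<k>.png`` with mask pixels in {0, 255}; the manifest has
    columns subject_id, image_path, mask_path, label, split (initially
    ``unassigned``) and paths relative to ``out_dir``.
    """
    from .dataio import build_manifest  # local import to avoid cycle

    cfg.validate()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    labels = assign_labels(cfg, rng)
    lo, hi = cfg.images_per_subject_range
    records = []
    for idx, label in enumerate(labels):
        sid = f"S{idx:04d}"
        rec = SubjectRecord(subject_id=sid, label=label)
        geo = _subject_geometry(rng, tuple(cfg.image_size))
        n_img = int(rng.integers(lo, hi + 1))
        for k in range(n_img):
            img, mask = synthesize_image(label, cfg, rng, geometry=geo)
            ip = out / "images" / f"{sid}_{k}.png"
            mp = out / "masks" / f"{sid}_{k}.png"
            Image.fromarray(img, mode="L").save(ip)
            Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(mp)
            rec.image_paths.append(str(ip.relative_to(out)))
            rec.mask_paths.append(str(mp.relative_to(out)))
        records.append(rec)
    manifest = build_manifest(records)
    from .dataio import write_manifest

    write_manifest(manifest, out / "manifest.csv")
    return manifest


def cohort_in_memory(cfg: CohortConfig):
    """Generate a cohort without touching disk.

    Returns (records, images, masks) where images/masks map a path-like key
    to arrays.  Used by tests and the pipeline when no artifact directory
    is wanted.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = assign_labels(cfg, rng)
    lo, hi = cfg.images_per_subject_range
    records, images, masks = [], {}, {}
    for idx, label in enumerate(labels):
        sid = f"S{idx:04d}"
        rec = SubjectRecord(subject_id=sid, label=label)
        geo = _subject_geometry(rng, tuple(cfg.image_size))
        n_img = int(rng.integers(lo, hi + 1))
        for k in range(n_img):
            img, mask = synthesize_image(label, cfg, rng, geometry=geo)
            key = f"{sid}_{k}"
            images[key], masks[key] = img, mask
            rec.image_paths.append(key)
            rec.mask_paths.append(key)
        records.append(rec)
    return records, images, masks


def with_seed(cfg: CohortConfig, seed: int) -> CohortConfig:
    return replace(cfg, seed=seed)
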