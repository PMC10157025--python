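"""The 70-feature texture bank and the 350-feature ROI extractor.

Seventy features are computed from a masked ROI of a single image mode:

* 16 first-order (histogram) features on raw intensities,
* 23 gray-level co-occurrence matrix (GLCM) features,
* 13 gray-level run length matrix (GLRLM) features,
* 13 gray-level size zone matrix (GLSZM) features,
* 5 neighboring gray tone difference matrix (NGTDM) features.

Running the bank on the original frame and on the four stationary-wavelet
subbands (A/H/V/D) yields the full 350-value feature vector per (image,
mask) pair, with canonical names ``{mode}_{family}_{feature}`` and mode in
``{orig, wA, wH, wV, wD}``.

Definitions follow the IBSI reference formulas under the feature names the
radiomics community uses.  Matrix families operate on intensities uniformly
discretized into ``n_gray`` levels between the ROI minimum and maximum;
first-order features use raw intensities except Entropy and Uniformity,
which are defined on the same discretization.  Two legacy naming aliases
are kept as separate columns (Homogeneity1 = Id and Homogeneity2 = Idm)
because the 23-feature GLCM battery enumerates all four names.

Degenerate denominators (constant ROI, single gray level) follow explicit
conventions with ``eps = 1e-6`` rather than returning NaN; each is noted on
the feature concerned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import RoiError, ShapeError
from .wavelets import wavelet_modes

MODES = ("orig", "wA", "wH", "wV", "wD")

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "Maximum", "Mean",
    "Median", "InterquartileRange", "StandardDeviation",
    "MeanAbsoluteDeviation", "Range", "RootMeanSquared", "Uniformity",
    "Variance", "Kurtosis", "Skewness",
)
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "SumVariance", "DifferenceAverage", "Correlation",
    "DifferenceEntropy", "Homogeneity1", "Homogeneity2", "SumAverage",
    "Dissimilarity", "JointEnergy", "Imc1", "Imc2",
    "InverseDifferenceMoment", "JointEntropy",
    "MaximalCorrelationCoefficient", "InverseDifference", "InverseVariance",
    "MaximumProbability", "DifferenceVariance",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "RunLengthNonUniformity", "RunPercentage", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis", "GrayLevelVariance",
    "RunLengthVariance",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "SizeZoneNonUniformity", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FAMILIES = (
    ("firstorder", FIRSTORDER_NAMES),
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)

# offsets for the four in-plane directions 0deg, 45deg, 90deg, 135deg
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def feature_names() -> list[str]:
    """The canonical 350-name vector layout (mode-major, Table-ordered)."""
    return [
        f"{mode}_{fam}_{name}"
        for mode in MODES
        for fam, names in FAMILIES
        for name in names
    ]


@dataclass
class TextureConfig:
    """Knobs of the feature bank.

    n_gray
        Gray-level count for discretization (uniform ROI min-max binning).
    glcm_distance
        Pixel offset distance for co-occurrence pairs.
    wavelet_family
        pywt wavelet name feeding the four subband modes.
    pixel_area
        Physical area of one pixel; scales TotalEnergy only.
    eps
        Guard for vanishing denominators; Coarseness on a flat ROI is
        reported as 1/eps.
    """

    n_gray: int = 32
    glcm_distance: int = 1
    wavelet_family: str = "haar"
    pixel_area: float = 1.0
    eps: float = 1e-6


@dataclass
class QuantizedRoi:
    """ROI intensities discretized to integer levels 1..n_gray (0 outside)."""

    levels: np.ndarray  # 2D int array, 0 = outside mask
    n_gray: int
    n_pixels: int
    mask: np.ndarray = field(repr=False)


def _check_pair(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask).astype(bool)
    if img.shape != msk.shape:
        raise ShapeError(f"image {img.shape} vs mask {msk.shape}")
    if not msk.any():
        raise RoiError("empty ROI mask")
    return img, msk


def quantize_roi(image_mode: np.ndarray, mask: np.ndarray, n_gray: int = 32) -> QuantizedRoi:
    """Uniformly bin in-mask intensities into ``n_gray`` levels.

    Bin edges split [ROI min, ROI max] into equal-width intervals; the top
    edge is inclusive.  A constant ROI maps entirely to level 1.
    """
    img, msk = _check_pair(image_mode, mask)
    if n_gray < 2:
        raise ValueError(f"n_gray must be >= 2, got {n_gray}")
    vals = img[msk]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(img.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor((img[msk] - lo) / (hi - lo) * n_gray).astype(np.int32) + 1
        np.clip(lv, 1, n_gray, out=lv)
        levels[msk] = lv
    else:
        levels[msk] = 1
    return QuantizedRoi(levels=levels, n_gray=n_gray, n_pixels=int(msk.sum()), mask=msk)


# ---------------------------------------------------------------------------
# first order


def first_order_features(
    image_mode: np.ndarray, mask: np.ndarray, n_gray: int = 32, pixel_area: float = 1.0
) -> dict[str, float]:
    """The 16 histogram features on raw in-mask intensities.

    Entropy and Uniformity are computed on the ``n_gray``-bin discretized
    histogram.  Skewness and Kurtosis use population moments and are 0 by
    convention on a constant ROI.
    """
    img, msk = _check_pair(image_mode, mask)
    x = img[msk]
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = float(np.mean(dev**2))
    energy = float(np.sum(x**2))
    q = quantize_roi(img, msk, n_gray)
    counts = np.bincount(q.levels[msk], minlength=n_gray + 1)[1:]
    p = counts[counts > 0] / n
    out = {
        "Energy": energy,
        "TotalEnergy": energy * pixel_area,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "StandardDeviation": float(np.sqrt(m2)),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "Range": float(x.max() - x.min()),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Uniformity": float(np.sum(p**2)),
        "Variance": m2,
        "Kurtosis": float(np.mean(dev**4) / m2**2) if m2 > 0 else 0.0,
        "Skewness": float(np.mean(dev**3) / m2**1.5) if m2 > 0 else 0.0,
    }
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrices(
    q: QuantizedRoi, distance: int = 1, directions=DIRECTIONS
) -> list[np.ndarray]:
    """Symmetric normalized co-occurrence matrix per direction.

    Only pixel pairs with both ends inside the mask are counted.
    Directions with no valid pair are dropped; if none remains (single
    pixel ROI) an error is raised.
    """
    lv = q.levels
    ng = q.n_gray
    mats = []
    for dr, dc in directions:
        dr, dc = dr * distance, dc * distance
        a, b = _shift_pairs(lv, dr, dc)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        i, j = a[valid] - 1, b[valid] - 1
        m = np.zeros((ng, ng))
        np.add.at(m, (i, j), 1.0)
        m += m.T  # symmetric accumulation
        mats.append(m / m.sum())
    if not mats:
        raise RoiError("ROI has no co-occurring pixel pair at any angle")
    return mats


def _shift_pairs(lv: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (source, neighbor) level arrays for offset (dr, dc)."""
    h, w = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = lv[r0:r1, c0:c1]
    dst = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return src.ravel(), dst.ravel()


def _glcm_single(p: np.ndarray, eps: float) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sigx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))
    # diagonal (difference) and cross-diagonal (sum) projections
    k_diff = np.arange(ng, dtype=np.float64)  # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    outer = px[:, None] * py[None, :]
    both = nz & (outer > 0)
    hxy1 = float(-np.sum(p[both] * np.log2(outer[both])))
    hxy2 = float(-np.sum(outer[outer > 0] * np.log2(outer[outer > 0])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))

    da = float(np.sum(k_diff * p_diff))
    sa = float(np.sum(k_sum * p_sum))
    corr = 1.0 if sigx * sigy < eps else float(
        (np.sum(ii * jj * p) - mux * muy) / (sigx * sigy)
    )
    imc1 = 0.0 if max(hx, hy) < eps else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    inv_diff = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    off = ii != jj
    inv_var = float(np.sum(p[off] / (ii - jj)[off] ** 2))
    pd = p_diff[p_diff > 0]
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mux,
        "ClusterProminence": float(np.sum((ii + jj - mux - muy) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mux - muy) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mux - muy) ** 2 * p)),
        "SumVariance": float(np.sum((k_sum - sa) ** 2 * p_sum)),
        "DifferenceAverage": da,
        "Correlation": corr,
        "DifferenceEntropy": float(-np.sum(pd * np.log2(pd))),
        "Homogeneity1": inv_diff,
        "Homogeneity2": idm,
        "SumAverage": sa,
        "Dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "JointEnergy": float(np.sum(p**2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseDifferenceMoment": idm,
        "JointEntropy": hxy,
        "MaximalCorrelationCoefficient": _mcc(p, px, py),
        "InverseDifference": inv_diff,
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
    }


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue magnitude of the Q matrix.

    Restricted to occupied gray levels; 1 by convention when fewer than two
    levels occur (Q is then the scalar 1).
    """
    occ = (px > 0) & (py > 0)
    if occ.sum() < 2:
        return 1.0
    sub = p[np.ix_(occ, occ)]
    a = sub / px[occ][:, None]
    b = sub / py[occ][None, :]
    qmat = a @ b.T
    ev = np.abs(np.linalg.eigvals(qmat))
    ev.sort()
    return float(np.sqrt(max(0.0, min(1.0, ev[-2]))))


def glcm_features(
    q: QuantizedRoi, distance: int = 1, directions=DIRECTIONS, eps: float = 1e-6
) -> dict[str, float]:
    """The 23 co-occurrence features, averaged over directions.

    Each feature is evaluated on the per-direction normalized symmetric
    matrix and the per-direction values are averaged (feature-level
    averaging), so anisotropy is smoothed at the feature level.
    """
    mats = glcm_matrices(q, distance, directions)
    per_angle = [_glcm_single(m, eps) for m in mats]
    return {k: float(np.mean([d[k] for d in per_angle])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def _lines(arr: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    """Image scan lines along a direction (sign-insensitive)."""
    dr, dc = abs(direction[0]), (direction[1] if direction[0] >= 0 else -direction[1])
    if (dr, dc) == (0, 1):
        return list(arr)
    if (dr, dc) == (1, 0):
        return list(arr.T)
    h, w = arr.shape
    if (dr, dc) == (1, 1):
        return [np.diagonal(arr, off) for off in range(-(h - 1), w)]
    # (1, -1): anti-diagonals
    fl = np.fliplr(arr)
    return [np.diagonal(fl, off) for off in range(-(h - 1), w)]


def glrlm_matrix(q: QuantizedRoi, direction: tuple[int, int]) -> np.ndarray:
    """Run-length matrix R[level-1, length-1]; out-of-mask pixels break runs."""
    lv = q.levels
    joined = np.concatenate(
        [np.concatenate((line, [0])) for line in _lines(lv, direction)]
    )
    change = np.flatnonzero(np.diff(joined) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [joined.size - 1]))
    run_val = joined[starts]
    run_len = ends - starts + 1
    keep = run_val > 0
    run_val, run_len = run_val[keep], run_len[keep]
    mat = np.zeros((q.n_gray, int(run_len.max()) if run_len.size else 1))
    np.add.at(mat, (run_val - 1, run_len - 1), 1.0)
    return mat


def _rlm_features(mat: np.ndarray, n_pixels: int) -> dict[str, float]:
    ng, nl = mat.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    nr = mat.sum()
    g = mat.sum(axis=1)
    r = mat.sum(axis=0)
    pm = mat / nr
    mu_i = float(np.sum(pm * i))
    mu_j = float(np.sum(pm * j))
    return {
        "ShortRunEmphasis": float(np.sum(mat / j**2) / nr),
        "LongRunEmphasis": float(np.sum(mat * j**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(g**2) / nr),
        "RunLengthNonUniformity": float(np.sum(r**2) / nr),
        "RunPercentage": float(nr / n_pixels),
        "LowGrayLevelRunEmphasis": float(np.sum(mat / i**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(mat * i**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(mat / (i**2 * j**2)) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(mat * i**2 / j**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(mat * j**2 / i**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(mat * i**2 * j**2) / nr),
        "GrayLevelVariance": float(np.sum(pm * (i - mu_i) ** 2)),
        "RunLengthVariance": float(np.sum(pm * (j - mu_j) ** 2)),
    }


def glrlm_features(q: QuantizedRoi, directions=DIRECTIONS) -> dict[str, float]:
    """The 13 run-length features averaged over the four run directions."""
    per_dir = [_rlm_features(glrlm_matrix(q, d), q.n_pixels) for d in directions]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(q: QuantizedRoi) -> np.ndarray:
    """Size-zone matrix Z[level-1, size-1]; zones are 8-connected components."""
    structure = np.ones((3, 3), dtype=int)
    sizes: list[tuple[int, int]] = []
    for level in np.unique(q.levels[q.levels > 0]):
        lab, nlab = ndimage.label(q.levels == level, structure=structure)
        if nlab:
            cnt = np.bincount(lab.ravel())[1:]
            sizes.extend((int(level), int(s)) for s in cnt)
    max_size = max(s for _, s in sizes)
    mat = np.zeros((q.n_gray, max_size))
    for level, s in sizes:
        mat[level - 1, s - 1] += 1.0
    return mat


def glszm_features(q: QuantizedRoi) -> dict[str, float]:
    """The 13 size-zone features (orientation-free single matrix)."""
    mat = glszm_matrix(q)
    f = _rlm_features(mat, q.n_pixels)
    # same algebra as GLRLM with runs -> zones; rename to the zone battery
    return {
        "SmallAreaEmphasis": f["ShortRunEmphasis"],
        "LargeAreaEmphasis": f["LongRunEmphasis"],
        "GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
        "SizeZoneNonUniformity": f["RunLengthNonUniformity"],
        "ZonePercentage": f["RunPercentage"],
        "GrayLevelVariance": f["GrayLevelVariance"],
        "ZoneVariance": f["RunLengthVariance"],
        "LowGrayLevelZoneEmphasis": f["LowGrayLevelRunEmphasis"],
        "HighGrayLevelZoneEmphasis": f["HighGrayLevelRunEmphasis"],
        "SmallAreaLowGrayLevelEmphasis": f["ShortRunLowGrayLevelEmphasis"],
        "SmallAreaHighGrayLevelEmphasis": f["ShortRunHighGrayLevelEmphasis"],
        "LargeAreaLowGrayLevelEmphasis": f["LongRunLowGrayLevelEmphasis"],
        "LargeAreaHighGrayLevelEmphasis": f["LongRunHighGrayLevelEmphasis"],
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(q: QuantizedRoi, delta: int = 1):
    """Per-level counts n_i, probabilities p_i, and difference sums s_i.

    For every in-mask pixel the mean level of its in-mask Chebyshev
    neighbors (radius ``delta``) is computed; out-of-mask neighbors are
    excluded from the mean.  Pixels with no valid neighbor are skipped.
    """
    lv = q.levels.astype(np.float64)
    inm = q.mask.astype(np.float64)
    k = 2 * delta + 1
    kernel = np.ones((k, k))
    kernel[delta, delta] = 0.0
    nbr_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.correlate(inm, kernel, mode="constant", cval=0.0)
    valid = q.mask & (nbr_cnt > 0)
    mean_nbr = np.zeros_like(lv)
    mean_nbr[valid] = nbr_sum[valid] / nbr_cnt[valid]
    diffs = np.abs(lv - mean_nbr)
    ng = q.n_gray
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    idx = q.levels[valid] - 1
    np.add.at(n_i, idx, 1.0)
    np.add.at(s_i, idx, diffs[valid])
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(q: QuantizedRoi, delta: int = 1, eps: float = 1e-6) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength.

    A perfectly flat neighborhood structure gives Coarseness = 1/eps (the
    capped convention) and zero for the other four.
    """
    n_i, p_i, s_i = ngtdm_table(q, delta)
    n_tot = n_i.sum()
    if n_tot == 0:
        raise RoiError("no ROI pixel has an in-mask neighbor")
    lv = np.arange(1, q.n_gray + 1, dtype=np.float64)
    occ = p_i > 0
    ngp = int(occ.sum())
    pi, li, si = p_i[occ], lv[occ], s_i[occ]
    dot = float(np.sum(pi * si))
    coarseness = 1.0 / dot if dot > eps else 1.0 / eps

    if ngp > 1:
        dmat = (li[:, None] - li[None, :]) ** 2
        contrast = (
            float(np.sum(pi[:, None] * pi[None, :] * dmat)) / (ngp * (ngp - 1))
        ) * (float(s_i.sum()) / n_tot)
        ipi = li * pi
        denom_busy = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = dot / denom_busy if denom_busy > eps else 0.0
        num = np.abs(li[:, None] - li[None, :]) * (
            (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
            / (pi[:, None] + pi[None, :])
        )
        complexity = float(num.sum()) / n_tot
        s_sum = float(s_i.sum())
        strength = (
            float(np.sum((pi[:, None] + pi[None, :]) * dmat)) / s_sum
            if s_sum > eps
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# full vector


def mode_features(image_mode: np.ndarray, mask: np.ndarray, cfg: TextureConfig) -> dict[str, float]:
    """All 70 features of one image mode, unprefixed."""
    q = quantize_roi(image_mode, mask, cfg.n_gray)
    out: dict[str, float] = {}
    out.update(first_order_features(image_mode, mask, cfg.n_gray, cfg.pixel_area))
    out.update(glcm_features(q, cfg.glcm_distance, eps=cfg.eps))
    out.update(glrlm_features(q))
    out.update(glszm_features(q))
    out.update(ngtdm_features(q, eps=cfg.eps))
    return out


def extract_feature_vector(
    image: np.ndarray, mask: np.ndarray, cfg: TextureConfig | None = None
) -> dict[str, float]:
    """The full 350-feature vector of one (image, mask) pair.

    Runs the 70-feature bank on the original image and on each of the four
    stationary-wavelet subbands; keys follow the canonical
    ``{mode}_{family}_{feature}`` scheme in :func:`feature_names` order.
    """
    cfg = cfg or TextureConfig()
    img, msk = _check_pair(image, mask)
    modeset = wavelet_modes(img, cfg.wavelet_family)
    planes = {"orig": img, **modeset.as_dict()}
    vec: dict[str, float] = {}
    for mode in MODES:
        try:
            feats = mode_features(planes[mode], msk, cfg)
        except Exception as exc:  # tag the offending mode for diagnosis
            raise type(exc)(f"[mode {mode}] {exc}") from exc
        for fam, names in FAMILIES:
            for name in names:
                vec[f"{mode}_{fam}_{name}"] = feats[name]
    assert len(vec) == 350
    return vec
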