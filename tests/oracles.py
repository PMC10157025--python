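"""Independent brute-force oracles for the texture-matrix features.

Everything here is written as plain Python loops, deliberately sharing no
code path with the package: matrices are built by explicit pixel walking
and features by direct formula transcription, so agreement with the
vectorized implementation is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np

DIRS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def glcm_matrix_bf(levels: np.ndarray, offset, n_gray: int) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair walking."""
    h, w = levels.shape
    m = np.zeros((n_gray, n_gray))
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0:
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and levels[r2, c2] > 0:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                m[i, j] += 1
                m[j, i] += 1
    return m


def glcm_features_bf(levels, n_gray, distance=1, eps=1e-6):
    """Per-direction features from loop-built matrices, then averaged."""
    per = []
    for dr, dc in DIRS:
        m = glcm_matrix_bf(levels, (dr * distance, dc * distance), n_gray)
        if m.sum() == 0:
            continue
        per.append(_glcm_feats_from_matrix(m / m.sum(), eps))
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def _glcm_feats_from_matrix(p, eps):
    ng = p.shape[0]
    idx = range(1, ng + 1)
    px = [sum(p[i - 1, j - 1] for j in idx) for i in idx]
    py = [sum(p[i - 1, j - 1] for i in idx) for j in idx]
    mux = sum(i * px[i - 1] for i in idx)
    muy = sum(j * py[j - 1] for j in idx)
    sigx = math.sqrt(sum((i - mux) ** 2 * px[i - 1] for i in idx))
    sigy = math.sqrt(sum((j - muy) ** 2 * py[j - 1] for j in idx))
    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng - 1)
    for i in idx:
        for j in idx:
            pdiff[abs(i - j)] += p[i - 1, j - 1]
            psum[i + j - 2] += p[i - 1, j - 1]
    da = sum(k * pdiff[k] for k in range(ng))
    sa = sum((k + 2) * psum[k] for k in range(len(psum)))
    hxy = -sum(
        p[i - 1, j - 1] * math.log2(p[i - 1, j - 1])
        for i in idx for j in idx if p[i - 1, j - 1] > 0
    )
    hxy1 = -sum(
        p[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in idx for j in idx
        if p[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in idx for j in idx if px[i - 1] * py[j - 1] > 0
    )
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    hy = -sum(v * math.log2(v) for v in py if v > 0)
    corr = 1.0 if sigx * sigy < eps else (
        sum(i * j * p[i - 1, j - 1] for i in idx for j in idx) - mux * muy
    ) / (sigx * sigy)
    inv_diff = sum(p[i - 1, j - 1] / (1 + abs(i - j)) for i in idx for j in idx)
    idm = sum(p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx)
    return {
        "Autocorrelation": sum(i * j * p[i - 1, j - 1] for i in idx for j in idx),
        "JointAverage": mux,
        "ClusterProminence": sum(
            (i + j - mux - muy) ** 4 * p[i - 1, j - 1] for i in idx for j in idx),
        "ClusterShade": sum(
            (i + j - mux - muy) ** 3 * p[i - 1, j - 1] for i in idx for j in idx),
        "ClusterTendency": sum(
            (i + j - mux - muy) ** 2 * p[i - 1, j - 1] for i in idx for j in idx),
        "SumVariance": sum(
            (k + 2 - sa) ** 2 * psum[k] for k in range(len(psum))),
        "DifferenceAverage": da,
        "Correlation": corr,
        "DifferenceEntropy": -sum(
            v * math.log2(v) for v in pdiff if v > 0),
        "Homogeneity1": inv_diff,
        "Homogeneity2": idm,
        "SumAverage": sa,
        "Dissimilarity": sum(
            abs(i - j) * p[i - 1, j - 1] for i in idx for j in idx),
        "JointEnergy": sum(p[i - 1, j - 1] ** 2 for i in idx for j in idx),
        "Imc1": 0.0 if max(hx, hy) < eps else (hxy - hxy1) / max(hx, hy),
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "InverseDifferenceMoment": idm,
        "JointEntropy": hxy,
        "MaximalCorrelationCoefficient": _mcc_bf(p, px, py),
        "InverseDifference": inv_diff,
        "InverseVariance": sum(
            p[i - 1, j - 1] / (i - j) ** 2 for i in idx for j in idx if i != j),
        "MaximumProbability": p.max(),
        "DifferenceVariance": sum(
            (k - da) ** 2 * pdiff[k] for k in range(ng)),
    }


def _mcc_bf(p, px, py):
    occ = [i for i in range(len(px)) if px[i] > 0 and py[i] > 0]
    if len(occ) < 2:
        return 1.0
    q = np.zeros((len(occ), len(occ)))
    for a, i in enumerate(occ):
        for b, j in enumerate(occ):
            q[a, b] = sum(
                p[i, k] * p[j, k] / (px[i] * py[k]) for k in occ
            )
    ev = sorted(abs(np.linalg.eigvals(q)))
    return math.sqrt(max(0.0, min(1.0, ev[-2])))


def runs_bf(levels: np.ndarray, direction) -> list[tuple[int, int]]:
    """All maximal runs (level, length) along one direction, by walking."""
    h, w = levels.shape
    dr, dc = abs(direction[0]), direction[1] if direction[0] >= 0 else -direction[1]
    runs = []
    # enumerate line start points
    starts = []
    if (dr, dc) == (0, 1):
        starts = [(r, 0) for r in range(h)]
    elif (dr, dc) == (1, 0):
        starts = [(0, c) for c in range(w)]
    elif (dr, dc) == (1, 1):
        starts = [(0, c) for c in range(w)] + [(r, 0) for r in range(1, h)]
    else:  # (1, -1)
        starts = [(0, c) for c in range(w)] + [(r, w - 1) for r in range(1, h)]
    for r0, c0 in starts:
        r, c = r0, c0
        cur, length = 0, 0
        while 0 <= r < h and 0 <= c < w:
            v = levels[r, c]
            if v == cur and v > 0:
                length += 1
            else:
                if cur > 0:
                    runs.append((cur, length))
                cur, length = v, (1 if v > 0 else 0)
            r, c = r + dr, c + dc
        if cur > 0:
            runs.append((cur, length))
    return runs


def glrlm_features_bf(levels, n_gray, n_pixels):
    per = []
    for d in DIRS:
        runs = runs_bf(levels, d)
        nr = len(runs)
        feats = {
            "ShortRunEmphasis": sum(1 / ln**2 for _, ln in runs) / nr,
            "LongRunEmphasis": sum(ln**2 for _, ln in runs) / nr,
            "GrayLevelNonUniformity": sum(
                sum(1 for lv, _ in runs if lv == g) ** 2
                for g in range(1, n_gray + 1)) / nr,
            "RunLengthNonUniformity": sum(
                sum(1 for _, ln in runs if ln == j) ** 2
                for j in set(ln for _, ln in runs)) / nr,
            "RunPercentage": nr / n_pixels,
            "LowGrayLevelRunEmphasis": sum(1 / lv**2 for lv, _ in runs) / nr,
            "HighGrayLevelRunEmphasis": sum(lv**2 for lv, _ in runs) / nr,
            "ShortRunLowGrayLevelEmphasis": sum(
                1 / (lv**2 * ln**2) for lv, ln in runs) / nr,
            "ShortRunHighGrayLevelEmphasis": sum(
                lv**2 / ln**2 for lv, ln in runs) / nr,
            "LongRunLowGrayLevelEmphasis": sum(
                ln**2 / lv**2 for lv, ln in runs) / nr,
            "LongRunHighGrayLevelEmphasis": sum(
                (lv * ln) ** 2 for lv, ln in runs) / nr,
        }
        mu_i = sum(lv for lv, _ in runs) / nr
        mu_j = sum(ln for _, ln in runs) / nr
        feats["GrayLevelVariance"] = sum((lv - mu_i) ** 2 for lv, _ in runs) / nr
        feats["RunLengthVariance"] = sum((ln - mu_j) ** 2 for _, ln in runs) / nr
        per.append(feats)
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def zones_bf(levels: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of every 8-connected equal-level zone, by flood fill."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            lv = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2]
                                and levels[r2, c2] == lv):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((int(lv), size))
    return zones


def glszm_features_bf(levels, n_gray, n_pixels):
    zones = zones_bf(levels)
    nz = len(zones)
    mu_i = sum(lv for lv, _ in zones) / nz
    mu_s = sum(s for _, s in zones) / nz
    return {
        "SmallAreaEmphasis": sum(1 / s**2 for _, s in zones) / nz,
        "LargeAreaEmphasis": sum(s**2 for _, s in zones) / nz,
        "GrayLevelNonUniformity": sum(
            sum(1 for lv, _ in zones if lv == g) ** 2
            for g in range(1, n_gray + 1)) / nz,
        "SizeZoneNonUniformity": sum(
            sum(1 for _, s in zones if s == j) ** 2
            for j in set(s for _, s in zones)) / nz,
        "ZonePercentage": nz / n_pixels,
        "GrayLevelVariance": sum((lv - mu_i) ** 2 for lv, _ in zones) / nz,
        "ZoneVariance": sum((s - mu_s) ** 2 for _, s in zones) / nz,
        "LowGrayLevelZoneEmphasis": sum(1 / lv**2 for lv, _ in zones) / nz,
        "HighGrayLevelZoneEmphasis": sum(lv**2 for lv, _ in zones) / nz,
        "SmallAreaLowGrayLevelEmphasis": sum(
            1 / (lv**2 * s**2) for lv, s in zones) / nz,
        "SmallAreaHighGrayLevelEmphasis": sum(
            lv**2 / s**2 for lv, s in zones) / nz,
        "LargeAreaLowGrayLevelEmphasis": sum(
            s**2 / lv**2 for lv, s in zones) / nz,
        "LargeAreaHighGrayLevelEmphasis": sum(
            (lv * s) ** 2 for lv, s in zones) / nz,
    }


def ngtdm_features_bf(levels, n_gray, eps=1e-6):
    """Per-pixel neighborhood walk then direct formula transcription."""
    h, w = levels.shape
    n_i = [0.0] * (n_gray + 1)
    s_i = [0.0] * (n_gray + 1)
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0:
                continue
            nbrs = [
                levels[r2, c2]
                for r2 in range(r - 1, r + 2)
                for c2 in range(c - 1, c + 2)
                if (r2, c2) != (r, c) and 0 <= r2 < h and 0 <= c2 < w
                and levels[r2, c2] > 0
            ]
            if not nbrs:
                continue
            n_i[levels[r, c]] += 1
            s_i[levels[r, c]] += abs(levels[r, c] - sum(nbrs) / len(nbrs))
    n_tot = sum(n_i)
    p_i = [v / n_tot for v in n_i]
    occ = [i for i in range(1, n_gray + 1) if p_i[i] > 0]
    ngp = len(occ)
    dot = sum(p_i[i] * s_i[i] for i in occ)
    coarseness = 1.0 / dot if dot > eps else 1.0 / eps
    if ngp > 1:
        contrast = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in occ for j in occ)
            / (ngp * (ngp - 1))
        ) * (sum(s_i) / n_tot)
        denom = sum(abs(i * p_i[i] - j * p_i[j]) for i in occ for j in occ)
        busyness = dot / denom if denom > eps else 0.0
        complexity = sum(
            abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
            for i in occ for j in occ
        ) / n_tot
        s_sum = sum(s_i)
        strength = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in occ for j in occ) / s_sum
            if s_sum > eps else 0.0
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


def auc_bf(scores, labels) -> float:
    """O(n^2) pairwise Mann-Whitney AUC with half-credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def swt_subband_bf(image: np.ndarray, row_taps, col_taps) -> np.ndarray:
    """Separable correlation with symmetric padding, per-pixel loops."""
    img = np.asarray(image, dtype=float)

    def corr_axis0(a, taps):
        n = len(taps)
        left = (n - 1) // 2
        pad = np.pad(a, ((left, n - 1 - left), (0, 0)), mode="symmetric")
        out = np.zeros_like(a)
        for r in range(a.shape[0]):
            for c in range(a.shape[1]):
                out[r, c] = sum(pad[r + t, c] * taps[t] for t in range(n))
        return out

    tmp = corr_axis0(img, row_taps)
    return corr_axis0(tmp.T, col_taps).T
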