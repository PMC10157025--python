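"""Single-level undecimated 2D wavelet decomposition.

The texture bank is computed on five image modes: the original grayscale
frame plus the approximation (A) and horizontal/vertical/diagonal detail
(H, V, D) subbands of a one-level wavelet transform.  The transform here is
undecimated (stationary), so every subband keeps the shape of the source
image and the ROI mask indexes all five modes without resampling.

Subband construction is separable: with ``lo``/``hi`` the decomposition
filters of the chosen family (taken from :mod:`pywt`),

    A = lo_rows * lo_cols      H = lo_rows * hi_cols
    V = hi_rows * lo_cols      D = hi_rows * hi_cols

where ``*_rows`` / ``*_cols`` denote 1D correlation along axis 0 / axis 1
with symmetric (mirror) boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ShapeError

MODE_TAGS = ("wA", "wH", "wV", "wD")


@dataclass(frozen=True)
class ModeSet:
    """The four same-shape subbands of a one-level stationary transform."""

    A: np.ndarray
    H: np.ndarray
    V: np.ndarray
    D: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"wA": self.A, "wH": self.H, "wV": self.V, "wD": self.D}


def _correlate_axis(arr: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """1D correlation along ``axis`` with symmetric padding, same shape out.

    The window for output index i covers input indices i .. i+len(taps)-1 of
    the array padded by len(taps)-1 samples split between both ends (left
    gets the smaller half), which centers even-length filters like Haar's.
    """
    n_taps = len(taps)
    left = (n_taps - 1) // 2
    right = n_taps - 1 - left
    pad = [(0, 0)] * arr.ndim
    pad[axis] = (left, right)
    padded = np.pad(arr, pad, mode="symmetric")
    moved = np.moveaxis(padded, axis, -1)
    windows = np.lib.stride_tricks.sliding_window_view(moved, n_taps, axis=-1)
    out = windows @ taps
    return np.moveaxis(out, -1, axis)


def wavelet_modes(image: np.ndarray, family: str = "haar") -> ModeSet:
    """Decompose ``image`` into A/H/V/D subbands at the original resolution.

    Parameters
    ----------
    image
        2D array; converted to float64.
    family
        Any discrete wavelet name understood by :mod:`pywt` (default Haar).

    H captures horizontal structure (low-pass rows, high-pass columns),
    V vertical structure, D diagonal.  A constant image therefore yields
    identically zero H, V, D and a constant A equal to the input value
    scaled by the squared sum of the low-pass taps.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ShapeError(f"expected a 2D image, got ndim={img.ndim}")
    wav = pywt.Wavelet(family)
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)
    if min(img.shape) < len(lo):
        raise ShapeError(
            f"image {img.shape} smaller than the '{family}' filter length {len(lo)}"
        )
    lo_r = _correlate_axis(img, lo, axis=0)
    hi_r = _correlate_axis(img, hi, axis=0)
    return ModeSet(
        A=_correlate_axis(lo_r, lo, axis=1),
        H=_correlate_axis(lo_r, hi, axis=1),
        V=_correlate_axis(hi_r, lo, axis=1),
        D=_correlate_axis(hi_r, hi, axis=1),
    )
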