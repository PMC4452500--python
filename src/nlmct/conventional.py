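"""Per-offset decomposition of non-local means.

The filter is broken into a cascade of four plane-wide passes repeated for
every offset of the full search window: a difference pass (per-pixel
intensity difference to the shifted partner), a weight pass (patch
similarity from kernel-weighted absolute differences), an accumulation pass
(running weight and weighted-intensity sums U3, U4), and a final
normalization U4/U3.  This mirrors a straight pixel-parallel GPU port of
the filter and is the baseline the row-cached engine is measured against:
its charged cost per pixel is |N|((2B+1)^2 + 2) + 1.

The "parallel" passes are realized as deterministic whole-plane sweeps;
results are independent of any internal chunking, and the offset order is
the same row-major order the naive oracle uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import (
    NLMParams,
    Offset,
    OpCount,
    enumerate_offsets,
    gaussian_kernel,
    inbounds_mask,
    shifted_values,
    validate_image,
)

__all__ = [
    "PassState",
    "diff_pass",
    "weight_pass",
    "accumulate_pass",
    "finalize",
    "nlm_filter_conventional",
]


@dataclass
class PassState:
    """State planes threaded through the per-offset cascade.

    U1, U2 are per-offset scratch (signed differences, weights); U3, U4 are
    the running weight and weighted-intensity sums initialized to zero.
    """

    U1: np.ndarray | None
    U2: np.ndarray | None
    U3: np.ndarray
    U4: np.ndarray

    @classmethod
    def zeros(cls, m: int, n: int) -> "PassState":
        return cls(U1=None, U2=None, U3=np.zeros((m, n)), U4=np.zeros((m, n)))


def _check_offset(off: Offset, T: int | None) -> None:
    ix, iy = off
    if T is not None and (abs(ix) > T or abs(iy) > T):
        raise ValueError(f"offset {off} outside the search radius T={T}")


def diff_pass(img: np.ndarray, off: Offset, B: int = 0, T: int | None = None) -> np.ndarray:
    """Signed center-pixel differences Y(p) - Y(p + off) for the offset.

    Computed on the B-padded domain — shape ``(m+2B, n+2B)``, element
    ``[y+B, x+B]`` for pixel ``(x, y)`` — so the weight pass can read it at
    patch-shifted positions without leaving the array.  Values outside the
    image come from the edge-duplicating mirror pad.
    """
    img = validate_image(img)
    _check_offset(off, T)
    ix, iy = off
    pad = B + max(abs(ix), abs(iy))
    P = np.pad(img, pad, mode="symmetric") if pad else img.copy()
    m, n = img.shape
    e = pad - B  # margin left around the B-padded domain
    center = P[e : e + m + 2 * B, e : e + n + 2 * B]
    partner = P[e + iy : e + iy + m + 2 * B, e + ix : e + ix + n + 2 * B]
    return center - partner


def weight_pass(
    img: np.ndarray,
    off: Offset,
    kernel: np.ndarray,
    params: NLMParams,
    U1: np.ndarray | None = None,
) -> np.ndarray:
    """Patch-similarity weights w(p, p + off) for every pixel.

    Reads the signed difference plane at patch-shifted positions and folds
    it with the kernel: dist(p) = sum_{dx,dy} |U1(p + (dx,dy))| G(dx,dy).
    Pixels whose partner falls outside the image record 0 — they contribute
    nothing under window truncation.
    """
    img = validate_image(img)
    _check_offset(off, params.T)
    B = params.B
    if kernel.shape != (2 * B + 1, 2 * B + 1):
        raise ValueError(f"kernel shape {kernel.shape} does not match patch radius B={B}")
    m, n = img.shape
    if U1 is None:
        U1 = diff_pass(img, off, B=B, T=params.T)
    elif U1.shape != (m + 2 * B, n + 2 * B):
        raise ValueError(f"difference plane shape {U1.shape} does not match image and B={B}")
    dist = np.zeros((m, n))
    for dy in range(-B, B + 1):
        for dx in range(-B, B + 1):
            dist += np.abs(U1[B + dy : B + dy + m, B + dx : B + dx + n]) * kernel[dx + B, dy + B]
    U2 = np.exp(-dist / (params.h**2 * (2 * B + 1) ** 2))
    U2[~inbounds_mask(m, n, off)] = 0.0
    return U2


def accumulate_pass(state: PassState, img: np.ndarray, off: Offset) -> PassState:
    """Fold the current weight plane into the running sums U3 and U4."""
    img = validate_image(img)
    if state.U2 is None:
        raise ValueError("weight plane U2 has not been computed for this offset")
    state.U3 += state.U2
    state.U4 += state.U2 * shifted_values(img, off)
    return state


def finalize(state: PassState) -> np.ndarray:
    """Normalize: X = U4 / U3.  U3 > 0 everywhere once the self offset ran."""
    if np.any(state.U3 <= 0):
        raise RuntimeError("zero weight sum encountered; the self offset was not accumulated")
    return state.U4 / state.U3


def nlm_filter_conventional(
    img: np.ndarray,
    params: NLMParams,
    counter: OpCount | None = None,
) -> np.ndarray:
    """Run the four-pass cascade over the full offset list.

    Equals the naive oracle to floating-point accumulation error.  When a
    counter is given, each pass charges the cost model's per-pixel units:
    1 (difference) + (2B+1)^2 (weights) + 1 (accumulation) per offset, plus
    1 for the final normalization, for a total of |N|((2B+1)^2 + 2) + 1 per
    pixel.
    """
    img = validate_image(img)
    m, n = img.shape
    B = params.B
    kernel = gaussian_kernel(B)
    patch = (2 * B + 1) ** 2
    npix = m * n
    state = PassState.zeros(m, n)
    for off in enumerate_offsets(params.T, "full"):
        state.U1 = diff_pass(img, off, B=B, T=params.T)
        state.U2 = weight_pass(img, off, kernel, params, U1=state.U1)
        accumulate_pass(state, img, off)
        if counter is not None:
            counter.add(intensity_reads=npix, charged_per_pixel=1)  # diff partner fetch
            counter.add(madds=patch * npix, exp_evals=npix, charged_per_pixel=patch)
            counter.add(intensity_reads=npix, madds=2 * npix, charged_per_pixel=1)
    out = finalize(state)
    if counter is not None:
        counter.add(madds=npix, charged_per_pixel=1)
    return out
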