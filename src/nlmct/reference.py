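"""Naive non-local means: the literal, loop-structured correctness oracle.

Every pixel is replaced by the weighted average of the pixels inside its
search window, the weight of each partner being an exponential of the
kernel-weighted sum of absolute patch differences:

    X(p) = sum_q w(p,q) Y(q) / sum_q w(p,q)
    w(p,q) = exp( - sum_{dx,dy} |Y(p+d) - Y(q+d)| G(dx,dy) / (h^2 (2B+1)^2) )

This engine is deliberately unoptimized — a direct transcription of the
filter definition, pixel by pixel and offset by offset — because it serves
as the oracle that the decomposed and the row-cached engines must match to
1e-10 relative.
"""

from __future__ import annotations

import math

import numpy as np

from .core import NLMParams, gaussian_kernel, pad_symmetric, validate_image

__all__ = ["patch_distance", "weight", "nlm_filter_naive"]


def patch_distance(
    padded: np.ndarray,
    p: tuple[int, int],
    q: tuple[int, int],
    B: int,
    kernel: np.ndarray,
) -> float:
    """Kernel-weighted sum of absolute patch differences between centers p and q.

    ``p`` and ``q`` are ``(x, y)`` centers in unpadded coordinates; ``padded``
    is the B-padded image, so the (2B+1)x(2B+1) patch around a center starts
    at the center's own unpadded index.  Symmetric in p and q; zero iff the
    two patches are identical.
    """
    px, py = p
    qx, qy = q
    w = 2 * B + 1
    patch_p = padded[py : py + w, px : px + w]
    patch_q = padded[qy : qy + w, qx : qx + w]
    if patch_p.shape != (w, w) or patch_q.shape != (w, w):
        raise IndexError(f"patch centers {p}, {q} out of the image domain")
    # kernel is indexed [dx+B, dy+B]; the slices are [row=dy, col=dx].  G is
    # symmetric under transposition so the orientation is immaterial.
    return float(np.sum(np.abs(patch_p - patch_q) * kernel))


def weight(dist: float, h: float, B: int) -> float:
    """Similarity weight exp(-dist / (h^2 (2B+1)^2)); 1 at dist = 0."""
    if not (h > 0):
        raise ValueError(f"smoothing parameter h must be positive, got {h!r}")
    if dist < 0:
        raise ValueError(f"patch distance must be non-negative, got {dist!r}")
    return math.exp(-dist / (h * h * (2 * B + 1) ** 2))


def nlm_filter_naive(img: np.ndarray, params: NLMParams) -> np.ndarray:
    """Filter *img* by the literal definition.

    Partners outside the image are skipped (window truncation); patch
    differences read the symmetrically padded image.  Offsets are visited
    in row-major order (i_y ascending, then i_x) so repeated runs accumulate
    in the same order and are bit-identical.
    """
    img = validate_image(img)
    m, n = img.shape
    T, B, h = params.T, params.B, params.h
    kernel = gaussian_kernel(B)
    padded = pad_symmetric(img, B)
    denom = h * h * (2 * B + 1) ** 2
    out = np.empty_like(img)
    for y in range(m):
        for x in range(n):
            wsum = 0.0
            vsum = 0.0
            for iy in range(-T, T + 1):
                qy = y + iy
                if qy < 0 or qy >= m:
                    continue
                for ix in range(-T, T + 1):
                    qx = x + ix
                    if qx < 0 or qx >= n:
                        continue
                    d = patch_distance(padded, (x, y), (qx, qy), B, kernel)
                    w = math.exp(-d / denom)
                    wsum += w
                    vsum += w * img[qy, qx]
            out[y, x] = vsum / wsum
    return out
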