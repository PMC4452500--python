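"""Shared primitives for the non-local means engines.

Conventions used across the whole package:

* Images are 2D ``float64`` numpy arrays of shape ``(m, n)`` — *m* rows,
  *n* columns.  A pixel is addressed as ``(x, y)`` with ``x`` the column
  (horizontal) and ``y`` the row (vertical), both 0-based, so the array
  element is ``img[y, x]``.  A "row" is the set of pixels at fixed ``y``.
* The search window around a pixel has radius ``T`` (``(2T+1) x (2T+1)``
  candidate positions); comparison patches have radius ``B``
  (``(2B+1) x (2B+1)`` pixels); ``h`` scales the patch distance inside the
  exponential weight.
* Candidate partners falling outside the image are excluded from the
  average (window truncation), while patch differences are evaluated on a
  symmetrically padded image, so the three engines share one exact
  semantics and can be compared to 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, List, Tuple

import numpy as np

Offset = Tuple[int, int]  # (i_x, i_y) displacement inside the search window

__all__ = [
    "NLMParams",
    "OpCount",
    "Offset",
    "validate_image",
    "gaussian_kernel",
    "pad_symmetric",
    "enumerate_offsets",
    "inbounds_mask",
    "shifted_values",
]


@dataclass(frozen=True)
class NLMParams:
    """Filter parameters.

    Parameters
    ----------
    T : int
        Search radius in pixels; the window holds ``(2T+1)**2`` candidates.
        Default 40 (an 81 x 81 window, the clinical low-dose CT setting).
    B : int
        Patch radius in pixels; patches hold ``(2B+1)**2`` pixels.
        Default 4 (9 x 9 patches).
    h : float
        Smoothing strength in intensity units, > 0.  Default 10, meant for
        images on a 0–255 display scale; ``h`` is scale-relative.
    """

    T: int = 40
    B: int = 4
    h: float = 10.0

    def __post_init__(self) -> None:
        if not (isinstance(self.T, (int, np.integer)) and self.T >= 0):
            raise ValueError(f"search radius T must be a non-negative integer, got {self.T!r}")
        if not (isinstance(self.B, (int, np.integer)) and self.B >= 0):
            raise ValueError(f"patch radius B must be a non-negative integer, got {self.B!r}")
        if not (np.isfinite(self.h) and self.h > 0):
            raise ValueError(f"smoothing parameter h must be positive and finite, got {self.h!r}")

    @property
    def window_size(self) -> int:
        """Number of candidate positions in the search window, |N|."""
        return (2 * self.T + 1) ** 2

    @property
    def patch_pixels(self) -> int:
        """Number of pixels in a comparison patch, (2B+1)^2."""
        return (2 * self.B + 1) ** 2


@dataclass
class OpCount:
    """Operation counters implementing the memory-bound cost model.

    ``intensity_reads`` counts fetches of image pixels from the
    (conceptually global) image buffer; reads of cached row differences are
    free and are charged to ``madds`` as arithmetic instead.
    ``charged_per_pixel`` accumulates the abstract per-pixel unit charges of
    the closed-form complexity model as an exact rational (the half-window
    engine produces half-integer totals).
    """

    intensity_reads: int = 0
    madds: int = 0
    exp_evals: int = 0
    charged_per_pixel: Fraction = field(default_factory=lambda: Fraction(0))

    def add(
        self,
        *,
        intensity_reads: int = 0,
        madds: int = 0,
        exp_evals: int = 0,
        charged_per_pixel: Fraction | int = 0,
    ) -> None:
        if min(intensity_reads, madds, exp_evals) < 0 or charged_per_pixel < 0:
            raise ValueError("operation counters only accumulate non-negative charges")
        self.intensity_reads += intensity_reads
        self.madds += madds
        self.exp_evals += exp_evals
        self.charged_per_pixel += Fraction(charged_per_pixel)


def validate_image(img: np.ndarray) -> np.ndarray:
    """Coerce *img* to a finite 2D float64 array (copying only if needed)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must be at least 1x1, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def gaussian_kernel(B: int) -> np.ndarray:
    """Distance-dependent patch kernel G.

    ``G(0, 0) = 2`` and ``G(dx, dy) = 1 / (dx^2 + dy^2)`` elsewhere, on the
    grid ``(dx, dy) in [-B..B]^2``.  Returned as a ``(2B+1, 2B+1)`` array
    indexed ``[dx + B, dy + B]`` (the table is symmetric under transposition
    and under either sign flip, so axis order never matters in practice).
    """
    if not (isinstance(B, (int, np.integer)) and B >= 0):
        raise ValueError(f"patch radius B must be a non-negative integer, got {B!r}")
    d = np.arange(-B, B + 1)
    r2 = d[:, None] ** 2 + d[None, :] ** 2
    with np.errstate(divide="ignore"):
        g = 1.0 / r2
    g[B, B] = 2.0
    return g


def pad_symmetric(img: np.ndarray, B: int) -> np.ndarray:
    """Pad *img* by *B* pixels on every side with an edge-duplicating mirror.

    ``[1, 2, 3]`` padded by 1 becomes ``[1, 1, 2, 3, 3]``; a 1x1 image pads
    to a constant block.  Patch differences near the border are evaluated on
    this padded image.
    """
    img = validate_image(img)
    if not (isinstance(B, (int, np.integer)) and B >= 0):
        raise ValueError(f"pad width must be a non-negative integer, got {B!r}")
    if B == 0:
        return img.copy()
    return np.pad(img, int(B), mode="symmetric")


def enumerate_offsets(T: int, mode: str = "full") -> List[Offset]:
    """Enumerate search-window offsets ``(i_x, i_y)`` in row-major order.

    ``mode="full"`` yields all ``(2T+1)**2`` offsets with ``i_y`` ascending,
    then ``i_x``.  ``mode="half"`` yields the ``((2T+1)**2 - 1) / 2`` offsets
    with ``i_y > 0``, plus those with ``i_y == 0 and i_x > 0``; the self
    offset ``(0, 0)`` is never included (the half-window engine handles it
    once, separately).  The half list, its negations and ``(0, 0)`` together
    are exactly the full list.
    """
    if not (isinstance(T, (int, np.integer)) and T >= 0):
        raise ValueError(f"search radius T must be a non-negative integer, got {T!r}")
    if mode == "full":
        return [(ix, iy) for iy in range(-T, T + 1) for ix in range(-T, T + 1)]
    if mode == "half":
        out: List[Offset] = [(ix, 0) for ix in range(1, T + 1)]
        out += [(ix, iy) for iy in range(1, T + 1) for ix in range(-T, T + 1)]
        return out
    raise ValueError(f"mode must be 'full' or 'half', got {mode!r}")


def inbounds_mask(m: int, n: int, off: Offset) -> np.ndarray:
    """Boolean plane: True where the partner ``p + off`` lies inside the image."""
    ix, iy = off
    mask = np.zeros((m, n), dtype=bool)
    y0, y1 = max(0, -iy), min(m, m - iy)
    x0, x1 = max(0, -ix), min(n, n - ix)
    if y0 < y1 and x0 < x1:
        mask[y0:y1, x0:x1] = True
    return mask


def shifted_values(img: np.ndarray, off: Offset) -> np.ndarray:
    """Plane of partner values ``Y(p + off)``, zero where the partner is outside."""
    m, n = img.shape
    ix, iy = off
    out = np.zeros_like(img)
    y0, y1 = max(0, -iy), min(m, m - iy)
    x0, x1 = max(0, -ix), min(n, n - ix)
    if y0 < y1 and x0 < x1:
        out[y0:y1, x0:x1] = img[y0 + iy : y1 + iy, x0 + ix : x1 + ix]
    return out
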